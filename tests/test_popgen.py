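"""Hardy–Weinberg tests, F-statistics, diversity and the Wahlund signal."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from hybridzone.core import GenotypeMatrix, ParameterError
from hybridzone.popgen import (
    allelic_richness,
    f_statistics,
    fis_bootstrap_ci,
    heterozygosity,
    hwe_exact_test,
    hwe_global,
    parametric_fst,
    wahlund_regression,
)
from hybridzone.synthetic import generate_parental_frequencies, sample_population

from conftest import make_genotypes


def genotypes_from_counts(counts, loci=("L1",)):
    """counts: dict genotype-pair -> n, e.g. {(1, 1): 25, (1, 2): 50}."""
    rows = []
    for pair, n in counts.items():
        rows.extend([[pair]] * n)
    return make_genotypes(rows, loci=list(loci))


class TestHeterozygosity:
    def test_all_heterozygous(self):
        gm = genotypes_from_counts({(1, 2): 10})
        assert heterozygosity(gm).loc["L1", "H_O"] == 1.0

    def test_monomorphic_he_zero(self):
        gm = genotypes_from_counts({(1, 1): 10})
        assert heterozygosity(gm).loc["L1", "H_E"] == 0.0

    def test_unbiased_formula_small_sample(self):
        # 5 individuals: 1/1, 1/1, 1/2, 2/2, 1/2 -> p1 = 0.6
        gm = genotypes_from_counts({(1, 1): 2, (1, 2): 2, (2, 2): 1})
        res = heterozygosity(gm)
        n, p1 = 5, 0.6
        expected = (2 * n) / (2 * n - 1) * (1 - p1**2 - (1 - p1) ** 2)
        assert res.loc["L1", "H_E"] == pytest.approx(expected, abs=1e-12)
        assert res.loc["L1", "H_O"] == pytest.approx(0.4)


def enumerate_hwe_exact_p(genotype_counts):
    """Full-enumeration exact Hardy–Weinberg p-value.

    Enumerates every genotype table with the observed allele margins under
    Levene's conditional distribution and sums the probabilities of tables
    no more probable than the observed one.
    """
    alleles = sorted({a for pair in genotype_counts for a in pair})
    k = len(alleles)
    idx = {a: i for i, a in enumerate(alleles)}
    n = sum(genotype_counts.values())
    margin = np.zeros(k, dtype=int)
    for (a, b), c in genotype_counts.items():
        margin[idx[a]] += c
        margin[idx[b]] += c
    cats = [(i, j) for i in range(k) for j in range(i, k)]
    logfact = gammaln(np.arange(2 * n + 1) + 1.0)

    def log_prob(counts):
        het = sum(c for (i, j), c in zip(cats, counts) if i != j)
        lp = logfact[n] + margin_logfact - logfact[2 * n] + het * np.log(2.0)
        lp -= sum(logfact[c] for c in counts)
        return lp

    margin_logfact = logfact[margin].sum()
    tables = []

    def recurse(pos, counts, used_margin, remaining):
        if pos == len(cats):
            if remaining == 0 and all(used_margin == margin):
                tables.append(tuple(counts))
            return
        i, j = cats[pos]
        for c in range(remaining + 1):
            um = used_margin.copy()
            um[i] += c
            um[j] += c
            if (um > margin).any():
                if c == 0:
                    continue
                break
            recurse(pos + 1, counts + [c], um, remaining - c)

    recurse(0, [], np.zeros(k, dtype=int), n)
    obs = tuple(genotype_counts.get((alleles[i], alleles[j]), 0) for i, j in cats)
    lp_obs = log_prob(obs)
    total = p = 0.0
    for t in tables:
        lp = log_prob(t)
        total += np.exp(lp)
        if lp <= lp_obs + 1e-9:
            p += np.exp(lp)
    assert total == pytest.approx(1.0, abs=1e-9)
    return p


class TestHweExact:
    def test_perfect_proportions_not_rejected(self):
        gm = genotypes_from_counts({(1, 1): 25, (1, 2): 50, (2, 2): 25})
        assert hwe_exact_test(gm, "L1", n_mc=1000, seed=0) > 0.5

    def test_total_heterozygote_deficit_rejected(self):
        gm = genotypes_from_counts({(1, 1): 50, (2, 2): 50})
        assert hwe_exact_test(gm, "L1", n_mc=1000, seed=0) <= 0.01

    def test_monomorphic_warns_p_one(self):
        gm = genotypes_from_counts({(1, 1): 10})
        with pytest.warns(UserWarning):
            assert hwe_exact_test(gm, "L1") == 1.0

    @pytest.mark.parametrize(
        "counts",
        [
            {(1, 1): 2, (1, 2): 3, (2, 2): 1, (1, 3): 2, (2, 3): 1, (3, 3): 1},
            {(1, 1): 4, (2, 3): 3, (1, 3): 2, (2, 2): 1},
        ],
    )
    def test_monte_carlo_matches_full_enumeration(self, counts):
        gm = genotypes_from_counts(counts)
        exact = enumerate_hwe_exact_p(counts)
        mc = hwe_exact_test(gm, "L1", n_mc=4000, seed=1)
        assert mc == pytest.approx(exact, abs=0.05)

    def test_global_fisher_combination(self):
        gm = make_genotypes(
            [[(1, 1), (1, 2)], [(1, 1), (1, 2)], [(2, 2), (1, 2)],
             [(2, 2), (1, 2)], [(1, 2), (1, 2)], [(1, 2), (1, 2)]]
        )
        per_locus, global_p = hwe_global(gm, n_mc=500, seed=0)
        assert set(per_locus.index) == {"L1", "L2"}
        assert 0.0 <= global_p <= 1.0


class TestFStatistics:
    def test_fixed_pools_fst_one(self, diagnostic_pools):
        p1, p2 = diagnostic_pools
        g1 = sample_population(p1, 20, seed=0, id_prefix="a")
        g2 = sample_population(p2, 20, seed=1, id_prefix="b")
        gm = GenotypeMatrix.concat([g1, g2])
        fs = f_statistics(gm, [0] * 20 + [1] * 20)
        assert fs.fst == pytest.approx(1.0)

    def test_hw_population_fis_near_zero(self, divergent_pools):
        wolf, _ = divergent_pools
        gm = sample_population(wolf, 10_000, seed=2)
        fs = f_statistics(gm)
        assert fs.fis == pytest.approx(0.0, abs=0.02)

    def test_two_population_toy_matches_hand_computation(self):
        # pop1: AA 4, AB 4, BB 2; pop2: AA 1, AB 3, BB 6.  Working through
        # the variance components with exact fractions gives
        # F_ST = 17/99, F_IS = 19/82, F_IT = 4/11.
        rows = ([[(1, 1)]] * 4 + [[(1, 2)]] * 4 + [[(2, 2)]] * 2
                + [[(1, 1)]] * 1 + [[(1, 2)]] * 3 + [[(2, 2)]] * 6)
        gm = make_genotypes(rows)
        fs = f_statistics(gm, [0] * 10 + [1] * 10)
        assert fs.fst == pytest.approx(17 / 99, abs=1e-12)
        assert fs.fis == pytest.approx(19 / 82, abs=1e-12)
        assert fs.fit == pytest.approx(4 / 11, abs=1e-12)

    def test_all_missing_locus_reported_nan(self):
        gm = make_genotypes([[(1, 2), None], [(1, 1), None]])
        fs = f_statistics(gm)
        assert np.isnan(fs.per_locus.loc["L2", "F_IS"])


class TestAllelicRichness:
    def test_monomorphic_everywhere(self):
        gm = genotypes_from_counts({(1, 1): 12})
        res = allelic_richness(gm, ["a"] * 6 + ["b"] * 6, n_boot=100, seed=0)
        assert (res["A_R"] == 1.0).all()
        assert (res["ci_high"] - res["ci_low"] == 0.0).all()

    def test_same_pool_groups_have_overlapping_cis(self, divergent_pools):
        wolf, _ = divergent_pools
        gm = sample_population(wolf, 60, seed=6)
        groups = ["big"] * 50 + ["small"] * 10
        res = allelic_richness(gm, groups, n_boot=300, seed=1)
        lo = res["ci_low"].max()
        hi = res["ci_high"].min()
        assert lo <= hi  # intervals overlap

    def test_standardised_to_smallest_group(self, divergent_pools):
        wolf, coyote = divergent_pools
        g1 = sample_population(wolf, 40, seed=1, id_prefix="w")
        g2 = sample_population(coyote, 10, seed=2, id_prefix="c")
        gm = GenotypeMatrix.concat([g1, g2])
        res = allelic_richness(gm, ["w"] * 40 + ["c"] * 10, n_boot=200, seed=3)
        # resampling 10 of 40 cannot reach the raw allele count of the
        # large group
        raw_mean = np.mean([len(g1.allele_counts(l)) for l in g1.loci])
        assert res.loc["w", "A_R"] < raw_mean


class TestWahlund:
    def test_exact_linear_relationship(self):
        fst = np.array([0.05, 0.1, 0.2, 0.3])
        reg = wahlund_regression(2 * fst, fst)
        assert reg.r == pytest.approx(1.0)
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)

    def test_pooled_divergent_sample_shows_positive_correlation(self):
        """Mixing two differentiated populations and analysing them as one
        inflates F_IS at the most differentiated loci."""
        f1, f2 = generate_parental_frequencies(17, 8, 0.3, seed=21)
        g1 = sample_population(f1, 60, seed=1, id_prefix="a")
        g2 = sample_population(f2, 60, seed=2, id_prefix="b")
        pooled = GenotypeMatrix.concat([g1, g2])
        fis = f_statistics(pooled).per_locus["F_IS"]
        fst = f_statistics(pooled, [0] * 60 + [1] * 60).per_locus["F_ST"]
        reg = wahlund_regression(fis, fst)
        assert reg.r > 0
        assert reg.p < 0.05

    def test_needs_three_loci(self):
        with pytest.raises(ParameterError):
            wahlund_regression([0.1, 0.2], [0.1, 0.2])


class TestFisBootstrap:
    def test_hw_population_ci_covers_zero(self, divergent_pools):
        wolf, _ = divergent_pools
        gm = sample_population(wolf, 300, seed=4)
        point, lo, hi = fis_bootstrap_ci(gm, n_boot=500, seed=0)
        assert lo <= 0.0 <= hi

    def test_inbreeding_signal_excludes_zero(self, divergent_pools):
        wolf, _ = divergent_pools
        gm = sample_population(wolf, 300, seed=5)
        # convert half the heterozygotes to homozygotes: strong F_IS > 0
        rng = np.random.default_rng(1)
        alleles = gm.alleles.copy()
        het = alleles[:, :, 0] != alleles[:, :, 1]
        flip = het & (rng.random(het.shape) < 0.5)
        alleles[:, :, 1] = np.where(flip, alleles[:, :, 0], alleles[:, :, 1])
        gm2 = GenotypeMatrix(gm.ids, gm.loci, alleles)
        point, lo, hi = fis_bootstrap_ci(gm2, n_boot=500, seed=0)
        assert lo > 0.0

    def test_seed_determinism(self, divergent_pools):
        wolf, _ = divergent_pools
        gm = sample_population(wolf, 100, seed=6)
        assert fis_bootstrap_ci(gm, n_boot=200, seed=3) == fis_bootstrap_ci(
            gm, n_boot=200, seed=3
        )


def test_parametric_fst_identical_pools_zero():
    a, b = generate_parental_frequencies(5, 4, 0.0, seed=0)
    _, fst = parametric_fst(a, b)
    assert fst == pytest.approx(0.0, abs=1e-12)
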