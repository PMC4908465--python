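"""Scenario compositions, classification, zone summaries, K-S and logistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hybridzone.core import GenotypeMatrix, ParameterError
from hybridzone.hybridsim import HybridClass
from hybridzone.scenario import (
    RegionSpec,
    build_scenario_dataset,
    classify_ancestry,
    fit_logistic,
    hybrid_percentage,
    ks_compare,
    run_scenario_comparison,
    solve_composition,
    zone_summary,
)


#: Region layout of the study system: 180 individuals in the zone of overlap
#: with mean red-wolf ancestry 0.437, 131 outside it with mean 0.024.
STUDY_REGIONS = [
    RegionSpec("overlap", 180, 0.437, core=True),
    RegionSpec("outside", 131, 0.024, core=False),
]


class TestSolveComposition:
    """Frozen compositions for the four study scenarios, hand-derived from
    the ancestry-balance equations before implementation."""

    def test_random_mating_scenario(self):
        comp = solve_composition(STUDY_REGIONS, 0.386)
        assert comp.red_wolves == 44
        assert comp.coyotes == 192
        assert comp.total_hybrids == 75
        assert comp.hybrids == {HybridClass.F1: 19, HybridClass.F2: 18,
                                HybridClass.BC1: 19, HybridClass.BC2: 19}
        assert comp.total == 311

    def test_assortative_mating_scenario(self):
        comp = solve_composition(STUDY_REGIONS, 0.276)
        assert comp.red_wolves == 54
        assert comp.coyotes == 201
        assert comp.total_hybrids == 56
        assert comp.total == 311

    def test_challenged_pairings_scenario(self):
        comp = solve_composition(STUDY_REGIONS, 0.189)
        assert comp.red_wolves == 62
        assert comp.coyotes == 209
        assert comp.total_hybrids == 40
        assert comp.total == 311

    def test_no_hybridization_scenario(self):
        comp = solve_composition(STUDY_REGIONS, 0.0)
        assert comp.red_wolves == 82
        assert comp.coyotes == 229
        assert comp.total_hybrids == 0
        assert comp.total == 311

    def test_core_region_detail(self):
        comp = solve_composition(STUDY_REGIONS, 0.386)
        row = comp.per_region.loc["overlap"]
        assert (row["red_wolves"], row["coyotes"], row["hybrids"]) == (44, 67, 69)
        out = comp.per_region.loc["outside"]
        assert (out["red_wolves"], out["coyotes"], out["hybrids"]) == (0, 125, 6)

    def test_totals_conserved_for_any_proportion(self):
        for p_h in np.linspace(0.0, 0.8, 17):
            comp = solve_composition(STUDY_REGIONS, float(p_h))
            assert comp.total == 311

    def test_red_wolves_decrease_as_hybrids_increase(self):
        wolves = [solve_composition(STUDY_REGIONS, p).red_wolves
                  for p in (0.0, 0.1, 0.2, 0.3, 0.4)]
        assert all(a >= b for a, b in zip(wolves, wolves[1:]))

    def test_infeasible_region_named(self):
        regions = [RegionSpec("tiny", 10, 0.1, core=True)]
        with pytest.raises(ParameterError, match="tiny"):
            solve_composition(regions, 0.9)  # 9 hybrids imply negative wolves

    def test_even_hybrid_split(self):
        comp = solve_composition([RegionSpec("z", 100, 0.5)], 0.4)
        assert set(comp.hybrids.values()) == {10}


class TestBuildDataset:
    def test_counts_and_labels_match_composition(self, diagnostic_pools):
        comp = solve_composition([RegionSpec("z", 40, 0.5)], 0.2)
        gm = build_scenario_dataset(comp, *diagnostic_pools, seed=0)
        counts = gm.metadata["true_class"].value_counts()
        for cls, n in comp.counts().items():
            assert counts.get(cls.value, 0) == n


class TestClassification:
    def test_thresholds(self):
        labels = classify_ancestry([1.0, 0.875, 0.8644, 0.5, 0.125, 0.124, 0.0])
        assert list(labels) == ["red wolf", "red wolf", "hybrid", "hybrid",
                                "hybrid", "coyote", "coyote"]

    def test_study_percentage(self):
        q = [1.0] * 75 + [0.0] * 224 + [0.5] * 12
        assert hybrid_percentage(classify_ancestry(q)) == 3.86

    def test_invalid_q_rejected(self):
        with pytest.raises(ParameterError):
            classify_ancestry([1.2])
        with pytest.raises(ParameterError):
            hybrid_percentage([])


class TestZoneSummary:
    def test_distinct_zones_significant_with_distinct_letters(self):
        rng = np.random.default_rng(0)
        q = np.concatenate([rng.normal(0.1, 0.02, 30).clip(0, 1),
                            rng.normal(0.5, 0.02, 30).clip(0, 1),
                            rng.normal(0.9, 0.02, 30).clip(0, 1)])
        zones = ["low"] * 30 + ["mid"] * 30 + ["high"] * 30
        res = zone_summary(q, zones, seed=1)
        assert res.anova_p < 1e-6
        assert len(set(res.table["letters"])) == 3
        for z, m in (("low", 0.1), ("mid", 0.5), ("high", 0.9)):
            row = res.table.loc[z]
            assert row["ci_low"] < m < row["ci_high"]

    def test_identical_zones_share_a_letter(self):
        rng = np.random.default_rng(2)
        q = rng.normal(0.4, 0.05, 60).clip(0, 1)
        res = zone_summary(q, ["a"] * 20 + ["b"] * 20 + ["c"] * 20, seed=0)
        assert res.anova_p > 0.01
        assert len(set(res.table["letters"])) == 1

    def test_uniform_hybrids_chi2_not_significant(self):
        # 5 hybrids (q = 0.5) in each of 3 zones among parental backgrounds
        q = ([0.5] * 5 + [0.0] * 20) * 3
        zones = sum([[z] * 25 for z in ("a", "b", "c")], [])
        res = zone_summary(q, zones, seed=3)
        assert res.chi2 == pytest.approx(0.0)
        assert res.chi2_p == pytest.approx(1.0)
        assert res.chi2_p_mc > 0.9

    def test_concentrated_hybrids_chi2_significant(self):
        q = [0.5] * 15 + [0.0] * 10 + [0.0] * 25 + [0.0] * 25
        zones = ["a"] * 25 + ["b"] * 25 + ["c"] * 25
        res = zone_summary(q, zones, seed=4)
        assert res.chi2_p < 0.001
        assert res.chi2_p_mc < 0.01

    def test_singleton_zone_excluded_but_reported(self):
        q = [0.1] * 10 + [0.9] * 10 + [0.5]
        zones = ["a"] * 10 + ["b"] * 10 + ["solo"]
        res = zone_summary(q, zones, seed=0)
        assert res.excluded_zones == ["solo"]
        assert res.table.loc["solo", "n"] == 1
        assert np.isnan(res.table.loc["solo", "ci_low"])


class TestKsCompare:
    def test_simple_example(self):
        d, p = ks_compare([0.1, 0.2, 0.3], [0.2, 0.3, 0.4])
        assert d == pytest.approx(1 / 3)

    def test_identical_samples_distance_zero(self):
        d, p = ks_compare([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_samples_distance_one(self):
        d, _ = ks_compare([0.0, 0.1], [0.8, 0.9, 1.0])
        assert d == 1.0

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50),
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50),
    )
    def test_matches_brute_force_ecdf_supremum(self, xs, ys):
        d, _ = ks_compare(xs, ys)
        x, y = np.asarray(xs), np.asarray(ys)
        pts = np.concatenate([x, y])
        brute = max(
            abs((x <= t).mean() - (y <= t).mean()) for t in pts
        )
        assert d == pytest.approx(brute, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            ks_compare([], [0.5])


class TestLogisticFit:
    def test_exact_recovery_of_known_curve(self):
        a, b, c, n = 1.0, 150.0, 0.364, 311
        x = np.arange(1, n + 1)
        y = a / (1 + np.exp(-c * (x - b)))
        fit = fit_logistic(y)
        assert fit.converged
        assert fit.a == pytest.approx(a, abs=1e-4)
        assert fit.b == pytest.approx(b, abs=1e-4)
        assert fit.c == pytest.approx(c, abs=1e-4)
        assert fit.rss < 1e-8

    def test_bimodal_distribution_steeper_than_ramp(self):
        """A parental-dominated (two-peaked) q distribution fits a much
        steeper logistic than a continuum of intermediate ancestries."""
        bimodal = np.array([0.02] * 150 + [0.98] * 150)
        ramp = np.linspace(0.0, 1.0, 300)
        assert fit_logistic(bimodal).c > 5 * fit_logistic(ramp).c

    def test_sorting_is_internal(self):
        rng = np.random.default_rng(1)
        y = 1 / (1 + np.exp(-0.2 * (np.arange(1, 101) - 50)))
        shuffled = rng.permutation(y)
        assert fit_logistic(shuffled).c == pytest.approx(fit_logistic(y).c)

    def test_needs_four_points(self):
        with pytest.raises(ParameterError):
            fit_logistic([0.1, 0.5, 0.9])


class TestScenarioComparison:
    def test_smoke_run_identifies_composition_and_metrics(self, divergent_pools):
        """An empirical q distribution produced by the pipeline itself from a
        hybrid-free composition is matched best by the hybrid-free scenario."""
        regions = [RegionSpec("core", 24, 0.5, core=True)]
        # "empirical" data: 12 wolves + 12 coyotes pushed through the same
        # simulate -> admixture -> anchor machinery with independent seeds
        from hybridzone.admixture import (align_runs, anchor_clusters,
                                          run_admixture_replicates)
        from hybridzone.hybridsim import simulate_class

        comp = solve_composition(regions, 0.0, label="emp")
        data = build_scenario_dataset(comp, *divergent_pools, seed=42)
        anchors = GenotypeMatrix.concat([
            simulate_class(*divergent_pools, "P1", 4, seed=43, id_prefix="kw"),
            simulate_class(*divergent_pools, "P2", 4, seed=44, id_prefix="kc"),
        ])
        full = GenotypeMatrix.concat([data, anchors])
        runs = run_admixture_replicates(full, 2, n_runs=2, seed=45,
                                        model="uncorrelated",
                                        burnin=150, reps=800)
        res = anchor_clusters(
            align_runs(runs),
            {**{i: "red wolf" for i in anchors.ids if i.startswith("kw")},
             **{i: "coyote" for i in anchors.ids if i.startswith("kc")}},
            strict=False,
        )
        emp = res.q[[i in data.ids for i in res.ids], 0]

        out = run_scenario_comparison(
            emp, {"none": 0.0, "half": 0.5}, regions, *divergent_pools,
            runs=2, seed=5, burnin=150, reps=800, model="uncorrelated",
            n_anchor=4,
        )
        assert "error" not in out.columns or out["error"].isna().all()
        assert out.loc["none", "n"] == 24 and out.loc["half", "n"] == 24
        assert out.loc["none", "hybrids"] == 0
        assert out.loc["half", "hybrids"] == 12
        # the no-hybrid scenario matches the bimodal empirical data better
        assert out.loc["none", "ks_d"] < out.loc["half", "ks_d"]
        assert out.loc["none", "logistic_c"] > out.loc["half", "logistic_c"]

    def test_failing_scenario_preserves_others(self, diagnostic_pools):
        regions = [RegionSpec("core", 10, 0.1, core=True)]
        out = run_scenario_comparison(
            [0.1, 0.2, 0.3, 0.4], {"ok": 0.0, "bad": 0.9}, regions,
            *diagnostic_pools, runs=2, seed=0, burnin=100, reps=400,
            model="uncorrelated", n_anchor=3,
        )
        assert np.isfinite(out.loc["ok", "ks_d"])
        assert "infeasible" in out.loc["bad", "error"]
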