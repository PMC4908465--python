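"""Locus- and group-level population-genetic summaries.

Implements the standard descriptive machinery for microsatellite surveys:
Hardy–Weinberg exact tests with Monte-Carlo evaluation, Weir–Cockerham
variance-component F-statistics, observed and unbiased expected
heterozygosity, bootstrap allelic richness, a locus-wise F_IS on F_ST
regression for diagnosing a Wahlund effect, and bias-corrected bootstrap
confidence intervals for F_IS.

Pooling two differentiated populations into one sample depresses observed
heterozygosity in proportion to how differentiated each locus is, so a
positive across-locus correlation between F_IS and F_ST is the signature of
such hidden structure (the Wahlund effect) — this is what
:func:`wahlund_regression` tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, ndtr, ndtri

from .core import MISSING, AlleleFrequencyTable, GenotypeMatrix, ParameterError

__all__ = [
    "heterozygosity",
    "hwe_exact_test",
    "hwe_global",
    "f_statistics",
    "FStatistics",
    "allelic_richness",
    "wahlund_regression",
    "WahlundRegression",
    "fis_bootstrap_ci",
    "parametric_fst",
    "popgen_summary",
]

_LOG2 = float(np.log(2.0))


# -- heterozygosity ----------------------------------------------------------

def heterozygosity(gm: GenotypeMatrix) -> pd.DataFrame:
    """Observed and Nei's unbiased expected heterozygosity per locus.

    H_O is the fraction of heterozygotes among typed individuals; H_E is
    ``2n/(2n-1) * (1 - sum p_hat_i^2)`` with n the number of typed
    individuals at the locus.
    """
    rows = []
    for j, loc in enumerate(gm.loci):
        a = gm.alleles[:, j]
        a = a[a[:, 0] != MISSING]
        n = len(a)
        if n < 2:
            rows.append({"locus": loc, "n": n, "H_O": np.nan, "H_E": np.nan})
            continue
        ho = float((a[:, 0] != a[:, 1]).mean())
        _, cnt = np.unique(a.ravel(), return_counts=True)
        p = cnt / (2 * n)
        he = (2 * n) / (2 * n - 1) * (1.0 - float(np.sum(p**2)))
        rows.append({"locus": loc, "n": n, "H_O": ho, "H_E": he})
    return pd.DataFrame(rows).set_index("locus")


# -- Hardy-Weinberg exact test ----------------------------------------------

def _genotype_log_prob(lo: np.ndarray, hi: np.ndarray, k: int,
                       const: float, logfact: np.ndarray) -> np.ndarray:
    """Log conditional probability of each row's genotype table given the
    allele counts (Levene's distribution).  ``lo``/``hi`` are (m, n) sorted
    allele-index pairs."""
    m, n = lo.shape
    het = (lo != hi).sum(axis=1)
    code = lo * k + hi
    offs = np.arange(m)[:, None] * (k * k)
    cnt = np.bincount((offs + code).ravel(), minlength=m * k * k).reshape(m, k * k)
    return het * _LOG2 + const - logfact[cnt].sum(axis=1)


def hwe_exact_test(
    gm: GenotypeMatrix,
    locus: str,
    n_mc: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo exact test of Hardy–Weinberg proportions at one locus.

    The observed allele pool is permuted into random diploid genotype tables
    ``n_mc`` times; the p-value is the proportion of tables (the observed
    one included) whose conditional probability under the Hardy–Weinberg
    null is at most the observed table's.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    j = gm.locus_index(locus)
    a = gm.alleles[:, j]
    a = a[a[:, 0] != MISSING]
    n = len(a)
    if n < 2:
        raise ParameterError(f"need >= 2 typed individuals at {locus!r}")
    vals, inv = np.unique(a.ravel(), return_inverse=True)
    k = len(vals)
    if k == 1:
        warnings.warn(f"locus {locus!r} is monomorphic; HWE p-value is 1")
        return 1.0
    logfact = gammaln(np.arange(2 * n + 1) + 1.0)
    allele_counts = np.bincount(inv, minlength=k)
    const = logfact[n] + logfact[allele_counts].sum() - logfact[2 * n]

    codes = np.sort(inv.reshape(n, 2), axis=1)
    obs_lp = _genotype_log_prob(codes[None, :, 0], codes[None, :, 1], k,
                                const, logfact)[0]
    perm = rng.permuted(np.tile(inv, (n_mc, 1)), axis=1).reshape(n_mc, n, 2)
    perm.sort(axis=2)
    mc_lp = _genotype_log_prob(perm[:, :, 0], perm[:, :, 1], k, const, logfact)
    hits = int(np.sum(mc_lp <= obs_lp + 1e-9))
    return (hits + 1) / (n_mc + 1)


def hwe_global(
    gm: GenotypeMatrix,
    loci: list[str] | None = None,
    n_mc: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.Series, float]:
    """Per-locus Hardy–Weinberg p-values plus a global p combined across
    loci by Fisher's method (monomorphic loci contribute p = 1)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loci = loci or list(gm.loci)
    ps = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for loc in loci:
            ps[loc] = hwe_exact_test(gm, loc, n_mc=n_mc, seed=rng)
    series = pd.Series(ps, name="hwe_p")
    stat, p = stats.combine_pvalues(series.to_numpy(), method="fisher")
    return series, float(p)


# -- Weir-Cockerham F-statistics ---------------------------------------------

@dataclass
class FStatistics:
    """Variance-component F-statistics (Weir & Cockerham 1984).

    ``per_locus`` rows hold F_IS, F_ST and F_IT; the multilocus estimates are
    ratios of variance components summed over alleles and loci, not averages
    of per-locus ratios.
    """

    per_locus: pd.DataFrame
    fis: float
    fst: float
    fit: float


def _wc_components(a: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Summed (a, b, c) variance components over alleles for one locus.

    ``a`` is (n, 2) typed allele pairs and ``labels`` the subpopulation of
    each row.  With a single subpopulation only (b, c) are meaningful and
    the among-population component is returned as NaN.
    """
    pops = np.unique(labels)
    r = len(pops)
    sizes, freqs, hets = [], [], []
    alleles = np.unique(a)
    for pop in pops:
        sub = a[labels == pop]
        ni = len(sub)
        if ni == 0:
            continue
        sizes.append(ni)
        cnt = np.array([(sub == al).sum() for al in alleles], dtype=float)
        freqs.append(cnt / (2 * ni))
        hets.append(np.array([((sub[:, 0] == al) ^ (sub[:, 1] == al)).mean()
                              for al in alleles]))
    sizes = np.array(sizes, dtype=float)
    r = len(sizes)
    P = np.stack(freqs)   # (r, n_alleles)
    H = np.stack(hets)
    nbar = sizes.mean()
    if nbar <= 1:
        return np.nan, np.nan, np.nan
    pbar = (sizes[:, None] * P).sum(0) / (r * nbar)
    hbar = (sizes[:, None] * H).sum(0) / (r * nbar)
    if r > 1:
        nc = (r * nbar - np.sum(sizes**2) / (r * nbar)) / (r - 1)
        s2 = (sizes[:, None] * (P - pbar) ** 2).sum(0) / ((r - 1) * nbar)
        a_comp = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b_comp = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        A = float(a_comp.sum())
    else:
        b_comp = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        A = np.nan
    c_comp = hbar / 2
    return A, float(b_comp.sum()), float(c_comp.sum())


def f_statistics(
    gm: GenotypeMatrix, labels: np.ndarray | pd.Series | list | None = None
) -> FStatistics:
    """Per-locus and multilocus F_IS / F_ST / F_IT.

    ``labels`` assigns each individual to a subpopulation; with one (or no)
    label F_ST is undefined and only F_IS is estimated.  Missing genotypes
    are excluded per locus; all-missing loci are reported as NaN.
    """
    if labels is None:
        labels = np.zeros(gm.n_individuals, dtype=int)
    labels = np.asarray(pd.Series(labels).to_numpy())
    if len(labels) != gm.n_individuals:
        raise ParameterError("labels length must equal the number of individuals")
    rows, sums = [], np.zeros(3)
    have_a = False
    for j, loc in enumerate(gm.loci):
        al = gm.alleles[:, j]
        typed = al[:, 0] != MISSING
        if typed.sum() < 2 or len(np.unique(al[typed])) < 2:
            rows.append({"locus": loc, "F_IS": np.nan, "F_ST": np.nan, "F_IT": np.nan})
            continue
        A, B, C = _wc_components(al[typed], labels[typed])
        fis = 1 - C / (B + C) if (B + C) != 0 else np.nan
        if np.isnan(A):
            fst = fit = np.nan
        else:
            have_a = True
            tot = A + B + C
            fst = A / tot if tot != 0 else np.nan
            fit = 1 - C / tot if tot != 0 else np.nan
            sums[0] += A
        sums[1] += B
        sums[2] += C
        rows.append({"locus": loc, "F_IS": fis, "F_ST": fst, "F_IT": fit})
    per_locus = pd.DataFrame(rows).set_index("locus")
    A, B, C = sums
    fis = 1 - C / (B + C) if (B + C) != 0 else np.nan
    if have_a:
        fst = A / (A + B + C)
        fit = 1 - C / (A + B + C)
    else:
        fst = fit = np.nan
    return FStatistics(per_locus, float(fis), float(fst), float(fit))


# -- allelic richness --------------------------------------------------------

def allelic_richness(
    gm: GenotypeMatrix,
    groups: np.ndarray | pd.Series | list,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Bootstrap allelic richness per group, standardised to the smallest
    group's size.

    Each group is resampled with replacement at the minimum group size
    ``n_boot`` times; A_R for a resample is the mean number of distinct
    alleles per locus, and the 95% CI is the percentile interval over
    resamples.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = pd.Series(list(groups), index=gm.ids)
    sizes = groups.value_counts()
    m = int(sizes.min())
    out = []
    for g in sizes.index:
        idx = np.flatnonzero((groups == g).to_numpy())
        draws = rng.choice(idx, size=(n_boot, m), replace=True)
        per_locus = np.zeros((n_boot, gm.n_loci))
        sentinel = np.iinfo(np.int64).max
        for j in range(gm.n_loci):
            al = gm.alleles[:, j, :].copy()
            al[al == MISSING] = sentinel
            d = al[draws].reshape(n_boot, 2 * m)
            d.sort(axis=1)
            valid = d < sentinel
            distinct = ((d[:, 1:] != d[:, :-1]) & valid[:, 1:]).sum(1) + valid[:, 0]
            per_locus[:, j] = distinct
        ar = per_locus.mean(axis=1)
        lo, hi = np.percentile(ar, [2.5, 97.5])
        out.append({"group": g, "A_R": float(ar.mean()),
                    "ci_low": float(lo), "ci_high": float(hi)})
    return pd.DataFrame(out).set_index("group")


# -- Wahlund regression ------------------------------------------------------

@dataclass
class WahlundRegression:
    r: float
    p: float
    slope: float
    intercept: float
    n_loci: int


def wahlund_regression(
    fis: np.ndarray | pd.Series, fst: np.ndarray | pd.Series
) -> WahlundRegression:
    """Across-locus correlation and OLS of F_IS on F_ST.

    A significantly positive relationship indicates a Wahlund effect:
    pooled, differentiated subpopulations inflate homozygosity most at the
    loci that differentiate them most.
    """
    fis = np.asarray(pd.Series(fis), dtype=float)
    fst = np.asarray(pd.Series(fst), dtype=float)
    ok = np.isfinite(fis) & np.isfinite(fst)
    fis, fst = fis[ok], fst[ok]
    if len(fis) < 3:
        raise ParameterError("need >= 3 loci with both statistics")
    if np.allclose(fst, fst[0]):
        return WahlundRegression(np.nan, np.nan, np.nan, np.nan, len(fis))
    r, p = stats.pearsonr(fst, fis)
    res = stats.linregress(fst, fis)
    return WahlundRegression(float(r), float(p), float(res.slope),
                             float(res.intercept), len(fis))


# -- bootstrap CI for F_IS ---------------------------------------------------

def fis_bootstrap_ci(
    gm: GenotypeMatrix,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Multilocus F_IS with a bias-corrected bootstrap-over-loci 95% CI.

    Loci are resampled with replacement; each replicate's F_IS is the ratio
    of its summed variance components.  Returns (point, low, high); with a
    single locus the point estimate is returned with a NaN interval and a
    warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comps = []
    for j in range(gm.n_loci):
        al = gm.alleles[:, j]
        typed = al[:, 0] != MISSING
        if typed.sum() < 2 or len(np.unique(al[typed])) < 2:
            continue
        _, B, C = _wc_components(al[typed], np.zeros(int(typed.sum()), dtype=int))
        comps.append((B, C))
    if not comps:
        raise ParameterError("no polymorphic locus available")
    comps = np.array(comps)
    point = 1 - comps[:, 1].sum() / comps.sum()
    if len(comps) < 2:
        warnings.warn("single locus: no bootstrap interval")
        return float(point), np.nan, np.nan
    L = len(comps)
    draws = rng.integers(0, L, size=(n_boot, L))
    bs = comps[draws]                      # (n_boot, L, 2)
    tot = bs.sum(axis=(1, 2))
    boot = 1 - bs[:, :, 1].sum(axis=1) / tot
    boot = boot[np.isfinite(boot)]
    # bias-corrected percentile interval
    prop = np.clip(np.mean(boot < point), 1.0 / len(boot), 1 - 1.0 / len(boot))
    z0 = ndtri(prop)
    zlo, zhi = ndtri(alpha / 2), ndtri(1 - alpha / 2)
    lo_q, hi_q = ndtr(2 * z0 + zlo), ndtr(2 * z0 + zhi)
    lo, hi = np.quantile(boot, [lo_q, hi_q])
    return float(point), float(lo), float(hi)


# -- parametric differentiation ----------------------------------------------

def parametric_fst(
    t1: AlleleFrequencyTable, t2: AlleleFrequencyTable
) -> tuple[pd.Series, float]:
    """Per-locus and mean Nei differentiation (G_ST) between two frequency
    tables, computed from the frequencies themselves (no sampling noise).
    Used to characterise simulated parental pools."""
    if t1.loci != t2.loci:
        raise ParameterError("tables must share loci")
    vals = {}
    for loc in t1.loci:
        a1, p1 = t1.alleles[loc], t1.freqs[loc]
        a2, p2 = t2.alleles[loc], t2.freqs[loc]
        allele_set = np.union1d(a1, a2)
        v1 = np.array([t1.frequency(loc, a) for a in allele_set])
        v2 = np.array([t2.frequency(loc, a) for a in allele_set])
        hs = 1 - 0.5 * (np.sum(v1**2) + np.sum(v2**2))
        pbar = (v1 + v2) / 2
        ht = 1 - np.sum(pbar**2)
        vals[loc] = np.nan if ht == 0 else (ht - hs) / ht
    series = pd.Series(vals, name="fst")
    return series, float(series.dropna().mean())


# -- tidy summary ------------------------------------------------------------

def popgen_summary(
    gm: GenotypeMatrix,
    groups: np.ndarray | pd.Series | list | None = None,
    n_mc: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Tidy per-group, per-locus table: n, H_O, H_E, F_IS and HWE p-value."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if groups is None:
        groups = ["all"] * gm.n_individuals
    groups = pd.Series(list(groups), index=gm.ids)
    frames = []
    for g in dict.fromkeys(groups):
        ids = list(groups.index[groups == g])
        sub = gm.subset(ids=ids)
        het = heterozygosity(sub)
        fstat = f_statistics(sub)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps = {loc: (hwe_exact_test(sub, loc, n_mc=n_mc, seed=rng)
                        if het.loc[loc, "n"] >= 2 else np.nan)
                  for loc in sub.loci}
        df = het.copy()
        df["F_IS"] = fstat.per_locus["F_IS"]
        df["hwe_p"] = pd.Series(ps)
        df.insert(0, "group", g)
        frames.append(df.reset_index())
    return pd.concat(frames, ignore_index=True)
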