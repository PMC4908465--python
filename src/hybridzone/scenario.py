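"""Scenario testing for a two-species hybrid zone.

Given region totals and their observed mean red-wolf ancestry, each
hybridization scenario (a hypothesised proportion of hybrids among the
individuals of the core region) is converted into an explicit composition —
how many red wolves, coyotes and hybrids of each class must be present for
the simulated data to reproduce the observed mean ancestry, with every
hybrid contributing ancestry 0.5.  In the core (hybrid-zone) region the
balance is ``q_bar * T = 0.5 * H + R``; in peripheral regions the small
residual ancestry is attributed to hybrids when the scenario allows them,
and to red wolves otherwise.

The composition is then realised as simulated genotypes, pushed through the
same admixture analysis as the empirical data, and compared with the
empirical q distribution via a two-sample Kolmogorov–Smirnov test and the
steepness of a logistic curve fitted to the sorted q values
(y = a / (1 + exp(-c (x - b))) with x the 1-based rank).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .admixture import align_runs, anchor_clusters, run_admixture_replicates
from .core import AlleleFrequencyTable, GenotypeMatrix, ParameterError
from .hybridsim import HybridClass, simulate_class

__all__ = [
    "RegionSpec",
    "ScenarioComposition",
    "LogisticFit",
    "solve_composition",
    "build_scenario_dataset",
    "classify_ancestry",
    "hybrid_percentage",
    "zone_summary",
    "ZoneSummary",
    "ks_compare",
    "fit_logistic",
    "run_scenario_comparison",
]

#: Order in which the remainder of the four-way hybrid split is assigned.
_HYBRID_ORDER = (HybridClass.F1, HybridClass.BC1, HybridClass.BC2, HybridClass.F2)


@dataclass
class RegionSpec:
    """A region's total detected individuals and observed mean ancestry.

    ``core=True`` marks the hybrid zone proper, where the scenario's hybrid
    proportion applies; peripheral regions (``core=False``) carry only the
    residual ancestry implied by their own mean.
    """

    label: str
    total: int
    mean_ancestry: float
    core: bool = True

    def __post_init__(self) -> None:
        if self.total < 0:
            raise ParameterError("region total must be >= 0")
        if not 0.0 <= self.mean_ancestry <= 1.0:
            raise ParameterError("mean ancestry must be in [0, 1]")


@dataclass
class ScenarioComposition:
    """Counts of parentals and hybrid classes satisfying a scenario."""

    label: str
    hybrid_proportion: float
    red_wolves: int
    coyotes: int
    hybrids: dict[HybridClass, int]
    per_region: pd.DataFrame  # rows: region; columns R, C, H

    @property
    def total(self) -> int:
        return self.red_wolves + self.coyotes + sum(self.hybrids.values())

    @property
    def total_hybrids(self) -> int:
        return sum(self.hybrids.values())

    def counts(self) -> dict[HybridClass, int]:
        out = {HybridClass.P1: self.red_wolves, HybridClass.P2: self.coyotes}
        out.update(self.hybrids)
        return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _split_hybrids(total: int) -> dict[HybridClass, int]:
    """Split a hybrid total as evenly as possible over the four classes,
    assigning the remainder in the fixed order F1, BC-wolf, BC-coyote, F2."""
    base, rem = divmod(total, 4)
    out = {c: base for c in (HybridClass.F1, HybridClass.F2,
                             HybridClass.BC1, HybridClass.BC2)}
    for c in _HYBRID_ORDER[:rem]:
        out[c] += 1
    return out


def solve_composition(
    regions: list[RegionSpec],
    hybrid_proportion: float,
    hybrid_mean_ancestry: float = 0.5,
    label: str = "scenario",
) -> ScenarioComposition:
    """Solve a scenario's composition from region totals and mean ancestries.

    For each core region, the hybrid count is ``round(p_h * T)`` and the
    red-wolf count follows from the ancestry balance
    ``q_bar * T = hybrid_mean_ancestry * H + R``; coyotes are the remainder.
    Peripheral regions attribute their ancestry entirely to hybrids when the
    scenario includes hybridization (``p_h > 0``) and to red wolves when it
    does not.  All rounding is half-up.  An infeasible region (negative
    implied wolves or coyotes) raises a :class:`ParameterError` naming it.
    """
    if not 0.0 <= hybrid_proportion <= 1.0:
        raise ParameterError("hybrid proportion must be in [0, 1]")
    if not regions:
        raise ParameterError("need >= 1 region")
    rows = []
    for reg in regions:
        T, qbar = reg.total, reg.mean_ancestry
        if reg.core:
            H = _round_half_up(hybrid_proportion * T)
            R = _round_half_up(qbar * T - hybrid_mean_ancestry * H)
            C = T - H - R
        elif hybrid_proportion > 0:
            H = _round_half_up(qbar * T / hybrid_mean_ancestry)
            R = 0
            C = T - H
        else:
            H = 0
            R = _round_half_up(qbar * T)
            C = T - R
        if R < 0 or C < 0 or H < 0:
            raise ParameterError(
                f"infeasible composition in region {reg.label!r}: "
                f"R={R}, C={C}, H={H}"
            )
        rows.append({"region": reg.label, "red_wolves": R, "coyotes": C,
                     "hybrids": H})
    per_region = pd.DataFrame(rows).set_index("region")
    return ScenarioComposition(
        label=label,
        hybrid_proportion=hybrid_proportion,
        red_wolves=int(per_region["red_wolves"].sum()),
        coyotes=int(per_region["coyotes"].sum()),
        hybrids=_split_hybrids(int(per_region["hybrids"].sum())),
        per_region=per_region,
    )


def build_scenario_dataset(
    comp: ScenarioComposition,
    p1_pool: AlleleFrequencyTable,
    p2_pool: AlleleFrequencyTable,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Simulate the genotypes of one scenario composition.

    Each class is generated by the gamete-based hybrid simulator with the
    composition's counts; ``true_class`` labels travel in the metadata.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parts = []
    for cls, n in comp.counts().items():
        if n > 0:
            parts.append(simulate_class(p1_pool, p2_pool, cls, n, rng,
                                        id_prefix=f"{comp.label}_{cls.value}"))
    if not parts:
        raise ParameterError(f"scenario {comp.label!r} has no individuals")
    return GenotypeMatrix.concat(parts)


# -- classification ----------------------------------------------------------

def classify_ancestry(
    q: np.ndarray | pd.Series | list,
    wolf_threshold: float = 0.875,
    coyote_threshold: float = 0.125,
) -> np.ndarray:
    """Label individuals red wolf / hybrid / coyote from red-wolf ancestry.

    q >= ``wolf_threshold`` is a red wolf, q < ``coyote_threshold`` a
    coyote, anything between a hybrid.  The defaults match the management
    thresholds equivalent to two generations of backcrossing.
    """
    if not coyote_threshold < wolf_threshold:
        raise ParameterError("coyote threshold must be below wolf threshold")
    q = np.asarray(pd.Series(q), dtype=float)
    if ((q < 0) | (q > 1)).any() or not np.isfinite(q).all():
        raise ParameterError("q values must lie in [0, 1]")
    out = np.full(q.shape, "hybrid", dtype=object)
    out[q >= wolf_threshold] = "red wolf"
    out[q < coyote_threshold] = "coyote"
    return out


def hybrid_percentage(labels: np.ndarray | list) -> float:
    """Percentage of hybrid labels, to two decimals."""
    labels = list(labels)
    if not labels:
        raise ParameterError("no labels")
    return round(100.0 * sum(1 for l in labels if l == "hybrid") / len(labels), 2)


# -- zone summaries ----------------------------------------------------------

@dataclass
class ZoneSummary:
    """Per-zone ancestry means with ANOVA, LSD letter groups and the
    hybrid-distribution chi-square test."""

    table: pd.DataFrame          # per zone: n, mean_q, ci_low, ci_high, letters
    anova_f: float
    anova_p: float
    chi2: float
    chi2_p: float
    chi2_p_mc: float | None = None
    excluded_zones: list[str] = field(default_factory=list)


def _lsd_letters(means: pd.Series, ns: pd.Series, mse: float, df: int,
                 alpha: float = 0.05) -> pd.Series:
    """Letter display from Fisher's LSD pairwise t-tests.

    Zones are scanned in descending mean order; a greedy left-to-right pass
    groups runs of zones whose pairwise differences are all non-significant.
    """
    order = means.sort_values(ascending=False).index.to_list()
    k = len(order)

    def differ(a: str, b: str) -> bool:
        se = math.sqrt(mse * (1 / ns[a] + 1 / ns[b]))
        if se == 0:
            return means[a] != means[b]
        t = abs(means[a] - means[b]) / se
        return 2 * stats.t.sf(t, df) < alpha

    groups: list[tuple[int, int]] = []   # inclusive index ranges in `order`
    start = 0
    while start < k:
        end = start
        while end + 1 < k and all(not differ(order[i], order[end + 1])
                                  for i in range(start, end + 1)):
            end += 1
        groups.append((start, end))
        # next group starts at the first zone that differs from `start`
        nxt = start + 1
        while nxt < k and not differ(order[start], order[nxt]):
            nxt += 1
        if nxt <= end and (start, end) != (nxt, k - 1):
            start = nxt
        else:
            start = end + 1
    letters = {z: "" for z in order}
    for gi, (s, e) in enumerate(groups):
        ch = chr(ord("a") + gi)
        for i in range(s, e + 1):
            letters[order[i]] += ch
    return pd.Series(letters)


def zone_summary(
    q: np.ndarray | pd.Series | list,
    zones: np.ndarray | pd.Series | list,
    alpha: float = 0.05,
    wolf_threshold: float = 0.875,
    coyote_threshold: float = 0.125,
    mc_reps: int = 10000,
    seed: int | np.random.Generator = 0,
) -> ZoneSummary:
    """Mean ancestry per zone with a one-way ANOVA, Fisher's LSD letter
    groups and a chi-square test of equal hybrid counts across zones.

    Zone confidence intervals are t-based on the pooled ANOVA mean square,
    Bonferroni-corrected across zones.  Zones with fewer than two
    individuals are excluded from the ANOVA (with the exclusion reported)
    but still summarised.  The chi-square test compares the observed
    distribution of classified hybrids across zones to equal expected
    counts, with both the asymptotic p-value and a Monte-Carlo version
    (useful when hybrid counts are small).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df_in = pd.DataFrame({"q": pd.Series(q).to_numpy(dtype=float),
                          "zone": pd.Series(zones).to_numpy()})
    zone_order = list(dict.fromkeys(df_in["zone"]))
    sizes = df_in.groupby("zone")["q"].size()
    small = [z for z in zone_order if sizes[z] < 2]
    work = df_in[~df_in["zone"].isin(small)]
    if work["zone"].nunique() < 2:
        raise ParameterError("need >= 2 zones with >= 2 individuals for ANOVA")

    grand = work["q"].mean()
    grp = work.groupby("zone")["q"]
    means, ns = grp.mean(), grp.size()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((work["q"] - work["zone"].map(means)) ** 2).sum())
    df_b = work["zone"].nunique() - 1
    df_w = len(work) - work["zone"].nunique()
    mse = ss_within / df_w if df_w > 0 else np.nan
    if mse > 0:
        f = (ss_between / df_b) / mse
        p = float(stats.f.sf(f, df_b, df_w))
        letters = _lsd_letters(means, ns, mse, df_w, alpha)
    else:
        f, p = np.nan, np.nan
        letters = pd.Series("a", index=means.index)

    tcrit = stats.t.ppf(1 - alpha / (2 * len(means)), df_w) if mse > 0 else np.nan
    rows = []
    for z in zone_order:
        n = int(sizes[z])
        m = float(df_in.loc[df_in["zone"] == z, "q"].mean())
        if z in means.index and mse > 0:
            half = tcrit * math.sqrt(mse / n)
            lo, hi = m - half, m + half
            let = letters[z]
        else:
            lo = hi = np.nan
            let = ""
        rows.append({"zone": z, "n": n, "mean_q": m,
                     "ci_low": lo, "ci_high": hi, "letters": let})
    table = pd.DataFrame(rows).set_index("zone")

    labels = classify_ancestry(df_in["q"], wolf_threshold, coyote_threshold)
    hyb = pd.Series(labels == "hybrid").groupby(df_in["zone"].to_numpy()).sum()
    obs = np.array([int(hyb.get(z, 0)) for z in zone_order])
    nh = int(obs.sum())
    if nh > 0:
        chi2, chi2_p = stats.chisquare(obs)
        mc = rng.multinomial(nh, np.full(len(obs), 1 / len(obs)), size=mc_reps)
        exp = nh / len(obs)
        mc_stat = ((mc - exp) ** 2 / exp).sum(axis=1)
        chi2_p_mc = float((np.sum(mc_stat >= chi2 - 1e-12) + 1) / (mc_reps + 1))
    else:
        chi2, chi2_p, chi2_p_mc = np.nan, np.nan, None
    return ZoneSummary(table, float(f), float(p), float(chi2), float(chi2_p),
                       chi2_p_mc, small)


# -- distribution comparison -------------------------------------------------

def ks_compare(
    q_empirical: np.ndarray | list, q_scenario: np.ndarray | list
) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov comparison of q distributions.

    D is the supremum distance between the two empirical CDFs (evaluated at
    all pooled points, so ties are handled exactly); the p-value is the
    asymptotic one.
    """
    x = np.asarray(q_empirical, dtype=float)
    y = np.asarray(q_scenario, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class LogisticFit:
    """Parameters of y = a / (1 + exp(-c (x - b))) fitted to sorted q values
    against their 1-based rank."""

    a: float
    b: float
    c: float
    converged: bool
    rss: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _logistic(np.asarray(x, float), self.a, self.b, self.c)


def _logistic(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    # exponent clipped so extreme steepness saturates instead of overflowing
    return a / (1.0 + np.exp(np.clip(-c * (x - b), -500.0, 500.0)))


def fit_logistic(q: np.ndarray | list, max_iter: int = 10000) -> LogisticFit:
    """Fit the three-parameter logistic to the sorted-q curve.

    The q values are sorted ascending and regressed on their rank
    1..N by nonlinear least squares.  The steepness c is large for a
    bimodal (parental-dominated) distribution, where the curve jumps from
    coyote-like to wolf-like q over few individuals, and small when
    intermediate (hybrid) values are abundant.  Initialisation:
    a0 = max(y), b0 = N/2, c0 = 4 * (y_(3N/4) - y_(N/4)) / (N/2).
    Non-convergence returns the best parameters found, flagged.
    """
    y = np.sort(np.asarray(q, dtype=float))
    n = y.size
    if n < 4:
        raise ParameterError("need >= 4 values to fit the logistic")
    x = np.arange(1, n + 1, dtype=float)
    a0 = float(y.max())
    b0 = n / 2.0
    q3, q1 = y[math.ceil(3 * n / 4) - 1], y[math.ceil(n / 4) - 1]
    c0 = 4.0 * (q3 - q1) / (n / 2.0)
    if not np.isfinite(c0) or c0 <= 0:
        c0 = 1e-3

    def resid(theta):
        a, b, c = theta
        return _logistic(x, a, b, c) - y

    sol = optimize.least_squares(resid, x0=[a0 if a0 > 0 else 1.0, b0, c0],
                                 max_nfev=max_iter, method="lm")
    a, b, c = sol.x
    rss = float(np.sum(sol.fun**2))
    return LogisticFit(float(a), float(b), float(c), bool(sol.success), rss)


# -- orchestration -----------------------------------------------------------

def run_scenario_comparison(
    q_empirical: np.ndarray | list,
    scenarios: list[tuple[str, float]] | dict[str, float],
    regions: list[RegionSpec],
    p1_pool: AlleleFrequencyTable,
    p2_pool: AlleleFrequencyTable,
    runs: int = 10,
    seed: int = 0,
    burnin: int = 5000,
    reps: int = 50000,
    model: str = "correlated",
    n_anchor: int = 10,
    hybrid_mean_ancestry: float = 0.5,
) -> pd.DataFrame:
    """Full scenario comparison against an empirical q distribution.

    For every scenario (label, hybrid proportion): solve the composition,
    simulate its genotypes, estimate admixture at K = 2 (``runs`` replicate
    chains, composited and anchored with simulated known parentals), then
    compare the composite q values with the empirical ones via the K-S test
    and the fitted logistic steepness.  Returns one row per scenario; a
    scenario that fails leaves a row with its error message, preserving the
    others.
    """
    if isinstance(scenarios, dict):
        scenarios = list(scenarios.items())
    q_empirical = np.asarray(q_empirical, dtype=float)
    seeds = np.random.SeedSequence(seed).spawn(len(scenarios))
    emp_fit = fit_logistic(q_empirical)
    rows = []
    for (label, p_h), ss in zip(scenarios, seeds):
        row: dict[str, object] = {"scenario": label, "hybrid_proportion": p_h}
        try:
            comp = solve_composition(regions, p_h, hybrid_mean_ancestry, label)
            rng = np.random.default_rng(ss)
            data = build_scenario_dataset(comp, p1_pool, p2_pool, rng)
            # anchor with extra simulated known parentals appended to the run
            anchors = GenotypeMatrix.concat([
                simulate_class(p1_pool, p2_pool, HybridClass.P1, n_anchor, rng,
                               id_prefix="known_wolf"),
                simulate_class(p1_pool, p2_pool, HybridClass.P2, n_anchor, rng,
                               id_prefix="known_coyote"),
            ])
            full = GenotypeMatrix.concat([data, anchors])
            results = run_admixture_replicates(
                full, K=2, n_runs=runs, seed=int(rng.integers(2**31 - 1)),
                model=model, burnin=burnin, reps=reps,
            )
            composite = align_runs(results)
            known = {i: "red wolf" for i in anchors.ids if i.startswith("known_wolf")}
            known.update({i: "coyote" for i in anchors.ids
                          if i.startswith("known_coyote")})
            composite = anchor_clusters(composite, known, strict=False)
            keep = [i in data.ids for i in composite.ids]
            q_sim = composite.q[np.array(keep), 0]
            d, p = ks_compare(q_empirical, q_sim)
            fit = fit_logistic(q_sim)
            row.update({
                "red_wolves": comp.red_wolves, "coyotes": comp.coyotes,
                "hybrids": comp.total_hybrids, "n": comp.total,
                "ks_d": d, "ks_p": p,
                "logistic_a": fit.a, "logistic_b": fit.b, "logistic_c": fit.c,
                "logistic_converged": fit.converged,
                "mean_q": float(q_sim.mean()),
            })
        except Exception as exc:  # keep partial results per scenario
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    out = pd.DataFrame(rows).set_index("scenario")
    out.attrs["empirical_logistic_c"] = emp_fit.c
    return out
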