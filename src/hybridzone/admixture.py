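"""Bayesian admixture estimation for multilocus genotypes.

A Gibbs sampler over the classic no-prior-population admixture model: each
of an individual's allele copies originates from one of K clusters, with
individual-specific mixing proportions q drawn from a symmetric Dirichlet
whose concentration alpha is itself sampled by Metropolis.  Cluster allele
frequencies follow either the uncorrelated model (independent Dirichlet per
cluster) or the correlated model, in which cluster frequencies drift around
a shared ancestral vector with per-cluster drift parameters F_k — the usual
choice for recently diverged taxa such as red wolves and coyotes.

The module also provides the supporting machinery of a complete admixture
analysis: replicate runs, label alignment and compositing across runs, the
second-difference (Evanno) ΔK criterion for choosing K, and anchoring of
clusters to species through individuals of known origin.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .core import MISSING, GenotypeMatrix, ParameterError

__all__ = [
    "AncestryResult",
    "DeltaKTable",
    "AnchoringError",
    "run_admixture",
    "run_admixture_replicates",
    "align_runs",
    "evanno_deltaK",
    "anchor_clusters",
]


class AnchoringError(ValueError):
    """Known-origin individuals contradict the inferred cluster labels."""


@dataclass
class AncestryResult:
    """Posterior admixture proportions for one run (or a composite).

    ``q`` has shape (n_individuals, K) and rows sum to one; ``ci_low`` and
    ``ci_high`` are the bounds of the equal-tailed 90% posterior interval,
    widened if necessary to bracket the posterior mean.  ``ln_prob`` is the
    model log-probability estimate mean(logL) - var(logL)/2 over post
    burn-in sweeps, comparable across K for the ΔK criterion.
    """

    ids: list[str]
    K: int
    q: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    ln_prob: float
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.ids), self.K):
            raise ParameterError("q shape does not match ids x K")
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-6):
            raise ParameterError("q rows must sum to 1")

    def to_dataframe(self) -> pd.DataFrame:
        cols = {}
        for k in range(self.K):
            cols[f"q{k + 1}"] = self.q[:, k]
            cols[f"q{k + 1}_lo"] = self.ci_low[:, k]
            cols[f"q{k + 1}_hi"] = self.ci_high[:, k]
        return pd.DataFrame(cols, index=pd.Index(self.ids, name="id"))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def write_runlog(self, path) -> None:
        log = dict(self.settings)
        log.update({"K": self.K, "ln_prob": self.ln_prob,
                    "n_individuals": len(self.ids)})
        with open(path, "w") as fh:
            json.dump(log, fh, indent=2, default=str)

    @property
    def wolf_q(self) -> np.ndarray:
        """Ancestry toward cluster 1 (the red-wolf cluster once anchored)."""
        return self.q[:, 0]


# -- the Gibbs sampler -------------------------------------------------------

def _encode(gm: GenotypeMatrix):
    """Integer-code alleles per locus.  Returns per-locus registries, the
    (n, L, 2) code array (-1 missing) and the per-locus allele counts."""
    L = gm.n_loci
    registries, codes = [], np.full(gm.alleles.shape, -1, dtype=np.int64)
    for j in range(L):
        a = gm.alleles[:, j]
        typed = a[:, 0] != MISSING
        reg = np.unique(a[typed])
        registries.append(reg)
        if reg.size:
            codes[typed, j, :] = np.searchsorted(reg, a[typed])
    return registries, codes


def _dirichlet_rows(rng: np.random.Generator, conc: np.ndarray,
                    valid: np.ndarray) -> np.ndarray:
    """Row-wise Dirichlet draws over the valid positions of ``conc`` (last
    axis), zeros elsewhere."""
    g = rng.gamma(np.where(valid, np.maximum(conc, 1e-12), 0.0))
    g *= valid
    s = g.sum(axis=-1, keepdims=True)
    # a fully underflowed row collapses onto its largest concentration
    bad = (s == 0.0) & valid.any(axis=-1, keepdims=True)
    if bad.any():
        idx = np.argmax(np.where(valid, conc, -1.0), axis=-1)
        g[np.nonzero(bad[..., 0]) + (idx[bad[..., 0]],)] = 1.0
        s = g.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        out = g / s
    return np.where(valid, np.nan_to_num(out), 0.0)


def _log_dirichlet(P: np.ndarray, conc: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Log Dirichlet density per row (last axis holds allele categories)."""
    c = np.where(valid, np.maximum(conc, 1e-12), 1.0)
    logp = np.log(np.clip(P, 1e-300, None))
    terms = np.where(valid, (c - 1.0) * logp - gammaln(c), 0.0)
    return gammaln(np.where(valid, c, 0.0).sum(axis=-1)) + terms.sum(axis=-1)


def _log_dirichlet_fast(logP: np.ndarray, conc: np.ndarray,
                        valid: np.ndarray) -> np.ndarray:
    """As :func:`_log_dirichlet` but taking precomputed clipped log(P)."""
    c = np.where(valid, np.maximum(conc, 1e-12), 1.0)
    terms = np.where(valid, (c - 1.0) * logP - gammaln(c), 0.0)
    return gammaln(np.where(valid, c, 0.0).sum(axis=-1)) + terms.sum(axis=-1)


def run_admixture(
    gm: GenotypeMatrix,
    K: int,
    model: str = "correlated",
    burnin: int = 5000,
    reps: int = 50000,
    thin: int = 10,
    lambda_: float = 1.0,
    alpha0: float = 1.0,
    alpha_step: float = 0.1,
    alpha_max: float = 10.0,
    f_init: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> AncestryResult:
    """One MCMC run of the admixture model.

    Parameters
    ----------
    gm
        Genotypes; every individual must be typed at >= 1 locus.  Missing
        loci contribute nothing to the likelihood.
    K
        Number of clusters (>= 1).
    model
        ``"correlated"`` (cluster frequencies drift around an ancestral
        vector, default) or ``"uncorrelated"`` (independent
        Dirichlet(lambda) priors).
    burnin, reps, thin
        ``burnin`` discarded sweeps followed by ``reps`` retained sweeps, of
        which every ``thin``-th contributes to the posterior summaries.
    alpha0, alpha_step, alpha_max
        The symmetric Dirichlet hyperparameter alpha (one value shared by
        all clusters) starts at ``alpha0`` and is updated by Metropolis on
        log-alpha with normal step ``alpha_step`` under a uniform
        (0, alpha_max) prior.
    """
    if K < 1:
        raise ParameterError("K must be >= 1")
    if K > gm.n_individuals:
        raise ParameterError("K cannot exceed the number of individuals")
    if model not in ("correlated", "uncorrelated"):
        raise ParameterError(f"unknown frequency model {model!r}")
    if not (reps > burnin >= 0):
        raise ParameterError("need reps > burnin >= 0")
    if not gm.typed.any(axis=1).all():
        bad = [i for i, ok in zip(gm.ids, gm.typed.any(axis=1)) if not ok]
        raise ParameterError(f"individuals with no typed locus: {bad}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    N, L = gm.n_individuals, gm.n_loci
    registries, codes = _encode(gm)
    A = max(r.size for r in registries)
    valid = np.zeros((L, A), dtype=bool)
    for j, r in enumerate(registries):
        valid[j, : r.size] = True

    # flatten to the typed allele copies only
    ok = (codes >= 0)
    locus_of = np.broadcast_to(np.arange(L)[None, :, None], codes.shape)
    flat_idx = (locus_of * A + np.where(ok, codes, 0)).ravel()[ok.ravel()]
    ind_idx = np.broadcast_to(np.arange(N)[:, None, None],
                              codes.shape).ravel()[ok.ravel()]
    M = flat_idx.size
    nik_idx = ind_idx * K       # precomputed offsets for the q-count bincount
    cnt_base = flat_idx.copy()

    # observed overall allele counts, for initialisation
    obs_counts = np.bincount(flat_idx, minlength=L * A).reshape(L, A).astype(float)

    # state
    q = rng.dirichlet(np.ones(K), size=N)
    qT = np.ascontiguousarray(q.T)
    P = _dirichlet_rows(rng, np.broadcast_to(obs_counts + 1.0, (K, L, A)),
                        np.broadcast_to(valid, (K, L, A)))
    alpha = float(alpha0)
    if model == "correlated":
        PA = _dirichlet_rows(rng, obs_counts + 1.0, valid)
        F = np.full(K, f_init)

    n_sweeps = burnin + reps
    n_keep = reps // thin
    q_samples = np.empty((n_keep, N, K))
    logliks = np.empty(reps)
    kept = 0
    alpha_acc = 0
    conc_prop = 100.0           # Dirichlet proposal concentration for PA

    validK = np.broadcast_to(valid, (K, L, A))
    old_err = np.seterr(divide="ignore", invalid="ignore")
    try:
        for sweep in range(n_sweeps):
            # -- Z: cluster of origin of each typed allele copy
            Pg = P.reshape(K, L * A).take(flat_idx, axis=1)   # (K, M)
            w = qT.take(ind_idx, axis=1)
            w *= Pg
            if K == 2:
                tot = w[0] + w[1]
                Z = (rng.random(M) * tot >= w[0]).view(np.int8).astype(np.int64)
            elif K == 1:
                tot = w[0]
                Z = np.zeros(M, dtype=np.int64)
            else:
                cum = np.cumsum(w, axis=0)
                tot = cum[-1]
                Z = (cum < rng.random(M) * tot).sum(axis=0)
                np.clip(Z, 0, K - 1, out=Z)

            post = sweep >= burnin
            if post:
                logliks[sweep - burnin] = np.log(tot).sum()

            # -- q | Z
            if K > 1:
                nik = np.bincount(nik_idx + Z, minlength=N * K).reshape(N, K)
                g = rng.gamma(alpha + nik)
                q = g / g.sum(axis=1, keepdims=True)
                qT = np.ascontiguousarray(q.T)

            # -- P | Z
            cnt = np.bincount(Z * (L * A) + cnt_base,
                              minlength=K * L * A).reshape(K, L, A)
            if model == "uncorrelated":
                P = _dirichlet_rows(rng, lambda_ + cnt, validK)
            else:
                concF = ((1.0 - F) / F)[:, None, None]
                P = _dirichlet_rows(rng, PA[None, :, :] * concF + cnt, validK)
                logP = np.log(np.clip(P, 1e-300, None))

                # -- ancestral frequencies: Metropolis, Dirichlet proposal
                PA_new = _dirichlet_rows(rng, PA * conc_prop, valid)
                d_cur = _log_dirichlet_fast(logP, PA[None] * concF, validK)
                d_new = _log_dirichlet_fast(logP, PA_new[None] * concF, validK)
                fwd = _log_dirichlet(PA_new, PA * conc_prop, valid)
                back = _log_dirichlet(PA, PA_new * conc_prop, valid)
                accept = (np.log(rng.random(L))
                          < d_new.sum(0) - d_cur.sum(0) + back - fwd)
                if accept.any():
                    PA[accept] = PA_new[accept]
                    d_cur[:, accept] = d_new[:, accept]

                # -- drift: Metropolis on log F, uniform(0, 1) prior
                F_new = F * np.exp(rng.normal(0.0, 0.1, size=K))
                inside = F_new < 1.0
                concF_new = ((1.0 - F_new) / F_new)[:, None, None]
                d_newF = _log_dirichlet_fast(logP, PA[None] * concF_new, validK)
                acc = inside & (np.log(rng.random(K))
                                < d_newF.sum(1) - d_cur.sum(1)
                                + np.log(F_new / F))
                F[acc] = F_new[acc]

            # -- alpha: Metropolis on log alpha
            if K > 1:
                a_new = alpha * float(np.exp(rng.normal(0.0, alpha_step)))
                if 0.0 < a_new < alpha_max:
                    slogq = float(np.log(np.clip(q, 1e-300, None)).sum())

                    def _lp(a: float) -> float:
                        return (N * (gammaln(K * a) - K * gammaln(a))
                                + (a - 1.0) * slogq)

                    if (np.log(rng.random())
                            < _lp(a_new) - _lp(alpha) + np.log(a_new / alpha)):
                        alpha = a_new
                        alpha_acc += 1

            if post and (sweep - burnin) % thin == 0 and kept < n_keep:
                q_samples[kept] = q
                kept += 1
    finally:
        np.seterr(**old_err)

    q_samples = q_samples[:kept]
    q_mean = q_samples.mean(axis=0)
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    ci_low = np.minimum(np.quantile(q_samples, 0.05, axis=0), q_mean)
    ci_high = np.maximum(np.quantile(q_samples, 0.95, axis=0), q_mean)
    ln_prob = float(logliks.mean() - logliks.var() / 2.0)

    settings = {
        "model": model, "burnin": burnin, "reps": reps, "thin": thin,
        "lambda": lambda_, "alpha_final": alpha,
        "alpha_acceptance": alpha_acc / max(1, n_sweeps),
    }
    if model == "correlated":
        settings["F_final"] = [float(f) for f in F]
    return AncestryResult(list(gm.ids), K, q_mean, ci_low, ci_high,
                          ln_prob, settings)


def run_admixture_replicates(
    gm: GenotypeMatrix,
    K: int,
    n_runs: int = 5,
    seed: int = 0,
    **kwargs,
) -> list[AncestryResult]:
    """Independent replicate runs differing only in their random seeds."""
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    out = []
    for i, ss in enumerate(seeds):
        res = run_admixture(gm, K, seed=np.random.default_rng(ss), **kwargs)
        res.settings["run"] = i + 1
        out.append(res)
    return out


# -- run alignment and compositing -------------------------------------------

def _best_permutation(ref: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Column permutation of ``q`` minimising the Frobenius distance to
    ``ref`` — solved exactly as a linear assignment on the cross products
    (equivalent to exhaustively scoring all K! label permutations)."""
    cost = -(ref.T @ q)
    _, cols = linear_sum_assignment(cost)
    return cols


def align_runs(results: Sequence[AncestryResult]) -> AncestryResult:
    """Composite ancestry over replicate runs after resolving label switching.

    Each run's cluster labels are permuted to best match the running mean of
    the previously aligned runs; the composite q (and intervals) are means
    over aligned runs and ``ln_prob`` is their average.
    """
    results = list(results)
    if not results:
        raise ParameterError("no runs to align")
    K = results[0].K
    ids = results[0].ids
    for r in results[1:]:
        if r.K != K or r.ids != ids:
            raise ParameterError("all runs must share K and the individual set")
    qs, los, his = [results[0].q], [results[0].ci_low], [results[0].ci_high]
    for r in results[1:]:
        ref = np.mean(qs, axis=0)
        perm = _best_permutation(ref, r.q)
        qs.append(r.q[:, perm])
        los.append(r.ci_low[:, perm])
        his.append(r.ci_high[:, perm])
    q = np.mean(qs, axis=0)
    q /= q.sum(axis=1, keepdims=True)
    lo = np.minimum(np.mean(los, axis=0), q)
    hi = np.maximum(np.mean(his, axis=0), q)
    ln = float(np.mean([r.ln_prob for r in results]))
    settings = {"composite_of": len(results),
                "runs": [r.settings for r in results]}
    return AncestryResult(ids, K, q, lo, hi, ln, settings)


# -- Evanno's delta-K --------------------------------------------------------

@dataclass
class DeltaKTable:
    """Mean and spread of the model log-probability per K plus ΔK.

    ΔK(K) = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)), defined for interior K
    with a positive between-run standard deviation.
    """

    table: pd.DataFrame
    best_k: int | None


def evanno_deltaK(runs_by_k: Mapping[int, Sequence[AncestryResult]]) -> DeltaKTable:
    """Choose K by the second-difference criterion on mean ln P(D)."""
    ks = sorted(runs_by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ParameterError("need >= 3 consecutive K values")
    for k in ks:
        if len(runs_by_k[k]) < 2:
            raise ParameterError(f"need >= 2 runs at K={k}")
    mean = {k: float(np.mean([r.ln_prob for r in runs_by_k[k]])) for k in ks}
    sd = {k: float(np.std([r.ln_prob for r in runs_by_k[k]], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        dk = np.nan
        if ks[0] < k < ks[-1]:
            if sd[k] > 0:
                dk = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1]) / sd[k]
            else:
                warnings.warn(f"zero run-to-run sd at K={k}; ΔK undefined there")
        rows.append({"K": k, "mean_ln_prob": mean[k], "sd_ln_prob": sd[k],
                     "delta_k": dk})
    df = pd.DataFrame(rows).set_index("K")
    defined = df["delta_k"].dropna()
    best = int(defined.idxmax()) if len(defined) else None
    return DeltaKTable(df, best)


# -- species anchoring -------------------------------------------------------

_WOLF = {"red wolf", "red_wolf", "wolf", "p1"}
_COYOTE = {"coyote", "p2"}


def anchor_clusters(
    result: AncestryResult,
    known: Mapping[str, str],
    strict: bool = True,
) -> AncestryResult:
    """Orient clusters so that cluster 1 is the red-wolf cluster.

    ``known`` maps individual ids to species labels ("red wolf"/"coyote").
    The cluster with the highest mean q among known red wolves becomes
    cluster 1 and the known coyotes' cluster becomes cluster 2.  Known
    individuals whose majority cluster contradicts their species raise an
    :class:`AnchoringError` listing the offenders (a warning instead when
    ``strict`` is false).  The anchoring confidence (mean q of the knowns in
    their species' cluster) is recorded in ``settings``.
    """
    wolves = [i for i, s in known.items() if s.lower() in _WOLF]
    coyotes = [i for i, s in known.items() if s.lower() in _COYOTE]
    if not wolves or not coyotes:
        raise ParameterError("need >= 1 known individual per species")
    idx = {i: n for n, i in enumerate(result.ids)}
    wi = [idx[i] for i in wolves]
    ci = [idx[i] for i in coyotes]
    wolf_k = int(np.argmax(result.q[wi].mean(axis=0)))
    coy_k = int(np.argmax(result.q[ci].mean(axis=0)))
    if wolf_k == coy_k:
        raise AnchoringError(
            "known red wolves and coyotes map to the same cluster"
        )
    offenders = [i for i in wolves if int(np.argmax(result.q[idx[i]])) != wolf_k]
    offenders += [i for i in coyotes if int(np.argmax(result.q[idx[i]])) != coy_k]
    if offenders:
        msg = f"known individuals contradict their species cluster: {offenders}"
        if strict:
            raise AnchoringError(msg)
        warnings.warn(msg)
    perm = [wolf_k, coy_k] + [k for k in range(result.K) if k not in (wolf_k, coy_k)]
    settings = dict(result.settings)
    settings["anchor_confidence"] = {
        "red wolf": float(result.q[wi, wolf_k].mean()),
        "coyote": float(result.q[ci, coy_k].mean()),
    }
    return AncestryResult(
        result.ids, result.K, result.q[:, perm], result.ci_low[:, perm],
        result.ci_high[:, perm], result.ln_prob, settings,
    )
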