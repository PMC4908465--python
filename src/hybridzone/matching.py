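"""Consensus genotyping, individual matching and identification power.

Noninvasive samples (scats) are genotyped through repeated PCRs; this module
turns those replicate observations into accepted consensus genotypes,
deduplicates samples into individuals by multilocus matching, and quantifies
the power of a locus panel to distinguish individuals via the probability of
identity for unrelated individuals (PID) and for full siblings (PID_sibs).

Acceptance rules for a consensus call follow the standard multiple-tubes
protocol: a heterozygote is accepted only when each of exactly two alleles
is seen in at least two independent PCRs, a homozygote only when its allele
is the sole allele seen in at least three.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, AlleleFrequencyTable, GenotypeMatrix, ParameterError

__all__ = [
    "MatchReport",
    "ConsensusResult",
    "RegroupResult",
    "call_consensus",
    "match_genotypes",
    "regroup_individuals",
    "compute_pid",
    "PidResult",
]


@dataclass
class MatchReport:
    """Outcome of comparing one query genotype against one reference."""

    query_id: str
    reference_id: str
    loci_compared: int
    mismatches: int
    verdict: str  # "match" | "no-match" | "ambiguous" | "no-comparison"


@dataclass
class ConsensusResult:
    genotypes: GenotypeMatrix
    accepted_loci: pd.Series          # accepted-locus count for every input sample
    excluded: dict[str, str]          # sample -> reason
    flagged: list[tuple[str, str]]    # (sample, locus) with >2 supported alleles


def _consensus_call(replicates: list[frozenset[int]]) -> tuple[int, int] | None | str:
    """Apply the replication rules to one sample x locus.

    Returns an allele pair, ``None`` for missing, or ``"flagged"`` when more
    than two alleles survive the two-observation support rule.
    """
    support: dict[int, int] = {}
    for rep in replicates:
        for a in rep:
            support[a] = support.get(a, 0) + 1
    candidates = sorted(a for a, s in support.items() if s >= 2)
    if len(candidates) == 2:
        return candidates[0], candidates[1]
    if len(candidates) == 1:
        a = candidates[0]
        solo = sum(1 for rep in replicates if rep == {a} or rep == frozenset({a}))
        if solo >= 3:
            return a, a
        return None
    if len(candidates) > 2:
        return "flagged"
    return None


def call_consensus(
    obs: pd.DataFrame,
    min_loci: int = 6,
    loci: list[str] | None = None,
) -> ConsensusResult:
    """Consensus genotypes from replicate-PCR observations.

    Parameters
    ----------
    obs
        Long-format table with columns ``sample``, ``locus``, ``replicate``
        and ``alleles`` (a set of allele labels per replicate; empty for a
        failed reaction).
    min_loci
        Samples with fewer accepted loci are excluded (default 6).
    loci
        Locus registry and ordering; defaults to order of first appearance.

    Samples with zero replicates are excluded with an explicit reason.
    """
    if min_loci < 1:
        raise ParameterError("min_loci must be >= 1")
    if loci is None:
        loci = list(dict.fromkeys(obs["locus"]))
    samples = list(dict.fromkeys(obs["sample"]))
    grouped: dict[tuple[str, str], list[frozenset[int]]] = {}
    for row in obs.itertuples(index=False):
        grouped.setdefault((row.sample, row.locus), []).append(frozenset(row.alleles))

    flagged: list[tuple[str, str]] = []
    excluded: dict[str, str] = {}
    counts: dict[str, int] = {}
    kept_ids: list[str] = []
    kept_alleles: list[np.ndarray] = []
    for s in samples:
        geno = np.full((len(loci), 2), MISSING, dtype=np.int64)
        n_rep = 0
        for j, loc in enumerate(loci):
            reps = grouped.get((s, loc), [])
            n_rep += len(reps)
            call = _consensus_call(reps)
            if call == "flagged":
                flagged.append((s, loc))
            elif call is not None:
                geno[j] = call
        accepted = int((geno[:, 0] != MISSING).sum())
        counts[s] = accepted
        if n_rep == 0:
            excluded[s] = "no replicates"
        elif accepted < min_loci:
            excluded[s] = f"only {accepted} accepted loci (< {min_loci})"
        else:
            kept_ids.append(s)
            kept_alleles.append(geno)
    alleles = (
        np.stack(kept_alleles)
        if kept_alleles
        else np.empty((0, len(loci), 2), dtype=np.int64)
    )
    gm = GenotypeMatrix(kept_ids, loci, alleles)
    return ConsensusResult(gm, pd.Series(counts, name="accepted_loci"), excluded, flagged)


# -- multilocus matching -----------------------------------------------------

def _pairwise_mismatch(
    query: GenotypeMatrix, reference: GenotypeMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """(overlap, mismatches) integer matrices of shape (n_query, n_ref),
    counting loci typed in both and loci whose allele pairs differ."""
    shared = [l for l in query.loci if l in reference.loci]
    if not shared:
        n, m = query.n_individuals, reference.n_individuals
        return np.zeros((n, m), int), np.zeros((n, m), int)
    qa = query.subset(loci=shared).alleles
    ra = reference.subset(loci=shared).alleles
    qt = qa[:, :, 0] != MISSING
    rt = ra[:, :, 0] != MISSING
    both = qt[:, None, :] & rt[None, :, :]
    differ = (qa[:, None, :, :] != ra[None, :, :, :]).any(axis=3)
    overlap = both.sum(axis=2)
    mism = (both & differ).sum(axis=2)
    return overlap, mism


def match_genotypes(
    query: GenotypeMatrix,
    reference: GenotypeMatrix,
    min_overlap: int = 6,
    max_mismatch: int = 0,
    only_matches: bool = False,
) -> list[MatchReport]:
    """Compare every query against every reference over jointly typed loci.

    A pair is a ``match`` when the overlap reaches ``min_overlap`` loci and
    the number of mismatching loci is at most ``max_mismatch`` (0 = exact
    matching on shared loci).  Queries matching more than one reference have
    those reports marked ``ambiguous``.  Disjoint locus panels produce
    ``no-comparison`` reports rather than an error.
    """
    if min_overlap < 1:
        raise ParameterError("min_overlap must be >= 1")
    if max_mismatch < 0:
        raise ParameterError("max_mismatch must be >= 0")
    overlap, mism = _pairwise_mismatch(query, reference)
    reports: list[MatchReport] = []
    is_match = (overlap >= min_overlap) & (mism <= max_mismatch)
    multi = is_match.sum(axis=1) > 1
    for i, q in enumerate(query.ids):
        for j, r in enumerate(reference.ids):
            if overlap[i, j] == 0:
                verdict = "no-comparison"
            elif is_match[i, j]:
                verdict = "ambiguous" if multi[i] else "match"
            else:
                verdict = "no-match"
            if only_matches and verdict not in ("match", "ambiguous"):
                continue
            reports.append(
                MatchReport(q, r, int(overlap[i, j]), int(mism[i, j]), verdict)
            )
    return reports


@dataclass
class RegroupResult:
    individuals: GenotypeMatrix   # one consensus genotype per individual
    metadata: pd.DataFrame        # centroid x, y, zone, n_detections, members
    ambiguous_groups: list[str] = field(default_factory=list)


def regroup_individuals(
    samples: GenotypeMatrix,
    min_overlap: int = 6,
    max_mismatch: int = 0,
    zone_intervals: list[tuple[str, float, float]] | None = None,
    zone_polygons: dict[str, object] | None = None,
) -> RegroupResult:
    """Collapse matching samples into unique individuals.

    The transitive closure of pairwise matches defines individuals; the
    result is invariant to input order (groups are named after their
    lexicographically smallest member).  Each individual's coordinate is the
    arithmetic mean of its samples' coordinates and its zone is looked up
    from that centroid (interval table in 1-D mode, polygons otherwise).
    Non-transitive groups (A~B, B~C but A!~C) are merged and flagged.
    """
    n = samples.n_individuals
    overlap, mism = _pairwise_mismatch(samples, samples)
    is_match = (overlap >= min_overlap) & (mism <= max_mismatch)

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if is_match[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    meta = samples.metadata
    ids_out, alleles_out, rows, ambiguous = [], [], [], []
    for members in groups.values():
        member_ids = sorted(samples.ids[i] for i in members)
        gid = member_ids[0]
        # pairwise-comparable members that mismatch mark the group ambiguous
        bad = any(
            overlap[i, j] >= min_overlap and mism[i, j] > max_mismatch
            for i in members
            for j in members
            if i < j
        )
        if bad:
            ambiguous.append(gid)
        idx = [samples.ids.index(m) for m in member_ids]
        sub = samples.alleles[idx]  # (m, L, 2)
        geno = np.full((samples.n_loci, 2), MISSING, dtype=np.int64)
        for l in range(samples.n_loci):
            calls = [tuple(sub[m, l]) for m in range(len(idx)) if sub[m, l, 0] != MISSING]
            if calls:
                # majority call, ties broken by smallest pair: order-invariant
                uniq = sorted(set(calls), key=lambda c: (-calls.count(c), c))
                geno[l] = uniq[0]
        ids_out.append(gid)
        alleles_out.append(geno)
        row = {"n_detections": len(member_ids), "members": ";".join(member_ids)}
        if meta is not None and {"x", "y"} <= set(meta.columns):
            row["x"] = float(meta.loc[member_ids, "x"].mean())
            row["y"] = float(meta.loc[member_ids, "y"].mean())
            row["zone"] = _assign_zone(row["x"], row["y"], zone_intervals, zone_polygons)
        rows.append(row)

    order = np.argsort(ids_out)
    ids_out = [ids_out[k] for k in order]
    alleles = (
        np.stack([alleles_out[k] for k in order])
        if ids_out
        else np.empty((0, samples.n_loci, 2), dtype=np.int64)
    )
    md = pd.DataFrame([rows[k] for k in order], index=ids_out)
    gm = GenotypeMatrix(ids_out, list(samples.loci), alleles, md)
    return RegroupResult(gm, md, sorted(ambiguous))


def _assign_zone(x, y, intervals, polygons):
    if polygons:
        from shapely.geometry import Point

        p = Point(x, y)
        for label, poly in polygons.items():
            if poly.contains(p) or poly.touches(p):
                return label
        return None
    if intervals:
        for label, lo, hi in intervals:
            if lo <= x < hi:
                return label
        return None
    return None


# -- probability of identity -------------------------------------------------

@dataclass
class PidResult:
    """Per-locus and cumulative probabilities of identity.

    ``table`` has one row per locus (in the requested order) with columns
    ``pid_unrelated``, ``pid_sibs`` and their running products
    ``cum_unrelated``, ``cum_sibs``.
    """

    table: pd.DataFrame

    @property
    def total_unrelated(self) -> float:
        return float(self.table["cum_unrelated"].iloc[-1])

    @property
    def total_sibs(self) -> float:
        return float(self.table["cum_sibs"].iloc[-1])


def compute_pid(
    freqs: AlleleFrequencyTable, loci_subset: list[str] | None = None
) -> PidResult:
    """Probability that two individuals share a multilocus genotype.

    Per locus with allele frequencies p_i:

    * unrelated pair:  PID = sum p_i^4 + sum_{i<j} (2 p_i p_j)^2
    * full siblings:   PID_sibs = 0.25 + 0.5 sum p_i^2
      + 0.5 (sum p_i^2)^2 - 0.25 sum p_i^4

    Multilocus values are products over loci, reported cumulatively in the
    requested locus order.
    """
    loci = list(freqs.loci) if loci_subset is None else list(loci_subset)
    if not loci:
        raise ParameterError("loci_subset must be non-empty")
    rows = []
    for loc in loci:
        if loc not in freqs.freqs:
            raise ParameterError(f"locus {loc!r} not in frequency table")
        p = freqs.freqs[loc]
        s2 = float(np.sum(p**2))
        s4 = float(np.sum(p**4))
        pid_u = s4 + float(sum((2 * p[i] * p[j]) ** 2
                               for i in range(len(p)) for j in range(i + 1, len(p))))
        pid_s = 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4
        rows.append({"locus": loc, "pid_unrelated": pid_u, "pid_sibs": pid_s})
    df = pd.DataFrame(rows).set_index("locus")
    df["cum_unrelated"] = df["pid_unrelated"].cumprod()
    df["cum_sibs"] = df["pid_sibs"].cumprod()
    return PidResult(df)
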