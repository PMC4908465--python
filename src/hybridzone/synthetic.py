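"""Synthetic survey data with the statistical structure of a canid hybrid zone.

This module generates every input the downstream pipeline needs, without any
external data:

* two divergent parental allele pools over a shared microsatellite registry
  (:func:`generate_parental_frequencies`), with a single ``divergence`` knob
  mapping to expected F_ST via a Balding–Nichols construction;
* Hardy–Weinberg samples from a pool (:func:`sample_population`);
* a zoned landscape of class-structured individuals — red wolves, coyotes and
  four hybrid classes arranged on an east–west gradient
  (:func:`generate_landscape`);
* a noisy replicate-PCR observation process with allelic dropout, false
  alleles and amplification failure (:func:`simulate_replicate_pcrs`),
  emulating noninvasive (scat) genotyping.

Determinism contract: identical seeds and configuration give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, AlleleFrequencyTable, GenotypeMatrix, ParameterError
from .hybridsim import HybridClass, simulate_class

__all__ = [
    "ObservationModel",
    "ZoneSpec",
    "LandscapeConfig",
    "SurveyDataset",
    "generate_parental_frequencies",
    "sample_population",
    "generate_landscape",
    "simulate_replicate_pcrs",
    "study_default_config",
]

#: Aliases accepted in zone count tables.
_CLASS_ALIASES = {
    "red_wolf": "P1",
    "red wolf": "P1",
    "wolf": "P1",
    "coyote": "P2",
}


@dataclass
class ObservationModel:
    """Error model for one PCR replicate of one sample x locus.

    dropout_rate
        Probability that each allele of a heterozygote independently fails
        to amplify (homozygotes cannot drop out — the surviving allele is
        the same).
    false_allele_rate
        Probability that one spurious allele (uniform over the locus allele
        registry, excluding the true alleles) is added to the observation.
    failure_rate
        Probability that the whole reaction yields nothing.
    n_replicates
        Number of independent PCRs per sample x locus.

    The default rates are typical of noninvasive scat genotyping, where
    degraded template makes dropout the dominant error mode.
    """

    dropout_rate: float = 0.15
    false_allele_rate: float = 0.05
    failure_rate: float = 0.2
    n_replicates: int = 4

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "false_allele_rate", "failure_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")


@dataclass
class ZoneSpec:
    """One sampling zone: a label and per-class individual counts."""

    label: str
    counts: dict[str, int] = field(default_factory=dict)

    def normalized_counts(self) -> dict[HybridClass, int]:
        out: dict[HybridClass, int] = {}
        for key, n in self.counts.items():
            cls = HybridClass(_CLASS_ALIASES.get(str(key).lower(), key))
            if n < 0:
                raise ParameterError(f"negative count for {key} in zone {self.label}")
            out[cls] = out.get(cls, 0) + int(n)
        return out


@dataclass
class LandscapeConfig:
    """Configuration of a synthetic zoned survey.

    ``zones`` are listed in geographic order west -> east; with no explicit
    geometry each zone occupies one unit interval on the x axis in that
    order, so zone means of true ancestry can be read as a transect.
    ``divergence`` in [0, 1] controls the expected differentiation between
    the two parental pools (0 = identical pools, 1 = alternately fixed).
    """

    n_loci: int = 17
    alleles_per_locus: int | list[int] = 8
    divergence: float = 0.5
    zones: list[ZoneSpec] = field(default_factory=list)
    zone_geometry: dict[str, object] | None = None  # label -> shapely polygon
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ParameterError("n_loci must be >= 1")
        if not 0.0 <= self.divergence <= 1.0:
            raise ParameterError("divergence must be in [0, 1]")
        labels = [z.label for z in self.zones]
        if len(set(labels)) != len(labels):
            raise ParameterError("zone labels must be unique")


@dataclass
class SurveyDataset:
    """Output of :func:`generate_landscape`.

    ``genotypes.metadata`` carries per-individual ``true_class``, ``true_q``
    (expected red-wolf ancestry), ``zone``, ``x`` and ``y``.
    """

    genotypes: GenotypeMatrix
    wolf_pool: AlleleFrequencyTable
    coyote_pool: AlleleFrequencyTable
    config: LandscapeConfig

    @property
    def metadata(self) -> pd.DataFrame:
        return self.genotypes.metadata


def _allele_labels(n: int) -> np.ndarray:
    # even fragment sizes starting at 100, like dinucleotide microsatellites
    return 100 + 2 * np.arange(n, dtype=np.int64)


def generate_parental_frequencies(
    n_loci: int = 17,
    alleles_per_locus: int | list[int] = 8,
    divergence: float = 0.5,
    seed: int | np.random.Generator = 0,
    ancestral_alpha: float = 1.0,
) -> tuple[AlleleFrequencyTable, AlleleFrequencyTable]:
    """Draw two parental allele pools over a shared registry.

    Each locus gets an ancestral frequency vector from a symmetric Dirichlet
    (concentration ``ancestral_alpha``); the two pools are then independent
    Dirichlet perturbations of it with concentration
    ``ancestral * (1 - divergence) / divergence`` (Balding–Nichols), so the
    expected between-pool F_ST rises monotonically with ``divergence``.
    ``divergence = 0`` returns two identical copies of the ancestral draw and
    ``divergence = 1`` fixes the pools for different alleles wherever the
    locus has at least two.
    """
    if n_loci < 1:
        raise ParameterError("n_loci must be >= 1")
    if not 0.0 <= divergence <= 1.0:
        raise ParameterError("divergence must be in [0, 1]")
    if np.isscalar(alleles_per_locus):
        per_locus = [int(alleles_per_locus)] * n_loci
    else:
        per_locus = [int(a) for a in alleles_per_locus]
        if len(per_locus) != n_loci:
            raise ParameterError("alleles_per_locus list length must equal n_loci")
    if any(a < 1 for a in per_locus):
        raise ParameterError("every locus needs >= 1 allele")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loci = [f"L{j + 1}" for j in range(n_loci)]
    alleles = {loc: _allele_labels(a) for loc, a in zip(loci, per_locus)}
    f1: dict[str, np.ndarray] = {}
    f2: dict[str, np.ndarray] = {}
    for loc, n_all in zip(loci, per_locus):
        anc = rng.dirichlet(np.full(n_all, ancestral_alpha))
        if divergence == 0.0 or n_all == 1:
            f1[loc] = anc.copy()
            f2[loc] = anc.copy()
        elif divergence == 1.0:
            pick = rng.choice(n_all, size=2, replace=False)
            for d, i in ((f1, pick[0]), (f2, pick[1])):
                v = np.zeros(n_all)
                v[i] = 1.0
                d[loc] = v
        else:
            conc = anc * (1.0 - divergence) / divergence
            for d in (f1, f2):
                g = rng.gamma(np.maximum(conc, 1e-12))
                if g.sum() == 0.0:  # extreme drift: collapse to one allele
                    g[rng.choice(n_all, p=anc)] = 1.0
                d[loc] = g / g.sum()
    t1 = AlleleFrequencyTable("P1", loci, alleles, f1)
    t2 = AlleleFrequencyTable("P2", loci, alleles, f2)
    return t1, t2


def sample_population(
    freqs: AlleleFrequencyTable,
    n: int,
    seed: int | np.random.Generator = 0,
    id_prefix: str = "ind",
) -> GenotypeMatrix:
    """Hardy–Weinberg sample: each of the 2n allele copies per locus is an
    independent draw from the locus frequency vector.  No missing data."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not freqs.loci:
        raise ParameterError("empty frequency table")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(freqs.loci)
    alleles = np.empty((n, L, 2), dtype=np.int64)
    for j, loc in enumerate(freqs.loci):
        alleles[:, j, :] = rng.choice(
            freqs.alleles[loc], size=(n, 2), p=freqs.freqs[loc]
        )
    ids = [f"{id_prefix}_{i + 1}" for i in range(n)]
    return GenotypeMatrix(ids, list(freqs.loci), alleles)


def _zone_point(
    zone_index: int, geometry, rng: np.random.Generator
) -> tuple[float, float]:
    if geometry is None:
        # unit interval per zone along the west->east axis
        return zone_index + rng.random(), rng.random()
    from shapely.geometry import Point

    minx, miny, maxx, maxy = geometry.bounds
    for _ in range(10_000):
        p = Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if geometry.contains(p):
            return p.x, p.y
    raise ParameterError("could not sample a point inside the zone polygon")


def generate_landscape(config: LandscapeConfig) -> SurveyDataset:
    """Simulate a full zoned survey: genotypes, classes, coordinates.

    Individuals of each class are produced by the gamete-based hybrid
    simulator from two parental pools drawn at the configured divergence;
    coordinates are uniform inside each zone's geometry (or its unit
    interval on the west->east axis when no polygons are given).
    """
    rng = np.random.default_rng(config.seed)
    wolf_pool, coyote_pool = generate_parental_frequencies(
        config.n_loci, config.alleles_per_locus, config.divergence, rng
    )
    parts: list[GenotypeMatrix] = []
    rows: list[dict] = []
    total = 0
    for zi, zone in enumerate(config.zones):
        geom = (config.zone_geometry or {}).get(zone.label)
        for cls, n in sorted(zone.normalized_counts().items(), key=lambda kv: kv[0].value):
            if n == 0:
                continue
            total += n
            gm = simulate_class(
                wolf_pool, coyote_pool, cls, n, rng,
                id_prefix=f"{zone.label}_{cls.value}",
            )
            parts.append(gm)
            for ind in gm.ids:
                x, y = _zone_point(zi, geom, rng)
                rows.append(
                    {
                        "id": ind,
                        "true_class": cls.value,
                        "true_q": cls.expected_ancestry,
                        "zone": zone.label,
                        "x": x,
                        "y": y,
                    }
                )
    if total == 0:
        raise ParameterError("all zone counts are zero: empty dataset")
    gm = GenotypeMatrix.concat(parts)
    meta = pd.DataFrame(rows).set_index("id").loc[gm.ids]
    gm = GenotypeMatrix(gm.ids, gm.loci, gm.alleles, meta)
    return SurveyDataset(gm, wolf_pool, coyote_pool, config)


def simulate_replicate_pcrs(
    truth: GenotypeMatrix,
    model: ObservationModel,
    seed: int | np.random.Generator = 0,
    registry: AlleleFrequencyTable | None = None,
) -> pd.DataFrame:
    """Noisy replicate-PCR observations of every sample x locus.

    Returns a long-format table (sample, locus, replicate, alleles) where
    ``alleles`` is a frozenset of observed allele labels, empty for a failed
    reaction.  Per replicate: with ``failure_rate`` nothing is observed;
    otherwise each allele of a heterozygote drops out independently with
    ``dropout_rate`` and with ``false_allele_rate`` one spurious allele from
    the locus registry is added.  A missing true genotype always yields an
    empty observation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if registry is not None:
        reg = {loc: np.asarray(registry.alleles[loc]) for loc in registry.loci}
    else:
        reg = {}
        for j, loc in enumerate(truth.loci):
            a = truth.alleles[:, j, :].ravel()
            reg[loc] = np.unique(a[a != MISSING])
    rows = []
    for i, sample in enumerate(truth.ids):
        for j, loc in enumerate(truth.loci):
            a1, a2 = truth.alleles[i, j]
            missing = a1 == MISSING
            for r in range(model.n_replicates):
                obs: set[int] = set()
                if not missing and rng.random() >= model.failure_rate:
                    if a1 == a2:
                        obs.add(int(a1))
                    else:
                        if rng.random() >= model.dropout_rate:
                            obs.add(int(a1))
                        if rng.random() >= model.dropout_rate:
                            obs.add(int(a2))
                    if rng.random() < model.false_allele_rate:
                        pool = reg[loc]
                        pool = pool[(pool != a1) & (pool != a2)]
                        if pool.size:
                            obs.add(int(rng.choice(pool)))
                rows.append(
                    {
                        "sample": sample,
                        "locus": loc,
                        "replicate": r + 1,
                        "alleles": frozenset(obs),
                    }
                )
    return pd.DataFrame(rows)


def study_default_config(seed: int = 0, divergence: float = 0.5) -> LandscapeConfig:
    """Landscape emulating the study's detected individuals: 75 red wolves,
    224 coyotes and 12 hybrids (split evenly over the four hybrid classes)
    across six zones ordered west -> east D, C, B, 3, 2, 1, with red-wolf
    ancestry concentrated in the three eastern zones."""
    zones = [
        ZoneSpec("D", {"coyote": 57}),
        ZoneSpec("C", {"coyote": 26, "BC2": 1}),
        ZoneSpec("B", {"coyote": 45, "F1": 1, "BC2": 1}),
        ZoneSpec("3", {"red_wolf": 20, "coyote": 76, "F1": 2, "F2": 1,
                       "BC1": 2, "BC2": 1}),
        ZoneSpec("2", {"red_wolf": 25, "coyote": 15, "F2": 2}),
        ZoneSpec("1", {"red_wolf": 30, "coyote": 5, "BC1": 1}),
    ]
    return LandscapeConfig(
        n_loci=17, alleles_per_locus=8, divergence=divergence,
        zones=zones, seed=seed,
    )
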