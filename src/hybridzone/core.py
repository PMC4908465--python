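"""Core data containers shared by every analysis stage.

Two objects circulate through the whole pipeline:

* :class:`GenotypeMatrix` — individuals × loci diploid allele calls, the
  universal currency of consensus calling, matching, population-genetic
  summaries, admixture estimation and simulation.
* :class:`AlleleFrequencyTable` — per-population, per-locus allele
  frequency vectors, which drive genotype simulation, probability-of-identity
  calculations and the admixture likelihood.

Allele labels are integers (conventionally microsatellite fragment sizes in
base pairs).  Missing data is whole-locus and encoded as ``-9`` in both the
in-memory array and all on-disk formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing allele call (whole-locus missing).
MISSING = -9


class ParameterError(ValueError):
    """A caller-supplied parameter is outside its valid domain."""


@dataclass
class GenotypeMatrix:
    """Diploid multilocus genotypes for a set of individuals.

    Parameters
    ----------
    ids
        Individual (or sample) identifiers, unique, length ``n``.
    loci
        Ordered locus labels, length ``L``.
    alleles
        Integer array of shape ``(n, L, 2)``.  Allele pairs are unordered and
        stored sorted; a missing locus has both entries equal to ``MISSING``.
    metadata
        Optional per-individual table indexed by ``ids`` (zone, coordinates,
        known-identity label, true ancestry, ...).
    """

    ids: list[str]
    loci: list[str]
    alleles: np.ndarray
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.loci = [str(l) for l in self.loci]
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n, L = len(self.ids), len(self.loci)
        if self.alleles.shape != (n, L, 2):
            raise ParameterError(
                f"allele array shape {self.alleles.shape} != ({n}, {L}, 2)"
            )
        if len(set(self.ids)) != n:
            raise ParameterError("individual ids must be unique")
        if len(set(self.loci)) != L:
            raise ParameterError("locus labels must be unique")
        # Half-missing calls are not representable: blank the whole locus.
        half = (self.alleles == MISSING).any(axis=2)
        self.alleles[half] = MISSING
        self.alleles = np.sort(self.alleles, axis=2)
        # sort puts -9 first, which keeps (MISSING, MISSING) intact and
        # canonicalises heterozygote order.
        if self.metadata is not None:
            self.metadata = self.metadata.loc[self.ids]

    # -- basic introspection -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def typed(self) -> np.ndarray:
        """Boolean ``(n, L)`` mask of non-missing locus calls."""
        return self.alleles[:, :, 0] != MISSING

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise ParameterError(f"unknown locus {locus!r}") from None

    def genotype(self, individual: str, locus: str) -> tuple[int, int] | None:
        """The sorted allele pair, or ``None`` if missing."""
        i = self.ids.index(individual)
        l = self.locus_index(locus)
        a = self.alleles[i, l]
        return None if a[0] == MISSING else (int(a[0]), int(a[1]))

    # -- derived tables ------------------------------------------------------

    def allele_counts(self, locus: str) -> dict[int, int]:
        """Counts of each allele among typed individuals at *locus*."""
        l = self.locus_index(locus)
        a = self.alleles[:, l, :].ravel()
        a = a[a != MISSING]
        vals, cnt = np.unique(a, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, cnt)}

    def estimate_frequencies(self, population_id: str = "pop") -> "AlleleFrequencyTable":
        """Observed allele frequencies (counts / typed gene copies) per locus.

        Loci with zero typed copies are dropped.
        """
        loci, alleles, freqs = [], {}, {}
        for loc in self.loci:
            counts = self.allele_counts(loc)
            tot = sum(counts.values())
            if tot == 0:
                continue
            loci.append(loc)
            labels = np.array(sorted(counts), dtype=np.int64)
            alleles[loc] = labels
            freqs[loc] = np.array([counts[a] / tot for a in labels])
        if not loci:
            raise ParameterError("no locus has any typed individual")
        return AlleleFrequencyTable(population_id, loci, alleles, freqs)

    # -- manipulation --------------------------------------------------------

    def subset(
        self,
        ids: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        ids = list(self.ids) if ids is None else [str(i) for i in ids]
        loci = list(self.loci) if loci is None else [str(l) for l in loci]
        ridx = [self.ids.index(i) for i in ids]
        cidx = [self.locus_index(l) for l in loci]
        meta = None if self.metadata is None else self.metadata.loc[ids]
        return GenotypeMatrix(ids, loci, self.alleles[np.ix_(ridx, cidx)], meta)

    @staticmethod
    def concat(parts: Iterable["GenotypeMatrix"]) -> "GenotypeMatrix":
        parts = list(parts)
        if not parts:
            raise ParameterError("nothing to concatenate")
        loci = parts[0].loci
        for p in parts[1:]:
            if p.loci != loci:
                raise ParameterError("locus registries differ between parts")
        ids = [i for p in parts for i in p.ids]
        alleles = np.concatenate([p.alleles for p in parts], axis=0)
        metas = [p.metadata for p in parts]
        meta = None if any(m is None for m in metas) else pd.concat(metas)
        return GenotypeMatrix(ids, loci, alleles, meta)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.ids == other.ids
            and self.loci == other.loci
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequency vectors for one population.

    ``alleles[locus]`` holds the integer allele labels (the registry) and
    ``freqs[locus]`` the matching frequencies, which must be non-negative and
    sum to one.
    """

    population_id: str
    loci: list[str]
    alleles: Mapping[str, np.ndarray] = field(repr=False)
    freqs: Mapping[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        self.loci = [str(l) for l in self.loci]
        if len(set(self.loci)) != len(self.loci):
            raise ParameterError("locus labels must be unique")
        alleles, freqs = {}, {}
        for loc in self.loci:
            a = np.asarray(self.alleles[loc], dtype=np.int64)
            p = np.asarray(self.freqs[loc], dtype=float)
            if a.size == 0:
                raise ParameterError(f"locus {loc!r} has no alleles")
            if a.size != np.unique(a).size:
                raise ParameterError(f"duplicate allele labels at {loc!r}")
            if a.shape != p.shape:
                raise ParameterError(f"allele/frequency length mismatch at {loc!r}")
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ParameterError(
                    f"frequencies at {loc!r} must be >= 0 and sum to 1"
                )
            alleles[loc], freqs[loc] = a, p
        self.alleles, self.freqs = alleles, freqs

    def n_alleles(self, locus: str) -> int:
        return int(self.alleles[locus].size)

    def frequency(self, locus: str, allele: int) -> float:
        a = self.alleles[locus]
        hit = np.nonzero(a == allele)[0]
        return float(self.freqs[locus][hit[0]]) if hit.size else 0.0

    def same_registry(self, other: "AlleleFrequencyTable") -> bool:
        """True if loci and allele label sets coincide (order-sensitive loci)."""
        if self.loci != other.loci:
            return False
        return all(
            np.array_equal(np.sort(self.alleles[l]), np.sort(other.alleles[l]))
            for l in self.loci
        )

    def expected_heterozygosity(self, locus: str) -> float:
        p = self.freqs[locus]
        return float(1.0 - np.sum(p**2))
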