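"""Gamete-based simulation of parental and hybrid-class genotypes.

Given allele frequencies for two parental gene pools (here red wolf and
coyote), multilocus genotypes are built for six classes: the two parentals,
F1, F2 and both first-generation backcrosses.  Gametes are drawn directly
from the pool allele frequencies, loci are unlinked and there is no
mutation, so the expected ancestry toward parental pool 1 is exactly
1, 0, 0.5, 0.5, 0.75 and 0.25 for P1, P2, F1, F2, BC1 and BC2.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .core import AlleleFrequencyTable, GenotypeMatrix, ParameterError


class HybridClass(str, Enum):
    """Genotype classes producible from two parental pools."""

    P1 = "P1"      # parental 1 (red wolf)
    P2 = "P2"      # parental 2 (coyote)
    F1 = "F1"      # P1 x P2
    F2 = "F2"      # F1 x F1
    BC1 = "BC1"    # F1 x P1 backcross
    BC2 = "BC2"    # F1 x P2 backcross

    @property
    def expected_ancestry(self) -> float:
        """Expected proportion of the genome tracing to parental pool 1."""
        return _EXPECTED_Q[self]


_EXPECTED_Q = {
    HybridClass.P1: 1.0,
    HybridClass.P2: 0.0,
    HybridClass.F1: 0.5,
    HybridClass.F2: 0.5,
    HybridClass.BC1: 0.75,
    HybridClass.BC2: 0.25,
}


def estimate_frequencies(
    parental: GenotypeMatrix, population_id: str = "pop"
) -> AlleleFrequencyTable:
    """Observed allele frequencies of a parental reference panel.

    Frequencies are allele counts over typed gene copies per locus; loci with
    no typed individual are dropped with a warning via the return value
    (they are simply absent).
    """
    return parental.estimate_frequencies(population_id)


def _parental_gametes(
    freqs: AlleleFrequencyTable, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``(n, L)`` array of allele labels, one gamete per locus drawn from the
    pool's frequencies."""
    out = np.empty((n, len(freqs.loci)), dtype=np.int64)
    for j, loc in enumerate(freqs.loci):
        out[:, j] = rng.choice(freqs.alleles[loc], size=n, p=freqs.freqs[loc])
    return out


def _f1_gametes(
    f1: AlleleFrequencyTable,
    f2: AlleleFrequencyTable,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gametes of an F1: per locus the transmitted allele is of P1 or P2
    origin with probability one half, independently across loci."""
    g1 = _parental_gametes(f1, n, rng)
    g2 = _parental_gametes(f2, n, rng)
    pick = rng.random(g1.shape) < 0.5
    return np.where(pick, g1, g2)


def simulate_class(
    freqs_p1: AlleleFrequencyTable,
    freqs_p2: AlleleFrequencyTable,
    hybrid_class: HybridClass | str,
    n: int,
    seed: int | np.random.Generator,
    id_prefix: str | None = None,
) -> GenotypeMatrix:
    """Simulate *n* individuals of one class from two parental pools.

    The two pools must share the same locus registry.  Genotypes carry no
    missing data; the class label is recorded in the metadata column
    ``true_class`` along with the expected ancestry ``true_q``.
    """
    hybrid_class = HybridClass(hybrid_class)
    if n < 1:
        raise ParameterError("n must be >= 1")
    if freqs_p1.loci != freqs_p2.loci:
        raise ParameterError("parental pools must share the same locus registry")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def gam(which: str) -> np.ndarray:
        if which == "P1":
            return _parental_gametes(freqs_p1, n, rng)
        if which == "P2":
            return _parental_gametes(freqs_p2, n, rng)
        return _f1_gametes(freqs_p1, freqs_p2, n, rng)

    recipe = {
        HybridClass.P1: ("P1", "P1"),
        HybridClass.P2: ("P2", "P2"),
        HybridClass.F1: ("P1", "P2"),
        HybridClass.F2: ("F1", "F1"),
        HybridClass.BC1: ("F1", "P1"),
        HybridClass.BC2: ("F1", "P2"),
    }[hybrid_class]
    alleles = np.stack([gam(recipe[0]), gam(recipe[1])], axis=2)

    prefix = id_prefix or hybrid_class.value
    ids = [f"{prefix}_{i + 1}" for i in range(n)]
    import pandas as pd

    meta = pd.DataFrame(
        {
            "true_class": hybrid_class.value,
            "true_q": hybrid_class.expected_ancestry,
        },
        index=ids,
    )
    return GenotypeMatrix(ids, list(freqs_p1.loci), alleles, meta)
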