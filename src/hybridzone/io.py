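"""Readers and writers for the plain-text interchange formats.

Genotypes travel in two equivalent representations:

* CSV — one row per individual, an ``id`` column, then two columns per locus
  (``LOC.1``, ``LOC.2``); missing alleles are ``-9``.
* STRUCTURE-format text — whitespace-delimited, one row per individual, the
  id first and then pairs of allele columns, ``-9`` missing.  A single header
  line carries the locus labels.

Replicate PCR observations use a long CSV (sample, locus, replicate,
alleles) with the allele set pipe-separated and an empty field for a failed
reaction.  Allele frequency tables use a tidy CSV
(population, locus, allele, frequency).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, AlleleFrequencyTable, GenotypeMatrix


# -- genotype CSV ------------------------------------------------------------

def write_genotypes_csv(gm: GenotypeMatrix, path: str | Path) -> None:
    cols: dict[str, object] = {"id": gm.ids}
    for j, loc in enumerate(gm.loci):
        cols[f"{loc}.1"] = gm.alleles[:, j, 0]
        cols[f"{loc}.2"] = gm.alleles[:, j, 1]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_genotypes_csv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype={"id": str})
    loci = [c[:-2] for c in df.columns if c.endswith(".1")]
    alleles = np.empty((len(df), len(loci), 2), dtype=np.int64)
    for j, loc in enumerate(loci):
        alleles[:, j, 0] = df[f"{loc}.1"].to_numpy()
        alleles[:, j, 1] = df[f"{loc}.2"].to_numpy()
    return GenotypeMatrix(list(df["id"]), loci, alleles)


# -- STRUCTURE format --------------------------------------------------------

def write_structure(gm: GenotypeMatrix, path: str | Path, header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(" ".join(gm.loci) + "\n")
        for i, ind in enumerate(gm.ids):
            row = [ind] + [str(a) for a in gm.alleles[i].ravel()]
            fh.write(" ".join(row) + "\n")


def read_structure(path: str | Path, header: bool = True) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if header:
        loci, rows = lines[0], lines[1:]
    else:
        rows = lines
        loci = [f"L{j + 1}" for j in range((len(rows[0]) - 1) // 2)]
    ids = [r[0] for r in rows]
    alleles = np.array([[int(x) for x in r[1:]] for r in rows], dtype=np.int64)
    return GenotypeMatrix(ids, loci, alleles.reshape(len(ids), len(loci), 2))


# -- replicate observations --------------------------------------------------

def write_replicates_csv(obs: "pd.DataFrame", path: str | Path) -> None:
    """Write a long-format replicate table (sample, locus, replicate, alleles).

    ``alleles`` holds a collection of ints per row; serialised pipe-separated,
    empty string for a failed reaction.
    """
    out = obs.copy()
    out["alleles"] = [
        "|".join(str(int(a)) for a in sorted(al)) for al in obs["alleles"]
    ]
    out.to_csv(path, index=False)


def read_replicates_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample": str, "locus": str}, keep_default_na=False)
    df["alleles"] = [
        frozenset(int(x) for x in str(s).split("|") if x != "")
        for s in df["alleles"]
    ]
    df["replicate"] = df["replicate"].astype(int)
    return df


# -- allele frequency tables -------------------------------------------------

def write_frequencies_csv(tables: list[AlleleFrequencyTable] | AlleleFrequencyTable,
                          path: str | Path) -> None:
    if isinstance(tables, AlleleFrequencyTable):
        tables = [tables]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["population", "locus", "allele", "frequency"])
        for t in tables:
            for loc in t.loci:
                for a, p in zip(t.alleles[loc], t.freqs[loc]):
                    w.writerow([t.population_id, loc, int(a), repr(float(p))])


def read_frequencies_csv(path: str | Path) -> list[AlleleFrequencyTable]:
    df = pd.read_csv(path, dtype={"population": str, "locus": str})
    tables = []
    for pop, sub in df.groupby("population", sort=False):
        loci = list(dict.fromkeys(sub["locus"]))
        alleles = {
            loc: grp["allele"].to_numpy(dtype=np.int64)
            for loc, grp in sub.groupby("locus", sort=False)
        }
        freqs = {
            loc: grp["frequency"].to_numpy(dtype=float)
            for loc, grp in sub.groupby("locus", sort=False)
        }
        tables.append(AlleleFrequencyTable(pop, loci, alleles, freqs))
    return tables


# -- coordinates -------------------------------------------------------------

def write_coordinates_csv(meta: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("x", "y", "zone") if c in meta.columns]
    meta[cols].rename_axis("id").to_csv(path)


def read_coordinates_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"id": str, "zone": str}).set_index("id")
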