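"""Data model and I/O for codominant SSR genotypes.

Genotypes are diploid allele-size calls (fragment lengths in bp) scored from
gels.  A single observed band at a locus is the conventional codominant
scoring of a homozygote, so every non-missing call is stored as an unordered
pair of positive integer allele labels, canonicalized as (min, max).  A locus
call is either fully observed or fully missing; the missing sentinel occupies
both slots.

Two file dialects are supported:

* ``long-table`` — one row per (individual, locus) with columns
  ``individual, population, locus, allele1[, allele2]``; a blank or absent
  second allele means a single band (homozygote).
* ``genalex-codominant`` — the GenAlEx codominant layout: three header rows
  (counts/sizes, titles + population names, column labels) followed by one
  row per individual with two columns per locus.

Both dialects are accepted as CSV or XLSX (same logical schema).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "LocusMeta",
    "BinningSpec",
    "GenotypeParseError",
    "GenotypeStructureError",
    "read_genotypes",
    "write_genotypes",
    "bin_alleles",
]

#: sentinel stored in both allele slots of a missing call
MISSING = 0

DIALECTS = ("long-table", "genalex-codominant")


class GenotypeParseError(ValueError):
    """A row of a genotype file could not be interpreted."""


class GenotypeStructureError(ValueError):
    """Header and body of a genotype file disagree."""


@dataclass(frozen=True)
class LocusMeta:
    """Metadata for one SSR marker (primer pair)."""

    name: str
    repeat_motif: str
    chromosome: str
    forward_primer: str
    reverse_primer: str
    annealing_temp_c: float


@dataclass(frozen=True)
class BinningSpec:
    """Rule for collapsing raw fragment sizes into discrete allele classes.

    mode:
      * ``exact`` — identity, sizes already discrete.
      * ``tolerance-cluster`` — single-linkage clustering of the sorted
        distinct sizes at each locus, cutting links larger than
        ``tolerance_bp``; each bin is represented by the rounded bin mean.
      * ``ladder-round`` — snap each size onto the repeat-motif ladder
        ``offset + repeat * round((size - offset) / repeat)``.

    All rounding is round-half-to-even so binning is deterministic across
    platforms.
    """

    mode: str = "exact"
    tolerance_bp: float = 0.0
    ladder_offset: float = 0.0
    ladder_repeat: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "tolerance-cluster", "ladder-round"):
            raise ValueError(f"unknown binning mode {self.mode!r}")
        if self.tolerance_bp < 0:
            raise ValueError("tolerance_bp must be >= 0")
        if self.mode == "ladder-round" and self.ladder_repeat < 1:
            raise ValueError("ladder_repeat must be >= 1")


@dataclass
class GenotypeMatrix:
    """Individuals x loci codominant allele-size calls with population labels.

    ``calls`` has shape (n_individuals, n_loci, 2) with positive integer
    allele labels; a missing call is ``(MISSING, MISSING)``.  Pairs are
    canonicalized as (min, max) on construction.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    populations: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if len(self.populations) != n:
            raise ValueError("one population label per individual required")
        if n < 1:
            raise ValueError("at least one individual required")
        if L < 1:
            raise ValueError("at least one locus required")
        if len(set(self.individuals)) != n:
            raise ValueError("individual IDs must be unique")
        if len(set(self.loci)) != L:
            raise ValueError("locus IDs must be unique")
        miss = self.missing_mask()
        half_missing = (self.calls == MISSING).any(axis=2) & ~miss
        if half_missing.any():
            raise ValueError("a call must be fully observed or fully missing")
        if (self.calls < 0).any():
            raise ValueError("allele labels must be positive")
        # canonical order within the pair
        self.calls = np.sort(self.calls, axis=2)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def pop_of(self) -> dict[str, str]:
        return dict(zip(self.individuals, self.populations))

    def population_names(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_indices(self) -> dict[str, np.ndarray]:
        pops = np.asarray(self.populations)
        return {p: np.flatnonzero(pops == p) for p in self.population_names()}

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean, True where the call is missing."""
        return (self.calls == MISSING).all(axis=2)

    def subset(self, individuals: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.individuals.index(i) for i in individuals]
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in idx],
            loci=list(self.loci),
            calls=self.calls[idx].copy(),
            populations=[self.populations[i] for i in idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and self.populations == other.populations
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# reading


def _read_rows(path: Path) -> list[list[str]]:
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        import openpyxl

        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
        ws = wb.active
        rows = [
            ["" if c is None else str(c) for c in row]
            for row in ws.iter_rows(values_only=True)
        ]
        wb.close()
        return rows
    with open(path, newline="") as fh:
        return [list(r) for r in csv.reader(fh)]


def _parse_allele(tok: str, missing_code: str, row_no: int) -> int:
    tok = tok.strip()
    if tok == "" or tok == missing_code:
        return MISSING
    try:
        val = int(round(float(tok)))
    except ValueError:
        raise GenotypeParseError(
            f"row {row_no}: allele {tok!r} is not numeric"
        ) from None
    if val <= 0:
        raise GenotypeParseError(f"row {row_no}: allele {tok!r} not positive")
    return val


def read_genotypes(
    path: str | Path,
    dialect: str = "long-table",
    missing_code: str = "0",
) -> GenotypeMatrix:
    """Read a codominant genotype table.

    Single-band records become homozygous pairs; row and column order is
    preserved.  Raises :class:`GenotypeParseError` for malformed rows and
    :class:`GenotypeStructureError` when header and body disagree.  An
    all-missing locus is retained with a warning.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}")
    rows = _read_rows(path)
    if dialect == "long-table":
        matrix = _read_long_table(rows, missing_code)
    else:
        matrix = _read_genalex(rows, missing_code)
    all_missing = matrix.missing_mask().all(axis=0)
    for j in np.flatnonzero(all_missing):
        warnings.warn(
            f"locus {matrix.loci[j]!r} has no genotyped individuals",
            stacklevel=2,
        )
    return matrix


def _read_long_table(rows: list[list[str]], missing_code: str) -> GenotypeMatrix:
    body = [r for r in rows if any(c.strip() for c in r)]
    if not body:
        raise GenotypeParseError("empty file")
    header = [c.strip().lower() for c in body[0]]
    if header[:3] == ["individual", "population", "locus"]:
        body = body[1:]
    individuals: list[str] = []
    pops: dict[str, str] = {}
    loci: list[str] = []
    calls: dict[tuple[str, str], tuple[int, int]] = {}
    for row_no, row in enumerate(body, start=1):
        if len(row) < 4:
            raise GenotypeParseError(f"row {row_no}: expected >= 4 columns")
        ind, pop, locus = (row[0].strip(), row[1].strip(), row[2].strip())
        if not ind or not pop or not locus:
            raise GenotypeParseError(f"row {row_no}: empty key field")
        a1 = _parse_allele(row[3], missing_code, row_no)
        if len(row) > 4 and row[4].strip() != "":
            a2 = _parse_allele(row[4], missing_code, row_no)
        else:
            a2 = a1  # single observed band scored as a homozygote
        if a1 == MISSING or a2 == MISSING:
            a1 = a2 = MISSING
        if ind not in pops:
            individuals.append(ind)
            pops[ind] = pop
        elif pops[ind] != pop:
            raise GenotypeStructureError(
                f"row {row_no}: individual {ind!r} has conflicting populations"
            )
        if locus not in loci:
            loci.append(locus)
        calls[(ind, locus)] = (a1, a2)
    arr = np.full((len(individuals), len(loci), 2), MISSING, dtype=np.int64)
    for (ind, locus), (a1, a2) in calls.items():
        arr[individuals.index(ind), loci.index(locus)] = (a1, a2)
    return GenotypeMatrix(individuals, loci, arr, [pops[i] for i in individuals])


def _read_genalex(rows: list[list[str]], missing_code: str) -> GenotypeMatrix:
    if len(rows) < 4:
        raise GenotypeParseError("GenAlEx file needs 3 header rows + data")
    try:
        n_loci = int(float(rows[0][0]))
        n_ind = int(float(rows[0][1]))
        n_pop = int(float(rows[0][2]))
        pop_sizes = [int(float(x)) for x in rows[0][3 : 3 + n_pop]]
    except (ValueError, IndexError):
        raise GenotypeParseError("malformed GenAlEx counts row") from None
    pop_names = [c.strip() for c in rows[1][3 : 3 + n_pop]]
    if len(pop_names) < n_pop or any(not p for p in pop_names):
        pop_names = [f"Pop{i + 1}" for i in range(n_pop)]
    label_row = rows[2]
    loci = [
        label_row[2 + 2 * j].strip() if 2 + 2 * j < len(label_row) else ""
        for j in range(n_loci)
    ]
    if any(not l for l in loci):
        raise GenotypeStructureError("locus names missing from header row 3")
    body = [r for r in rows[3:] if any(c.strip() for c in r)]
    if len(body) != n_ind:
        raise GenotypeStructureError(
            f"header declares {n_ind} individuals, body has {len(body)} rows"
        )
    if sum(pop_sizes) != n_ind:
        raise GenotypeStructureError("population sizes do not sum to N")
    individuals, populations = [], []
    arr = np.full((n_ind, n_loci, 2), MISSING, dtype=np.int64)
    for i, row in enumerate(body):
        row_no = i + 4
        if len(row) < 2 + 2 * n_loci:
            raise GenotypeParseError(
                f"row {row_no}: expected {2 + 2 * n_loci} columns"
            )
        individuals.append(row[0].strip())
        populations.append(row[1].strip())
        for j in range(n_loci):
            a1 = _parse_allele(row[2 + 2 * j], missing_code, row_no)
            a2 = _parse_allele(row[3 + 2 * j], missing_code, row_no)
            if a1 == MISSING and a2 == MISSING:
                pass
            elif a1 == MISSING or a2 == MISSING:
                a1 = a2 = max(a1, a2)  # single band -> homozygote
            arr[i, j] = (a1, a2)
    declared = dict(zip(pop_names, pop_sizes))
    found = {p: populations.count(p) for p in dict.fromkeys(populations)}
    if set(found) != set(declared) or any(
        declared[p] != found[p] for p in found
    ):
        raise GenotypeStructureError(
            f"population sizes in header {declared} != body {found}"
        )
    return GenotypeMatrix(individuals, loci, arr, populations)


# ---------------------------------------------------------------------------
# writing


def write_genotypes(
    matrix: GenotypeMatrix,
    path: str | Path,
    dialect: str = "long-table",
    missing_code: str = "0",
) -> Path:
    """Write ``matrix`` so that reading the file back reproduces it."""
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}")
    rows: list[list[str]]
    if dialect == "long-table":
        rows = [["individual", "population", "locus", "allele1", "allele2"]]
        for i, ind in enumerate(matrix.individuals):
            for j, locus in enumerate(matrix.loci):
                a1, a2 = matrix.calls[i, j]
                tok1 = missing_code if a1 == MISSING else str(int(a1))
                tok2 = missing_code if a2 == MISSING else str(int(a2))
                rows.append([ind, matrix.populations[i], locus, tok1, tok2])
    else:
        pops = matrix.population_names()
        sizes = [matrix.populations.count(p) for p in pops]
        rows = [
            [str(matrix.n_loci), str(matrix.n_individuals), str(len(pops))]
            + [str(s) for s in sizes]
        ]
        rows.append(["SSR genotypes", "", ""] + pops)
        label = ["Ind", "Pop"]
        for locus in matrix.loci:
            label += [locus, ""]
        rows.append(label)
        for i, ind in enumerate(matrix.individuals):
            row = [ind, matrix.populations[i]]
            for j in range(matrix.n_loci):
                a1, a2 = matrix.calls[i, j]
                row.append(missing_code if a1 == MISSING else str(int(a1)))
                row.append(missing_code if a2 == MISSING else str(int(a2)))
            rows.append(row)
    with open(path, "w", newline="") as fh:
        csv.writer(fh).writerows(rows)
    return path


# ---------------------------------------------------------------------------
# allele binning


def _single_linkage_bins(sizes: np.ndarray, tol: float) -> dict[int, int]:
    """Map each distinct size to its bin representative (rounded bin mean)."""
    order = np.sort(sizes)
    bins: list[list[int]] = [[int(order[0])]]
    for s in order[1:]:
        if s - bins[-1][-1] <= tol:
            bins[-1].append(int(s))
        else:
            bins.append([int(s)])
    mapping: dict[int, int] = {}
    for b in bins:
        rep = int(np.round(np.mean(b)))  # round-half-to-even
        for s in b:
            mapping[s] = rep
    return mapping


def bin_alleles(matrix: GenotypeMatrix, spec: BinningSpec) -> GenotypeMatrix:
    """Collapse raw fragment sizes into discrete allele classes per locus.

    Never increases the number of distinct alleles at a locus; with
    ``tolerance_bp=0`` the tolerance-cluster mode equals ``exact``.
    """
    if spec.mode == "exact":
        return GenotypeMatrix(
            list(matrix.individuals),
            list(matrix.loci),
            matrix.calls.copy(),
            list(matrix.populations),
        )
    new = matrix.calls.copy()
    for j in range(matrix.n_loci):
        col = matrix.calls[:, j, :]
        observed = col[col != MISSING]
        if observed.size == 0:
            continue
        distinct = np.unique(observed)
        if spec.mode == "tolerance-cluster":
            mapping = _single_linkage_bins(distinct, spec.tolerance_bp)
        else:  # ladder-round
            reps = spec.ladder_offset + spec.ladder_repeat * np.round(
                (distinct - spec.ladder_offset) / spec.ladder_repeat
            )
            mapping = {
                int(s): int(round(r)) for s, r in zip(distinct, reps)
            }
        lut = np.vectorize(lambda a: MISSING if a == MISSING else mapping[int(a)])
        new[:, j, :] = lut(col)
    return GenotypeMatrix(
        list(matrix.individuals), list(matrix.loci), new, list(matrix.populations)
    )
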