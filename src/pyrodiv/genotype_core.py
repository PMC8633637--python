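"""Core data model, I/O and quality control for codominant microsatellite genotypes.

Genotypes are diploid allele pairs at each of L loci, stored as an
``(n_individuals, n_loci, 2)`` integer array. Allele labels are opaque
positive integers (typically fragment sizes in base pairs); no stepwise
mutation model is assumed anywhere downstream. Missing calls are held as
the internal sentinel :data:`MISSING` (written as ``0`` in GenAlEx files,
``-9`` in STRUCTURE files). A genotype with either allele missing is
treated as untyped at that locus: a half-scored genotype cannot be scored
for heterozygosity, so conservative QC discards it.

Individuals carry a three-part sampling hierarchy: ``block`` (top level),
``plot`` (nested within block) and ``timepoint`` (``pre``/``post``/``none``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Internal sentinel for a missing allele call. Files use 0 (GenAlEx) or -9
#: (STRUCTURE); in memory all missing calls are normalised to this value.
MISSING: int = -1

_LEVELS = ("block", "plot", "timepoint")


class GenotypeFormatError(ValueError):
    """Raised when a genotype file violates its declared layout."""


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele-call matrix with hierarchy labels.

    Parameters
    ----------
    individuals
        DataFrame with columns ``id``, ``block``, ``plot``, ``timepoint``
        (one row per individual, in the row order of ``calls``).
    loci
        Ordered locus identifiers.
    calls
        ``(n_individuals, n_loci, 2)`` integer array; missing = ``MISSING``.
        Half-missing genotypes are normalised to fully missing on
        construction.
    """

    individuals: pd.DataFrame
    loci: list[str]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.individuals = self.individuals.reset_index(drop=True)
        for col in ("id",) + _LEVELS:
            if col not in self.individuals.columns:
                if col == "timepoint":
                    self.individuals["timepoint"] = "none"
                else:
                    raise ValueError(f"individuals frame lacks column {col!r}")
        self.loci = list(self.loci)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        # half-missing genotypes are untyped: blank the partner allele too
        half = (self.calls == MISSING).any(axis=2) & (self.calls != MISSING).any(axis=2)
        self.calls[half] = MISSING
        # plots must nest uniquely within blocks
        nest = self.individuals.groupby("plot")["block"].nunique()
        bad = nest[nest > 1]
        if len(bad):
            raise ValueError(f"plot labels appear in multiple blocks: {list(bad.index)}")

    # ------------------------------------------------------------------ basics
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def typed_mask(self) -> np.ndarray:
        """Boolean ``(n_individuals, n_loci)`` mask of fully typed genotypes."""
        return (self.calls != MISSING).all(axis=2)

    def missing_fraction(self) -> np.ndarray:
        """Per-individual fraction of untyped loci."""
        return 1.0 - self.typed_mask().mean(axis=1)

    def subset(self, row_mask: np.ndarray) -> "GenotypeTable":
        """New table restricted to individuals where ``row_mask`` is True."""
        row_mask = np.asarray(row_mask)
        return GenotypeTable(
            self.individuals.loc[row_mask].copy(),
            self.loci,
            self.calls[row_mask].copy(),
        )

    def group_labels(self, level: str) -> np.ndarray:
        """Group label per individual at a hierarchy level.

        ``plot`` labels are qualified as ``"block:plot"`` so that groups
        respect the nesting even if bare plot names were reused.
        """
        if level == "block":
            return self.individuals["block"].to_numpy(dtype=object)
        if level == "plot":
            return (
                self.individuals["block"].astype(str)
                + ":"
                + self.individuals["plot"].astype(str)
            ).to_numpy(dtype=object)
        if level == "timepoint":
            return self.individuals["timepoint"].to_numpy(dtype=object)
        if level == "all":
            return np.asarray(["all"] * self.n_individuals, dtype=object)
        raise ValueError(f"unknown grouping level {level!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
            and self.individuals[["id", "block", "plot", "timepoint"]]
            .astype(str)
            .equals(other.individuals[["id", "block", "plot", "timepoint"]].astype(str))
        )


# ---------------------------------------------------------------------- I/O


def _parse_allele(cell: str, row: int, col: int) -> int:
    cell = cell.strip()
    if cell in ("", "0", "-9", "NA"):
        return MISSING
    try:
        value = int(cell)
    except ValueError:
        raise GenotypeFormatError(
            f"non-integer allele {cell!r} at data row {row}, column {col}"
        ) from None
    return value if value > 0 else MISSING


def read_genalex(path) -> GenotypeTable:
    """Read a GenAlEx codominant CSV file.

    Layout: row 1 = ``n_loci, n_individuals, n_groups, size_1, ...``;
    row 2 = title then group names; row 3 = column headers (sample,
    population, then two columns per locus, optionally a trailing
    ``timepoint`` column); data rows follow. The population column encodes
    the hierarchy as ``block:plot`` (a bare label is taken as the block,
    with one plot per block). Missing alleles are coded 0.
    """
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)]
    if len(rows) < 3:
        raise GenotypeFormatError("file has fewer than 3 header rows")
    try:
        n_loci = int(rows[0][0])
        n_ind = int(rows[0][1])
    except (ValueError, IndexError):
        raise GenotypeFormatError("row 1 must start with n_loci, n_individuals") from None
    header = rows[2]
    loci = [header[2 + 2 * j].strip() for j in range(n_loci)]
    has_timepoint = len(header) > 2 + 2 * n_loci and header[2 + 2 * n_loci].strip()
    data = [r for r in rows[3:] if any(c.strip() for c in r)]
    if len(data) != n_ind:
        raise GenotypeFormatError(
            f"header declares {n_ind} individuals but file contains {len(data)} data rows"
        )
    ids, blocks, plots, tps = [], [], [], []
    calls = np.full((n_ind, n_loci, 2), MISSING, dtype=np.int64)
    for i, row in enumerate(data):
        if len(row) < 2 + 2 * n_loci:
            raise GenotypeFormatError(
                f"data row {i + 1} has {len(row)} cells, expected at least {2 + 2 * n_loci}"
            )
        ids.append(row[0].strip())
        pop = row[1].strip()
        block, _, plot = pop.partition(":")
        blocks.append(block)
        plots.append(plot if plot else block)
        tps.append(row[2 + 2 * n_loci].strip() if has_timepoint else "none")
        for j in range(n_loci):
            calls[i, j, 0] = _parse_allele(row[2 + 2 * j], i + 1, 2 + 2 * j)
            calls[i, j, 1] = _parse_allele(row[3 + 2 * j], i + 1, 3 + 2 * j)
    individuals = pd.DataFrame(
        {"id": ids, "block": blocks, "plot": plots, "timepoint": tps}
    )
    return GenotypeTable(individuals, loci, calls)


def write_genalex(table: GenotypeTable, path) -> None:
    """Write a table in the GenAlEx codominant CSV dialect (missing = 0)."""
    pops = (
        table.individuals["block"].astype(str)
        + ":"
        + table.individuals["plot"].astype(str)
    )
    pop_order = list(dict.fromkeys(pops))
    sizes = [int((pops == p).sum()) for p in pop_order]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [table.n_loci, table.n_individuals, len(pop_order), *sizes]
        )
        w.writerow(["pyrodiv genotype table", "", *pop_order])
        header = ["sample", "pop"]
        for locus in table.loci:
            header += [locus, ""]
        header.append("timepoint")
        w.writerow(header)
        out = np.where(table.calls == MISSING, 0, table.calls)
        for i in range(table.n_individuals):
            row = [table.individuals["id"].iat[i], pops.iat[i]]
            for j in range(table.n_loci):
                row += [out[i, j, 0], out[i, j, 1]]
            row.append(table.individuals["timepoint"].iat[i])
            w.writerow(row)


def read_structure(path, n_loci: int | None = None) -> GenotypeTable:
    """Read a STRUCTURE-style two-rows-per-individual flat file.

    Whitespace-delimited; each individual contributes two consecutive rows:
    ``id  population  allele_1 ... allele_L`` with missing coded -9. The
    population field is interpreted as ``block:plot`` like the GenAlEx reader.
    """
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if len(lines) % 2:
        raise GenotypeFormatError("odd number of rows: expected two rows per individual")
    if not lines:
        raise GenotypeFormatError("empty file")
    width = len(lines[0])
    if n_loci is None:
        n_loci = width - 2
    if n_loci <= 0:
        raise GenotypeFormatError("no locus columns found")
    n_ind = len(lines) // 2
    ids, blocks, plots = [], [], []
    calls = np.full((n_ind, n_loci, 2), MISSING, dtype=np.int64)
    for i in range(n_ind):
        top, bot = lines[2 * i], lines[2 * i + 1]
        if top[0] != bot[0]:
            raise GenotypeFormatError(
                f"row pair {i + 1}: ids {top[0]!r} and {bot[0]!r} differ"
            )
        ids.append(top[0])
        block, _, plot = top[1].partition(":")
        blocks.append(block)
        plots.append(plot if plot else block)
        for j in range(n_loci):
            calls[i, j, 0] = _parse_allele(top[2 + j], 2 * i + 1, 2 + j)
            calls[i, j, 1] = _parse_allele(bot[2 + j], 2 * i + 2, 2 + j)
    individuals = pd.DataFrame(
        {"id": ids, "block": blocks, "plot": plots, "timepoint": "none"}
    )
    return GenotypeTable(individuals, [f"L{j + 1}" for j in range(n_loci)], calls)


# ----------------------------------------------------------------- QC & stats


def filter_missing(
    table: GenotypeTable, max_missing_fraction: float
) -> tuple[GenotypeTable, list[str]]:
    """Drop individuals whose untyped-locus fraction exceeds the threshold.

    The comparison is strict (``> max_missing_fraction`` removes), so an
    individual exactly at the threshold is retained. Returns the filtered
    table and the removed ids; the input table is not modified.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = table.missing_fraction()
    keep = frac <= max_missing_fraction + 1e-12
    removed = list(table.individuals.loc[~keep, "id"])
    return table.subset(keep), removed


def allele_counts(
    table: GenotypeTable, level: str = "all"
) -> dict[str, dict[str, dict[int, int]]]:
    """Per-group, per-locus counts of allele copies (missing excluded)."""
    labels = table.group_labels(level)
    typed = table.typed_mask()
    out: dict[str, dict[str, dict[int, int]]] = {}
    for group in dict.fromkeys(labels):
        rows = labels == group
        out[group] = {}
        for j, locus in enumerate(table.loci):
            copies = table.calls[rows, j][typed[rows, j]].ravel()
            vals, counts = np.unique(copies, return_counts=True)
            out[group][locus] = {int(v): int(c) for v, c in zip(vals, counts)}
    return out


def allele_frequencies(
    table: GenotypeTable, level: str = "all"
) -> dict[str, dict[str, dict[int, float]]]:
    """Per-group, per-locus allele frequencies over typed allele copies.

    A locus with no typed individual in a group maps to an empty dict
    (flagged absent); otherwise frequencies sum to 1 within the locus/group.
    """
    counts = allele_counts(table, level)
    freqs: dict[str, dict[str, dict[int, float]]] = {}
    for group, by_locus in counts.items():
        freqs[group] = {}
        for locus, cnt in by_locus.items():
            total = sum(cnt.values())
            freqs[group][locus] = (
                {a: c / total for a, c in cnt.items()} if total else {}
            )
    return freqs
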