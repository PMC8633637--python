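"""Per-group genetic diversity statistics.

For each group at a chosen hierarchy level: mean alleles per locus (A),
private allele counts (A_P), rarefied allelic richness (A_R, the
hypergeometric expectation of distinct alleles in a standardized subsample
of gene copies), observed and expected heterozygosity (H_O, Nei gene
diversity H_E = 1 - sum p_i^2), and the inbreeding coefficient
F = (H_E - H_O)/H_E.

Group means over loci are unweighted; loci with no typed data in a group
are excluded from the H_O/H_E/F means but count 0 toward A (the convention
of the common spreadsheet tooling for codominant data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_core import GenotypeTable, allele_counts


@dataclass
class DiversitySummary:
    """One group's diversity summary (one row of a Table-2-style report)."""

    group_id: str
    n: int
    a_mean: float
    a_rarefied: float
    a_private: int
    h_obs: float
    h_exp: float
    f_mean_of_loci: float
    f_from_means: float


# ------------------------------------------------------------------ operations


def mean_alleles(table: GenotypeTable, level: str = "all") -> dict[str, float]:
    """Per-group mean number of distinct alleles per locus.

    A locus entirely missing in a group contributes 0 alleles to the mean.
    """
    counts = allele_counts(table, level)
    return {
        g: float(np.mean([len(c) for c in by_locus.values()]))
        for g, by_locus in counts.items()
    }


def private_alleles(
    table: GenotypeTable, level: str
) -> tuple[dict[str, int], dict[str, list[tuple[str, int]]]]:
    """Alleles present in exactly one group at the given level.

    Returns per-group counts and the (locus, allele) lists themselves.
    """
    counts = allele_counts(table, level)
    groups = list(counts)
    if len(groups) < 2:
        raise ValueError("private alleles need at least two groups")
    carriers: dict[tuple[str, int], list[str]] = {}
    for g in groups:
        for locus, cnt in counts[g].items():
            for a in cnt:
                carriers.setdefault((locus, a), []).append(g)
    lists: dict[str, list[tuple[str, int]]] = {g: [] for g in groups}
    for (locus, a), gs in carriers.items():
        if len(gs) == 1:
            lists[gs[0]].append((locus, a))
    return {g: len(v) for g, v in lists.items()}, lists


def rarefied_allele_count(copy_counts: dict[int, int], g: int) -> float:
    """Expected distinct alleles in a subsample of ``g`` gene copies.

    Hypergeometric rarefaction: ``sum_i [1 - C(N - N_i, g)/C(N, g)]`` over
    alleles with ``N_i`` copies out of ``N`` typed copies.
    """
    n_total = sum(copy_counts.values())
    if not 1 <= g <= n_total:
        raise ValueError(f"subsample size {g} outside [1, {n_total}]")
    denom = math.comb(n_total, g)
    return float(
        sum(1.0 - math.comb(n_total - ni, g) / denom for ni in copy_counts.values())
    )


def rarefied_richness(
    table: GenotypeTable, level: str = "all", standard_n: int | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-group, per-locus and mean rarefied allelic richness A_R.

    ``standard_n`` is a number of individuals; the gene-copy subsample size
    is ``2 * standard_n``. Default: the smallest per-group, per-locus typed
    sample across the dataset, so every cell is computable. Cells whose
    typed copy count falls below the standard size are NaN and excluded
    from group means.
    """
    counts = allele_counts(table, level)
    typed_copies = {
        g: {loc: sum(c.values()) for loc, c in by.items()} for g, by in counts.items()
    }
    if standard_n is None:
        least = min(
            (n for by in typed_copies.values() for n in by.values() if n > 0),
            default=0,
        )
        g_copies = max(least, 1)
    else:
        if standard_n < 1:
            raise ValueError("standard_n must be >= 1")
        g_copies = 2 * standard_n
    records = []
    for group, by_locus in counts.items():
        for locus, cnt in by_locus.items():
            n = typed_copies[group][locus]
            value = rarefied_allele_count(cnt, g_copies) if n >= g_copies and n else np.nan
            records.append({"group": group, "locus": locus, "a_r": value})
    per_locus = pd.DataFrame(records)
    means = {
        g: float(sub["a_r"].mean())
        for g, sub in per_locus.groupby("group", sort=False)
    }
    return per_locus, means


def heterozygosity(
    table: GenotypeTable, level: str = "all", unbiased: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group per-locus and mean observed / expected heterozygosity.

    H_O = heterozygotes / typed individuals; H_E = 1 - sum p_i^2 over the
    group's allele frequencies (Nei gene diversity; ``unbiased`` applies
    the 2N/(2N-1) small-sample correction). Group means are unweighted
    over loci with data.
    """
    labels = table.group_labels(level)
    typed = table.typed_mask()
    het = typed & (table.calls[:, :, 0] != table.calls[:, :, 1])
    records = []
    for group in dict.fromkeys(labels):
        rows = labels == group
        for j, locus in enumerate(table.loci):
            n_typed = int(typed[rows, j].sum())
            if n_typed == 0:
                records.append(
                    {"group": group, "locus": locus, "n_typed": 0,
                     "h_obs": np.nan, "h_exp": np.nan}
                )
                continue
            h_obs = het[rows, j].sum() / n_typed
            copies = table.calls[rows, j][typed[rows, j]].ravel()
            _, cnt = np.unique(copies, return_counts=True)
            p = cnt / cnt.sum()
            h_exp = 1.0 - float(np.sum(p**2))
            if unbiased:
                h_exp *= (2 * n_typed) / (2 * n_typed - 1) if n_typed > 0 else 1.0
            records.append(
                {"group": group, "locus": locus, "n_typed": n_typed,
                 "h_obs": float(h_obs), "h_exp": h_exp}
            )
    per_locus = pd.DataFrame(records)
    means = (
        per_locus.groupby("group", sort=False)[["h_obs", "h_exp"]]
        .mean()
        .reset_index()
    )
    return per_locus, means


def inbreeding_coefficient(
    table: GenotypeTable, level: str = "all"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group inbreeding coefficient F = (H_E - H_O) / H_E.

    Loci with H_E = 0 are undefined (NaN). The group mean is reported two
    ways: the mean of defined per-locus F values, and F recomputed from the
    group's mean H_O and H_E (the two conventions common across tools).
    """
    per_locus, _ = heterozygosity(table, level)
    per_locus = per_locus.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (per_locus["h_exp"] - per_locus["h_obs"]) / per_locus["h_exp"]
    per_locus["f"] = f.where(per_locus["h_exp"] > 0)
    rows = []
    for group, sub in per_locus.groupby("group", sort=False):
        mh_obs, mh_exp = sub["h_obs"].mean(), sub["h_exp"].mean()
        rows.append(
            {
                "group": group,
                "f_mean_of_loci": float(sub["f"].mean()),
                "f_from_means": float(1.0 - mh_obs / mh_exp) if mh_exp > 0 else np.nan,
            }
        )
    return per_locus, pd.DataFrame(rows)


def summarize(
    table: GenotypeTable,
    level: str = "block",
    rarefaction_n: int | None = None,
    private_level: str | None = None,
) -> pd.DataFrame:
    """Table-2-style diversity report: one row per group.

    Columns: N, H_O, H_E, A, A_R, A_P, F (both conventions). ``private_level``
    defaults to ``level``; with a single group A_P is reported as 0.
    """
    labels = table.group_labels(level)
    _, het_means = heterozygosity(table, level)
    het_means = het_means.set_index("group")
    a_mean = mean_alleles(table, level)
    _, ar_means = rarefied_richness(table, level, rarefaction_n)
    _, f_means = inbreeding_coefficient(table, level)
    f_means = f_means.set_index("group")
    groups = list(dict.fromkeys(labels))
    try:
        ap_counts, _ = private_alleles(table, private_level or level)
    except ValueError:
        ap_counts = {g: 0 for g in groups}
    rows = []
    for g in groups:
        rows.append(
            DiversitySummary(
                group_id=g,
                n=int((labels == g).sum()),
                a_mean=a_mean[g],
                a_rarefied=ar_means[g],
                a_private=ap_counts[g],
                h_obs=float(het_means.loc[g, "h_obs"]),
                h_exp=float(het_means.loc[g, "h_exp"]),
                f_mean_of_loci=float(f_means.loc[g, "f_mean_of_loci"]),
                f_from_means=float(f_means.loc[g, "f_from_means"]),
            ).__dict__
        )
    return pd.DataFrame(rows)
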