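"""Hierarchical analysis of molecular variance (AMOVA) for codominant data.

Partitions genetic variance over a four-level nested hierarchy — among
blocks, among plots within blocks, among individuals within plots, within
individuals — from allele-identity distances (infinite-allele model: two
allele copies are distance 0 if identical, 1 otherwise, summed over loci;
no stepwise/size assumption). Each individual contributes two allele
copies per locus. Sums of squares follow the distance decomposition

    SS(cluster) = (1/n) * sum_{i<j in cluster} d^2(i, j)

with n the cluster's allele-copy count and d^2 summed over loci typed in
both individuals (pair deletion). Variance components are solved from
expected mean squares top-down with unequal-sample-size coefficients
computed from the actual design; degrees of freedom come from the design
(individuals), not from typed loci.

F-statistics: F_RT = s2_a/s2_tot, F_SR = s2_b/(s2_b+s2_c+s2_d),
F_ST = (s2_a+s2_b)/s2_tot, F_IS = s2_c/(s2_c+s2_d),
F_IT = (s2_a+s2_b+s2_c)/s2_tot. Permutation tests shuffle units at the
stratum appropriate to each statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_core import MISSING, GenotypeTable

F_STATS = ("f_rt", "f_sr", "f_st", "f_is", "f_it")


@dataclass
class AmovaResult:
    levels: pd.DataFrame  # level, df, ss, ms, variance, percent
    f_stats: dict[str, float]
    n_individuals: int
    include_within_individual: bool
    truncated: bool
    p_values: dict[str, float] = field(default_factory=dict)

    @property
    def variance_components(self) -> dict[str, float]:
        return dict(zip(self.levels["level"], self.levels["variance"]))


def _cluster_ss(calls: np.ndarray, typed: np.ndarray, members: np.ndarray) -> float:
    """Distance SS of one cluster of individuals (allele-copy units)."""
    n_copies = 2 * len(members)
    if n_copies < 2:
        return 0.0
    total_pairs_diff = 0.0
    sub = calls[members]  # (m, L, 2)
    sub_typed = typed[members]
    for j in range(calls.shape[1]):
        copies = sub[sub_typed[:, j], j].ravel()
        n = len(copies)
        if n < 2:
            continue
        _, cnt = np.unique(copies, return_counts=True)
        same = (cnt * (cnt - 1) // 2).sum()
        total_pairs_diff += n * (n - 1) / 2 - same
    return float(total_pairs_diff) / n_copies


def _within_individual_ss(calls: np.ndarray, typed: np.ndarray) -> float:
    het = typed & (calls[:, :, 0] != calls[:, :, 1])
    return float(het.sum()) / 2.0


def _decompose(
    calls: np.ndarray, typed: np.ndarray, blocks: np.ndarray, plots: np.ndarray
) -> dict:
    """SS, df, EMS coefficients and variance components for the 4 levels."""
    n = len(calls)
    block_ids = list(dict.fromkeys(blocks))
    plot_ids = list(dict.fromkeys(plots))
    n_b, n_p = len(block_ids), len(plot_ids)
    if n_b < 2:
        raise ValueError("AMOVA needs at least two blocks at the top level")

    all_idx = np.arange(n)
    ss_total = _cluster_ss(calls, typed, all_idx)
    ss_wb = sum(
        _cluster_ss(calls, typed, np.flatnonzero(blocks == b)) for b in block_ids
    )
    ss_wp = sum(
        _cluster_ss(calls, typed, np.flatnonzero(plots == p)) for p in plot_ids
    )
    ss_wi = _within_individual_ss(calls, typed)

    ss = {
        "among_blocks": ss_total - ss_wb,
        "among_plots": ss_wb - ss_wp,
        "among_individuals": ss_wp - ss_wi,
        "within_individuals": ss_wi,
    }
    df = {
        "among_blocks": n_b - 1,
        "among_plots": n_p - n_b,
        "among_individuals": n - n_p,
        "within_individuals": n,
    }
    ms = {k: (ss[k] / df[k] if df[k] > 0 else np.nan) for k in ss}

    # unequal-size EMS coefficients; units are allele copies (2 per individual)
    m_total = 2 * n
    m_plot = {p: 2 * int((plots == p).sum()) for p in plot_ids}
    m_block = {b: 2 * int((blocks == b).sum()) for b in block_ids}
    plot_block = {p: blocks[plots == p][0] for p in plot_ids}
    sum_mp2_in_b = {
        b: sum(m_plot[p] ** 2 for p in plot_ids if plot_block[p] == b)
        for b in block_ids
    }
    term_pb = sum(sum_mp2_in_b[b] / m_block[b] for b in block_ids)
    term_p = sum(m ** 2 for m in m_plot.values()) / m_total
    term_b = sum(m ** 2 for m in m_block.values()) / m_total
    k_b2 = (m_total - term_pb) / df["among_plots"] if df["among_plots"] > 0 else np.nan
    k_a2 = (term_pb - term_p) / df["among_blocks"]
    k_a3 = (m_total - term_b) / df["among_blocks"]

    var_d = ms["within_individuals"]
    var_c = (
        (ms["among_individuals"] - var_d) / 2.0
        if df["among_individuals"] > 0
        else 0.0
    )
    var_b = (
        (ms["among_plots"] - var_d - 2.0 * var_c) / k_b2
        if df["among_plots"] > 0
        else 0.0
    )
    var_a = (ms["among_blocks"] - var_d - 2.0 * var_c - k_a2 * var_b) / k_a3
    return {
        "ss": ss,
        "df": df,
        "ms": ms,
        "var": {
            "among_blocks": var_a,
            "among_plots": var_b,
            "among_individuals": var_c,
            "within_individuals": var_d,
        },
    }


def _f_statistics(var: dict[str, float]) -> dict[str, float]:
    a, b = var["among_blocks"], var["among_plots"]
    c, d = var["among_individuals"], var["within_individuals"]
    tot = a + b + c + d
    out = {}
    out["f_rt"] = a / tot if tot > 0 else np.nan
    out["f_sr"] = b / (b + c + d) if (b + c + d) > 0 else np.nan
    out["f_st"] = (a + b) / tot if tot > 0 else np.nan
    out["f_is"] = c / (c + d) if (c + d) > 0 else np.nan
    out["f_it"] = (a + b + c) / tot if tot > 0 else np.nan
    return out


def amova(
    table: GenotypeTable,
    include_within_individual: bool = True,
    truncate_negative: bool = False,
) -> AmovaResult:
    """Four-level nested AMOVA on a block > plot > individual hierarchy.

    With ``include_within_individual=False`` the among-individual and
    within-individual levels are pooled into one "within plots" level
    (components summed, df merged); upper levels are unchanged.

    ``truncate_negative`` clamps negative variance components to zero for
    the percent column (raw components are always reported in
    ``variance``); by default percents are computed from raw components.
    """
    blocks = table.group_labels("block")
    plots = table.group_labels("plot")
    typed = table.typed_mask()
    dec = _decompose(table.calls, typed, blocks, plots)
    f_stats = _f_statistics(dec["var"])

    order = ["among_blocks", "among_plots", "among_individuals", "within_individuals"]
    ss, df, ms, var = dec["ss"], dec["df"], dec["ms"], dec["var"]
    if not include_within_individual:
        ss = dict(ss)
        df = dict(df)
        var = dict(var)
        ss["within_plots"] = ss.pop("among_individuals") + ss.pop("within_individuals")
        df["within_plots"] = df.pop("among_individuals") + df.pop("within_individuals")
        var["within_plots"] = var.pop("among_individuals") + var.pop(
            "within_individuals"
        )
        ms = {k: (ss[k] / df[k] if df[k] > 0 else np.nan) for k in ss}
        order = ["among_blocks", "among_plots", "within_plots"]
        f_stats = {k: f_stats[k] for k in ("f_rt", "f_sr", "f_st")}

    pct_base = {k: (max(v, 0.0) if truncate_negative else v) for k, v in var.items()}
    tot = sum(pct_base.values())
    levels = pd.DataFrame(
        {
            "level": order,
            "df": [df[k] for k in order],
            "ss": [ss[k] for k in order],
            "ms": [ms[k] for k in order],
            "variance": [var[k] for k in order],
            "percent": [
                (100.0 * pct_base[k] / tot if tot > 0 else np.nan) for k in order
            ],
        }
    )
    return AmovaResult(
        levels=levels,
        f_stats=f_stats,
        n_individuals=table.n_individuals,
        include_within_individual=include_within_individual,
        truncated=truncate_negative,
    )


# ----------------------------------------------------------- permutations


def _fstats_from_labels(calls, typed, blocks, plots) -> dict[str, float]:
    return _f_statistics(_decompose(calls, typed, blocks, plots)["var"])


def amova_permutation_test(
    result: AmovaResult,
    table: GenotypeTable,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    statistics: tuple[str, ...] = ("f_rt", "f_sr", "f_is"),
) -> dict[str, float]:
    """Permutation p-values for the F-statistics.

    Permutation strata: whole plots among blocks (F_RT); individuals among
    plots within their block (F_SR); individuals among all plots (F_ST);
    allele copies among individuals within plots, per locus (F_IS); allele
    copies among all individuals, per locus (F_IT). The within-individual
    stratum carries no information for F_IS because copy order within an
    individual is meaningless, so copies are exchanged between individuals
    of the same plot. p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    blocks = table.group_labels("block")
    plots = table.group_labels("plot")
    typed = table.typed_mask()
    calls = table.calls
    obs = {k: result.f_stats[k] for k in statistics}
    exceed = dict.fromkeys(statistics, 0)
    plot_ids = np.array(list(dict.fromkeys(plots)), dtype=object)
    plot_block = np.array([blocks[plots == p][0] for p in plot_ids], dtype=object)

    for _ in range(n_perm):
        for stat in statistics:
            if stat == "f_rt":
                # shuffle block membership over whole plots
                perm_pb = plot_block[rng.permutation(len(plot_ids))]
                lookup = dict(zip(plot_ids, perm_pb))
                new_blocks = np.array([lookup[p] for p in plots], dtype=object)
                f = _fstats_from_labels(calls, typed, new_blocks, plots)["f_rt"]
            elif stat == "f_sr":
                new_plots = plots.copy()
                for b in dict.fromkeys(blocks):
                    rows = np.flatnonzero(blocks == b)
                    new_plots[rows] = new_plots[rows[rng.permutation(len(rows))]]
                f = _fstats_from_labels(calls, typed, blocks, new_plots)["f_sr"]
            elif stat == "f_st":
                perm = rng.permutation(len(plots))
                f = _fstats_from_labels(calls, typed, blocks[perm], plots[perm])["f_st"]
            elif stat == "f_is":
                new_calls = calls.copy()
                for p in plot_ids:
                    rows = np.flatnonzero(plots == p)
                    for j in range(calls.shape[1]):
                        t = rows[typed[rows, j]]
                        if len(t) < 2:
                            continue
                        copies = new_calls[t, j].ravel()
                        new_calls[t, j] = rng.permutation(copies).reshape(-1, 2)
                f = _fstats_from_labels(new_calls, typed, blocks, plots)["f_is"]
            elif stat == "f_it":
                new_calls = calls.copy()
                for j in range(calls.shape[1]):
                    t = np.flatnonzero(typed[:, j])
                    if len(t) < 2:
                        continue
                    copies = new_calls[t, j].ravel()
                    new_calls[t, j] = rng.permutation(copies).reshape(-1, 2)
                f = _fstats_from_labels(new_calls, typed, blocks, plots)["f_it"]
            else:
                raise ValueError(f"unknown statistic {stat!r}")
            if np.isfinite(f) and np.isfinite(obs[stat]) and f >= obs[stat] - 1e-12:
                exceed[stat] += 1
    return {k: (1 + exceed[k]) / (n_perm + 1) for k in statistics}
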