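"""Summaries of externally estimated cluster-membership (Q) matrices.

Bayesian clustering programs emit, per individual, a vector of membership
proportions over K clusters. This module does not estimate those
memberships; it summarizes them per plot: the predominant cluster (the
modal argmax assignment), the percentage of the plot's individuals whose
greatest assignment is to that cluster, and the mean membership in it
(average admixture proportion), plus pre/post comparisons across matched
plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class QMatrixFormatError(ValueError):
    """Raised when a membership matrix violates its format contract."""


@dataclass
class QMatrix:
    """Per-individual cluster membership proportions with hierarchy labels."""

    individuals: pd.DataFrame  # id, block, plot, timepoint
    memberships: np.ndarray  # (n, K), rows sum to 1

    def __post_init__(self) -> None:
        self.individuals = self.individuals.reset_index(drop=True)
        self.memberships = np.asarray(self.memberships, dtype=float)
        if self.memberships.ndim != 2 or len(self.memberships) != len(self.individuals):
            raise QMatrixFormatError("memberships shape does not match individuals")
        sums = self.memberships.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-3)
        if len(bad):
            raise QMatrixFormatError(
                f"membership rows do not sum to 1 (first offender: row {bad[0] + 1}, "
                f"sum {sums[bad[0]]:.4f})"
            )
        self.memberships = self.memberships / sums[:, None]

    @property
    def k(self) -> int:
        return self.memberships.shape[1]

    def plot_labels(self) -> np.ndarray:
        return (
            self.individuals["block"].astype(str)
            + ":"
            + self.individuals["plot"].astype(str)
        ).to_numpy(dtype=object)


def read_qmatrix(path) -> QMatrix:
    """Read a membership matrix from a labelled CSV or a whitespace table.

    Labelled CSV: columns ``id, block, plot[, timepoint], Q1..QK``.
    Whitespace table (CLUMPAK/STRUCTURE-like): ``id plot q1 ... qK`` per
    row, the plot field optionally ``block:plot``. Rows are renormalized
    when within 1e-3 of summing to 1, otherwise a format error is raised.
    """
    with open(path) as fh:
        text = fh.read()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    if "," in first:
        df = pd.read_csv(path)
        qcols = [c for c in df.columns if c.lower().startswith("q")]
        if not qcols:
            raise QMatrixFormatError("no Q columns found in CSV")
        ind = pd.DataFrame(
            {
                "id": df["id"].astype(str),
                "block": df.get("block", pd.Series(["all"] * len(df))).astype(str),
                "plot": df.get("plot", pd.Series(["all"] * len(df))).astype(str),
                "timepoint": df.get(
                    "timepoint", pd.Series(["none"] * len(df))
                ).astype(str),
            }
        )
        return QMatrix(ind, df[qcols].to_numpy(dtype=float))
    rows = [ln.split() for ln in text.splitlines() if ln.strip()]
    ids, blocks, plots, q = [], [], [], []
    for r in rows:
        if len(r) < 3:
            raise QMatrixFormatError(f"row {r!r} too short")
        ids.append(r[0])
        block, _, plot = r[1].partition(":")
        blocks.append(block)
        plots.append(plot if plot else block)
        try:
            q.append([float(x) for x in r[2:]])
        except ValueError:
            raise QMatrixFormatError(f"non-numeric membership in row for {r[0]!r}") from None
    ind = pd.DataFrame({"id": ids, "block": blocks, "plot": plots, "timepoint": "none"})
    return QMatrix(ind, np.asarray(q))


def write_qmatrix(q: QMatrix, path) -> None:
    """Write the labelled-CSV dialect accepted by :func:`read_qmatrix`."""
    df = q.individuals[["id", "block", "plot", "timepoint"]].copy()
    for j in range(q.k):
        df[f"Q{j + 1}"] = q.memberships[:, j]
    df.to_csv(path, index=False)


def _plot_rows(q: QMatrix, plot: str) -> np.ndarray:
    labels = q.plot_labels()
    rows = np.flatnonzero((labels == plot) | (q.individuals["plot"].astype(str) == plot))
    if not len(rows):
        raise ValueError(f"plot {plot!r} is empty or unknown")
    return rows


def predominant_cluster(q: QMatrix, plot: str) -> int:
    """Modal argmax cluster of a plot's individuals (0-based index).

    Ties on the count are broken by higher mean membership in the tied
    cluster, then by lower cluster index.
    """
    rows = _plot_rows(q, plot)
    peaks = q.memberships[rows].argmax(axis=1)
    counts = np.bincount(peaks, minlength=q.k)
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if len(tied) == 1:
        return int(tied[0])
    means = q.memberships[rows].mean(axis=0)
    order = sorted(tied, key=lambda c: (-means[c], c))
    return int(order[0])


def percent_assigned(q: QMatrix, plot: str) -> float:
    """% of the plot's individuals whose greatest assignment is the predominant cluster."""
    rows = _plot_rows(q, plot)
    c = predominant_cluster(q, plot)
    peaks = q.memberships[rows].argmax(axis=1)
    return float(100.0 * (peaks == c).mean())


def mean_admixture(q: QMatrix, plot: str) -> float:
    """Unweighted mean membership in the predominant cluster over the plot."""
    rows = _plot_rows(q, plot)
    c = predominant_cluster(q, plot)
    return float(q.memberships[rows, c].mean())


def summarize_plots(q: QMatrix) -> pd.DataFrame:
    """Per-plot predominant cluster, % assigned and mean admixture."""
    labels = q.plot_labels()
    rows = []
    for plot in dict.fromkeys(labels):
        rows.append(
            {
                "plot": plot,
                "n": int((labels == plot).sum()),
                "predominant_cluster": predominant_cluster(q, plot),
                "percent_assigned": percent_assigned(q, plot),
                "mean_admixture": mean_admixture(q, plot),
            }
        )
    return pd.DataFrame(rows)


def pre_post_delta(
    q_pre: QMatrix, q_post: QMatrix
) -> tuple[pd.DataFrame, dict[str, float], list[str]]:
    """Per-plot pre/post change in % assigned and mean admixture.

    Plots are matched by label; unmatched plots are listed and excluded.
    Returns the per-plot table, across-plot unweighted averages (including
    mean deltas), and the unmatched plot labels. Assumes both matrices come
    from one joint clustering run (consistent cluster labels).
    """
    pre = summarize_plots(q_pre).set_index("plot")
    post = summarize_plots(q_post).set_index("plot")
    shared = [p for p in pre.index if p in post.index]
    unmatched = sorted(set(pre.index).symmetric_difference(post.index))
    rows = []
    for p in shared:
        rows.append(
            {
                "plot": p,
                "pre_percent_assigned": pre.loc[p, "percent_assigned"],
                "post_percent_assigned": post.loc[p, "percent_assigned"],
                "delta_percent_assigned": post.loc[p, "percent_assigned"]
                - pre.loc[p, "percent_assigned"],
                "pre_mean_admixture": pre.loc[p, "mean_admixture"],
                "post_mean_admixture": post.loc[p, "mean_admixture"],
                "delta_mean_admixture": post.loc[p, "mean_admixture"]
                - pre.loc[p, "mean_admixture"],
            }
        )
    table = pd.DataFrame(rows)
    averages = (
        {c: float(table[c].mean()) for c in table.columns if c != "plot"}
        if len(table)
        else {}
    )
    return table, averages, unmatched


def match_clusters(q_pre: QMatrix, q_post: QMatrix) -> QMatrix:
    """Greedy column matcher for matrices from separate runs (optional).

    Reorders the post matrix's clusters to maximize, greedily, the
    correlation with the pre matrix's columns over shared individuals
    (matched by id). Not needed for joint runs.
    """
    if q_pre.k != q_post.k:
        raise ValueError("cluster counts differ")
    pre_ids = {i: r for r, i in enumerate(q_pre.individuals["id"].astype(str))}
    shared = [
        (pre_ids[i], r)
        for r, i in enumerate(q_post.individuals["id"].astype(str))
        if i in pre_ids
    ]
    if not shared:
        raise ValueError("no shared individual ids to match on")
    a = q_pre.memberships[[s[0] for s in shared]]
    b = q_post.memberships[[s[1] for s in shared]]
    k = q_pre.k
    corr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            sa, sb = np.std(a[:, i]), np.std(b[:, j])
            corr[i, j] = (
                np.corrcoef(a[:, i], b[:, j])[0, 1] if sa > 0 and sb > 0 else -np.inf
            )
    perm = [-1] * k
    used = set()
    for i in np.argsort(-corr.max(axis=1)):
        j = max(
            (j for j in range(k) if j not in used), key=lambda j: corr[i, j]
        )
        perm[i] = j
        used.add(j)
    return QMatrix(q_post.individuals.copy(), q_post.memberships[:, perm])
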