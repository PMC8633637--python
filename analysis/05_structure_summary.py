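#!/usr/bin/env python
"""Admixture and cluster-assignment change between timepoints.

Summarizes the pre and post cluster-membership matrices per plot
(predominant cluster, % of individuals assigned to it, mean admixture
proportion) and their per-plot deltas. Writes
results/structure_prepost.tsv and results/structure_averages.json.
"""

import argparse
import json
from pathlib import Path

from pyrodiv.structure_summary import pre_post_delta, read_qmatrix

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--outdir", type=Path, default=ROOT / "results")
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    q_pre = read_qmatrix(args.datadir / "q_pre.csv")
    q_post = read_qmatrix(args.datadir / "q_post.csv")
    table, averages, unmatched = pre_post_delta(q_pre, q_post)
    table.to_csv(args.outdir / "structure_prepost.tsv", sep="\t", index=False)
    (args.outdir / "structure_averages.json").write_text(
        json.dumps({"averages": averages, "unmatched_plots": unmatched}, indent=2)
    )
    if unmatched:
        print(f"excluded unmatched plots: {unmatched}")
    print(
        f"average % assigned to predominant cluster: "
        f"{averages['pre_percent_assigned']:.1f}% pre -> "
        f"{averages['post_percent_assigned']:.1f}% post; "
        f"mean admixture delta {averages['delta_mean_admixture']:+.3f}"
    )


if __name__ == "__main__":
    main()
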