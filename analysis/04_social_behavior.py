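#!/usr/bin/env python
"""Compute pair metrics for the simulated fish pairs and compare groups.

Reads the trajectories and manifest from step 01, computes the nine
individual and pair metrics per fish pair, and runs the homotypic (S),
heterotypic (D) and pair-type (HM/HD) rank-sum comparison scheme.
"""

import json
from pathlib import Path

import pandas as pd

from mexphen.social import (Arena, compute_pair_metrics, pair_comparison,
                            read_trajectory_csv)

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    manifest = json.loads((DATA / "pairs_manifest.json").read_text())
    frames = []
    for entry in manifest:
        pair = read_trajectory_csv(
            DATA / f"{entry['pair_id']}.csv", fps=entry["fps"],
            genotypes=tuple(entry["genotypes"]),
            arena=Arena(radius_cm=entry["arena_radius_cm"]),
            pair_id=entry["pair_id"])
        frames.append(compute_pair_metrics(pair))
    metrics = pd.concat(frames, ignore_index=True)
    metrics.to_csv(OUT / "pair_metrics.tsv", sep="\t", index=False)
    print(f"{metrics['pair_id'].nunique()} pairs, "
          f"{len(metrics)} fish rows")
    print("\nmedian per genotype within heterotypic pairs:")
    het = metrics[metrics["pair_type"] == "HetDel"]
    print(het.groupby("genotype")[["speed", "ratio_in_front",
                                   "neighbor_distance"]].median().round(3))

    comparisons = pair_comparison(metrics)
    comparisons.to_csv(OUT / "pair_comparisons.tsv", sep="\t", index=False)
    print("\ncomparison scheme results:")
    print(comparisons.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
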