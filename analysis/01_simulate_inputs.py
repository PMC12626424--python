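#!/usr/bin/env python
"""Generate the synthetic inputs used by every downstream analysis step.

Writes, under results/data/: a PSI table with a planted neural-enriched
event class plus its tissue-group config, a simulated larval activity
clutch (WT/Het/Del with a planted Del baseline increase), a set of
leader-follower fish-pair trajectories, and per-line WT/Del count
matrices with a planted coordinately shifted pathway.
"""

import json
from pathlib import Path

import pandas as pd

from mexphen import social as soc, splicing as spl, synthetic as syn

OUT = Path("results/data")
SEED = 20250929


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cfg = syn.SimConfig(seed=SEED)
    table, groups, labels = syn.gen_psi_table(cfg)
    spl.write_psi_table(table, OUT / "psi_table.tsv")
    spl.write_group_config(groups, OUT / "psi_groups.tsv")
    labels.to_csv(OUT / "psi_truth.tsv", sep="\t")
    print(f"PSI table: {table.psi.shape[0]} events x {table.psi.shape[1]} samples, "
          f"{(labels['truth'] == 'neural').sum()} planted neural events")

    effects = {"Del": syn.GenotypeEffects(baseline_mult=1.5)}
    traces = syn.gen_activity_experiment(cfg, effects)
    rows, zrows = [], []
    for t in traces:
        rows.extend((t.trial, t.larva_id, s, a) for s, a in enumerate(t.activity))
        for m in t.zone_tdm.index:
            for zone in ("center", "periphery"):
                zrows.append((t.trial, t.larva_id, m, zone,
                              t.zone_tdm.loc[m, zone], t.zone_activity.loc[m, zone]))
    pd.DataFrame(rows, columns=["trial", "larva_id", "time_s", "activity_pct"]
                 ).to_csv(OUT / "activity_trace.csv", index=False)
    pd.DataFrame(zrows, columns=["trial", "larva_id", "minute", "zone",
                                 "tdm_mm", "activity_pct"]
                 ).to_csv(OUT / "activity_zones.csv", index=False)
    print(f"Activity: {len(traces)} larvae with a 1.5x Del baseline effect")

    manifest = []
    for i, (pt, genos) in enumerate([("HetHet", ("Het", "Het")),
                                     ("HetDel", ("Het", "Del")),
                                     ("DelDel", ("Del", "Del"))] * 4):
        gain = 2.0 if "Del" not in genos else 0.8  # Del fish follow less
        pair_id = f"pair{i:03d}_{pt}"
        pair = syn.gen_pair_trajectories(
            syn.SimConfig(seed=SEED, n_frames=6000, follow_gain=gain),
            genotypes=genos, pair_id=pair_id, pair_index=i)
        soc.write_trajectory_csv(pair, OUT / f"{pair_id}.csv")
        manifest.append({"pair_id": pair_id, "genotypes": list(genos),
                         "fps": 30.0, "arena_radius_cm": 21.0})
    (OUT / "pairs_manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"Trajectories: {len(manifest)} pairs (weaker coupling in Del pairs)")

    counts, sheet, truth = syn.gen_expression_counts(
        syn.SimConfig(seed=SEED, pathway_shift=1.5), host_shift=1.0)
    counts.to_csv(OUT / "counts.tsv", sep="\t")
    sheet.to_csv(OUT / "samples.tsv", sep="\t")
    (OUT / "counts_truth.json").write_text(json.dumps(
        {"pathway_genes": truth["pathway_genes"],
         "shifted_lines": truth["shifted_lines"],
         "host_gene": {k: str(v) for k, v in truth["host_gene"].items()},
         "paralogs": {k: list(map(str, v)) for k, v in truth["paralogs"].items()}},
        indent=2))
    print(f"Counts: {counts.shape[0]} genes x {counts.shape[1]} samples, "
          f"planted pathway of {len(truth['pathway_genes'])} genes "
          f"shifted in {len(truth['shifted_lines'])} lines")


if __name__ == "__main__":
    main()
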