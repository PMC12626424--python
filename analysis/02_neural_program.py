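#!/usr/bin/env python
"""Call the neural exon program and reproduce its published arithmetic.

Part 1 runs the tissue-enriched caller on the synthetic PSI table from
step 01 and reports recovery of the planted neural class.  Part 2
feeds the published per-class tables of the 708 zebrafish neural exons
through the same reporting operations: length-class composition,
regulator-response fractions per class, and the two-sided Fisher test
for the association between length class and regulator response.
"""

from pathlib import Path

import pandas as pd

from mexphen.splicing import (affected_fraction, call_tissue_enriched,
                              classify_exon_length,
                              classify_regulator_response,
                              length_class_association,
                              length_class_composition, read_group_config,
                              read_psi_table)

DATA = Path("results/data")
OUT = Path("results")

NEURAL_EXON_COUNTS = {"micro_3_27": 246, "mid_28_51": 139, "long_gt51": 323}
AFFECTED_OF_COVERED = {"micro_3_27": (191, 243), "mid_28_51": (82, 136),
                       "long_gt51": (122, 317)}
REPRESENTATIVE_NT = {"micro_3_27": 12, "mid_28_51": 40, "long_gt51": 120}


def main() -> None:
    table = read_psi_table(DATA / "psi_table.tsv")
    groups = read_group_config(DATA / "psi_groups.tsv")
    truth = pd.read_csv(DATA / "psi_truth.tsv", sep="\t", index_col=0)

    calls = call_tissue_enriched(table, groups)
    calls.to_csv(OUT / "neural_calls.tsv", sep="\t")
    called = calls.index[calls["called"]]
    planted = truth.index[truth["truth"] == "neural"]
    tp = len(set(called) & set(planted))
    print(f"caller: {len(called)} called, {len(planted)} planted, "
          f"{tp} recovered ({100 * tp / len(planted):.1f}%)")

    lengths = [REPRESENTATIVE_NT[cls]
               for cls, n in NEURAL_EXON_COUNTS.items() for _ in range(n)]
    comp = length_class_composition(classify_exon_length(nt) for nt in lengths)
    comp.to_csv(OUT / "length_composition.tsv", sep="\t")
    print("\nlength-class composition of the 708 neural exons:")
    print(comp.round(1).to_string())

    rows = []
    for cls, (affected, covered) in AFFECTED_OF_COVERED.items():
        classes = [classify_regulator_response({"cmp": -30.0})] * affected \
            + [classify_regulator_response({"cmp": -5.0})] * (covered - affected)
        rows.append({"length_class": cls, "affected": affected,
                     "covered": covered,
                     "percent_affected": 100 * affected_fraction(classes)})
    resp = pd.DataFrame(rows).set_index("length_class")
    resp.to_csv(OUT / "regulator_response.tsv", sep="\t")
    print("\nregulator loss-of-function response (dPSI < -15):")
    print(resp.round(1).to_string())

    a_aff, a_cov = AFFECTED_OF_COVERED["micro_3_27"]
    l_aff, l_cov = AFFECTED_OF_COVERED["long_gt51"]
    odds, p = length_class_association(
        [[a_aff, a_cov - a_aff], [l_aff, l_cov - l_aff]])
    print(f"\nmicroexons vs long exons, affected vs not: "
          f"odds ratio {odds:.2f}, two-sided Fisher p = {p:.2e}")


if __name__ == "__main__":
    main()
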