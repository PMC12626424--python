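import numpy as np
import pandas as pd
import pytest

from mexphen.splicing import PsiTable, TissueGroupConfig


@pytest.fixture
def toy_psi_table():
    """Six tissue groups x 2 samples, three hand-crafted events.

    EV1: neural mean 80, all other groups 10 -> dpsi_target 70.
    EV2: neural mean 22, others 10 -> dpsi_target 12 (below threshold).
    EV3: coverage in only 4 groups -> ineligible.
    """
    groups = ["Neural", "Muscle", "Liver", "Heart", "Skin", "Gut"]
    samples = [f"{g}_{r}" for g in groups for r in (1, 2)]
    group_of = {s: s.rsplit("_", 1)[0] for s in samples}

    def row(neural, other):
        return [neural if group_of[s] == "Neural" else other for s in samples]

    psi = pd.DataFrame([row(80.0, 10.0), row(22.0, 10.0), row(80.0, 10.0)],
                       index=pd.Index(["EV1", "EV2", "EV3"], name="event_id"),
                       columns=samples)
    qual = pd.DataFrame("OK", index=psi.index, columns=samples)
    for s in samples:
        if group_of[s] in ("Skin", "Gut", "Heart"):
            qual.loc["EV3", s] = "N"
            psi.loc["EV3", s] = np.nan
    meta = pd.DataFrame({"gene_id": ["gA", "gB", "gC"],
                         "length_nt": [10, 40, 100]}, index=psi.index)
    table = PsiTable(meta=meta, psi=psi, quality=qual)
    config = TissueGroupConfig(group_of=group_of)
    return table, config
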