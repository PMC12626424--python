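"""Neural exon / microexon program calling from PSI tables.

A tissue-enriched ("neural") exon is called from an events x samples
percent-spliced-in (PSI) matrix with per-cell coverage-quality codes
(vast-tools INCLUSION-table style).  For a target tissue group the
caller requires

* a valid mean PSI in at least ``n_groups`` tissue groups (a group is
  valid when it has >= ``min_rep`` samples at coverage ``min_quality``
  or better),
* |dPSI target| >= ``min_dpsi``, where dPSI target is the target-group
  mean minus the unweighted mean of the other group means,
* |dPSI global| >= ``min_dpsi_glob``, where dPSI global is the target
  mean minus the mean over all pooled non-target samples,
* positive enrichment (configurable; neural programs are inclusion
  gains, not losses).

Groups listed in a sample-group config's EXCLUDED column for the target
(tissues with known partial overlap of microexon inclusion, e.g.
endocrine pancreas for a neural target) are dropped from both the
eligibility count and the comparison means.

Length classes follow the microexon convention: 3-27 nt microexons,
28-51 nt mid-size, >51 nt long; 1-2 nt events are invalid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "QUALITY_ORDER",
    "LENGTH_CLASSES",
    "PsiTable",
    "TissueGroupConfig",
    "CallingParams",
    "RegulationClass",
    "classify_exon_length",
    "call_tissue_enriched",
    "classify_regulator_response",
    "classify_conservation",
    "length_class_association",
    "length_class_composition",
    "affected_fraction",
    "impute_group_means",
    "read_psi_table",
    "write_psi_table",
    "read_group_config",
    "write_group_config",
]

#: coverage-quality codes, worst to best; N means insufficient coverage
QUALITY_ORDER: dict[str, int] = {"N": 0, "VLOW": 1, "LOW": 2, "OK": 3, "SOUND": 4}

LENGTH_CLASSES = ("micro_3_27", "mid_28_51", "long_gt51")


@dataclass
class PsiTable:
    """Events x samples PSI matrix with per-cell quality codes.

    ``meta`` is indexed by event id with columns ``gene_id`` and
    ``length_nt``; ``psi`` and ``quality`` share that index and the
    sample columns.  PSI values lie in [0, 100]; a PSI present at
    quality ``N`` is treated as missing.
    """

    meta: pd.DataFrame
    psi: pd.DataFrame
    quality: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.meta.index.equals(self.psi.index)
                and self.psi.index.equals(self.quality.index)):
            raise ValueError("meta/psi/quality must share the event index")
        if not self.psi.columns.equals(self.quality.columns):
            raise ValueError("psi and quality must share sample columns")
        vals = self.psi.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 100:
                raise ValueError("PSI values must lie in [0, 100]")
        bad = set(np.unique(self.quality.to_numpy(dtype=str))) - set(QUALITY_ORDER)
        if bad:
            raise ValueError(f"unknown quality codes: {sorted(bad)}")

    @property
    def events(self) -> pd.Index:
        return self.meta.index

    @property
    def samples(self) -> pd.Index:
        return self.psi.columns

    def valid_psi(self, min_quality: str = "VLOW") -> pd.DataFrame:
        """PSI with cells below ``min_quality`` (or missing) masked to NaN."""
        qmin = QUALITY_ORDER[min_quality]
        qnum = self.quality.apply(lambda c: c.map(QUALITY_ORDER))
        return self.psi.where(qnum >= qmin)


@dataclass
class TissueGroupConfig:
    """Sample -> tissue-group map with per-group target exclusions.

    ``excluded_for[g]`` is the set of *target* groups for which group
    ``g`` must be dropped from the comparison (partial inclusion
    overlap).
    """

    group_of: Mapping[str, str]
    excluded_for: Mapping[str, frozenset] = field(default_factory=dict)

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group_of.values():
            seen.setdefault(g)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.group_of.items() if g == group]

    def dropped_groups(self, target: str) -> set[str]:
        return {g for g, targets in self.excluded_for.items()
                if target in targets and g != target}


@dataclass(frozen=True)
class CallingParams:
    min_dpsi: float = 15.0
    min_dpsi_glob: float = 25.0
    n_groups: int = 5
    min_rep: int = 1
    min_quality: str = "VLOW"
    require_enrichment: bool = True  # direction: target must gain inclusion

    def __post_init__(self) -> None:
        if self.min_dpsi < 0 or self.min_dpsi_glob < 0:
            raise ValueError("dPSI thresholds must be >= 0")
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")
        if self.min_rep < 1:
            raise ValueError("min_rep must be >= 1")
        if self.min_quality not in QUALITY_ORDER:
            raise ValueError(f"unknown quality code {self.min_quality!r}")


@dataclass
class RegulationClass:
    """Response of an event to regulator loss-of-function.

    ``min_delta_psi`` is the lowest dPSI over all mutant-vs-control
    comparisons with coverage; the event is ``affected`` when that
    minimum is below -15 PSI.
    """

    min_delta_psi: Optional[float]
    cls: str  # affected | not_affected | no_coverage


def classify_exon_length(length_nt: int) -> str:
    """Length class of an exon: 3-27 micro, 28-51 mid, >51 long."""
    length_nt = int(length_nt)
    if length_nt < 3:
        raise ValueError(f"exon length {length_nt} nt below the 3 nt minimum")
    if length_nt <= 27:
        return "micro_3_27"
    if length_nt <= 51:
        return "mid_28_51"
    return "long_gt51"


def call_tissue_enriched(table: PsiTable, config: TissueGroupConfig,
                         params: CallingParams = CallingParams(),
                         target_group: str = "Neural") -> pd.DataFrame:
    """Call target-tissue-enriched events.

    Returns a frame indexed by event id with columns ``length_class``,
    ``dpsi_target``, ``dpsi_global``, ``n_valid_groups``, ``eligible``
    and ``called``.  Events without enough valid groups get NaN dPSI
    and ``eligible=False``.
    """
    if target_group not in config.groups():
        raise ValueError(f"target group {target_group!r} not in config")
    samples = [s for s in table.samples if s in config.group_of]
    if not samples:
        raise ValueError("no table samples present in the group config")
    target_samples = [s for s in samples if config.group_of[s] == target_group]
    if not target_samples:
        raise ValueError(f"no samples for target group {target_group!r}")
    if len(table.events) == 0:
        return pd.DataFrame(columns=["length_class", "dpsi_target", "dpsi_global",
                                     "n_valid_groups", "eligible", "called"])

    dropped = config.dropped_groups(target_group)
    psi = table.valid_psi(params.min_quality)[samples]
    group_labels = pd.Series({s: config.group_of[s] for s in samples})
    keep = ~group_labels.isin(dropped)
    psi = psi.loc[:, keep[keep].index]
    group_labels = group_labels[keep]

    # per-group mean PSI and valid-sample count, events x groups
    gmeans = psi.T.groupby(group_labels).mean().T
    gcounts = psi.notna().T.groupby(group_labels).sum().T
    valid = gcounts >= params.min_rep
    gmeans = gmeans.where(valid)

    n_valid = valid.sum(axis=1)
    target_valid = valid[target_group]
    eligible = target_valid & (n_valid >= params.n_groups)

    others = [g for g in gmeans.columns if g != target_group]
    mean_other_groups = gmeans[others].mean(axis=1)
    dpsi_target = gmeans[target_group] - mean_other_groups

    other_samples = group_labels.index[group_labels != target_group]
    # pool only samples belonging to valid groups so group validity and the
    # global mean agree on what counts as covered
    pool = psi[other_samples].where(
        valid[group_labels[other_samples]].to_numpy())
    dpsi_global = gmeans[target_group] - pool.mean(axis=1)

    called = (eligible
              & (dpsi_target.abs() >= params.min_dpsi)
              & (dpsi_global.abs() >= params.min_dpsi_glob))
    if params.require_enrichment:
        called &= dpsi_target > 0

    out = pd.DataFrame({
        "length_class": table.meta["length_nt"].map(classify_exon_length),
        "dpsi_target": dpsi_target.where(eligible),
        "dpsi_global": dpsi_global.where(eligible),
        "n_valid_groups": n_valid,
        "eligible": eligible,
        "called": called.fillna(False),
    }, index=table.events)
    return out


def classify_regulator_response(
        deltas: Mapping[str, Optional[float]] | Iterable[Optional[float]],
        affected_below: float = -15.0) -> RegulationClass:
    """Classify an event by its strongest regulator loss-of-function response.

    ``deltas`` maps comparison ids (e.g. srrm3-KO retina, srrm3/4-KO
    larva) to dPSI (mutant - control), with None for comparisons
    without coverage.  The lowest covered dPSI decides: affected when
    it falls below ``affected_below``.
    """
    values = list(deltas.values()) if isinstance(deltas, Mapping) else list(deltas)
    covered = [v for v in values if v is not None and np.isfinite(v)]
    if not covered:
        return RegulationClass(None, "no_coverage")
    m = float(min(covered))
    return RegulationClass(m, "affected" if m < affected_below else "not_affected")


def classify_conservation(has_ortholog: bool,
                          target_dpsi: Optional[float],
                          conserved_at: float = 15.0) -> str:
    """Cross-species regulatory-conservation class of an event.

    No ortholog in the target species -> ``no_event_ortholog``;
    ortholog without target-species coverage -> ``no_coverage_in_target``;
    ortholog with target neural dPSI >= 15 -> ``regulatory_conserved``;
    otherwise genomically conserved only.
    """
    if not has_ortholog:
        return "no_event_ortholog"
    if target_dpsi is None or not np.isfinite(target_dpsi):
        return "no_coverage_in_target"
    return "regulatory_conserved" if target_dpsi >= conserved_at else "genomic_only"


def length_class_association(table_2x2) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    Returns ``(odds_ratio, p)`` with the sample odds ratio (a*d)/(b*c),
    infinity when b*c = 0.  Raises on a zero margin.
    """
    t = np.asarray(table_2x2, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    (a, b), (c, d) = t
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def length_class_composition(length_classes: Iterable[str]) -> pd.DataFrame:
    """Counts and percentages of events per length class."""
    s = pd.Series(list(length_classes), dtype=str)
    counts = s.value_counts().reindex(LENGTH_CLASSES, fill_value=0)
    return pd.DataFrame({"count": counts,
                         "percent": 100.0 * counts / counts.sum()})


def affected_fraction(classes: Iterable[RegulationClass | str]) -> float:
    """Fraction of regulator-affected events among events with coverage."""
    labels = [c.cls if isinstance(c, RegulationClass) else str(c) for c in classes]
    covered = [c for c in labels if c != "no_coverage"]
    if not covered:
        raise ValueError("no events with coverage")
    return sum(c == "affected" for c in covered) / len(covered)


def impute_group_means(table: PsiTable, config: TissueGroupConfig,
                       min_quality: str = "VLOW") -> pd.DataFrame:
    """Group-mean PSI matrix with missing groups imputed by the event mean.

    Plotting/heatmap convenience only — imputation never feeds the
    caller.
    """
    psi = table.valid_psi(min_quality)
    labels = pd.Series({s: config.group_of.get(s) for s in psi.columns}).dropna()
    gmeans = psi[labels.index].T.groupby(labels).mean().T
    row_mean = gmeans.mean(axis=1)
    return gmeans.apply(lambda col: col.fillna(row_mean))


# ---------------------------------------------------------------------------
# TSV dialects (vast-tools INCLUSION-table style)

def write_psi_table(table: PsiTable, path) -> None:
    """Write EVENT/GENE/LENGTH plus per-sample PSI and <sample>-Q columns.

    The quality column holds a comma-separated string whose first field
    is the coverage code, as in vast-tools INCLUSION tables.
    """
    out = pd.DataFrame({"EVENT": table.events,
                        "GENE": table.meta["gene_id"].to_numpy(),
                        "LENGTH": table.meta["length_nt"].to_numpy()})
    for s in table.samples:
        out[s] = table.psi[s].to_numpy()
        out[f"{s}-Q"] = table.quality[s].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_psi_table(path) -> PsiTable:
    df = pd.read_csv(path, sep="\t")
    meta = pd.DataFrame({"gene_id": df["GENE"].to_numpy(),
                         "length_nt": df["LENGTH"].to_numpy()},
                        index=pd.Index(df["EVENT"], name="event_id"))
    samples = [c for c in df.columns
               if c not in ("EVENT", "GENE", "LENGTH") and not c.endswith("-Q")]
    psi = df[samples].set_index(meta.index)
    qual = pd.DataFrame(
        {s: df[f"{s}-Q"].astype(str).str.split(",").str[0].to_numpy()
         for s in samples}, index=meta.index)
    return PsiTable(meta=meta, psi=psi.astype(float), quality=qual)


def write_group_config(config: TissueGroupConfig, path) -> None:
    rows = []
    for sample, group in config.group_of.items():
        excl = ",".join(sorted(config.excluded_for.get(group, ())))
        rows.append({"Sample": sample, "Group": group, "EXCLUDED": excl})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_group_config(path) -> TissueGroupConfig:
    df = pd.read_csv(path, sep="\t").fillna({"EXCLUDED": ""})
    group_of = dict(zip(df["Sample"].astype(str), df["Group"].astype(str)))
    excluded: dict[str, frozenset] = {}
    for _, row in df.iterrows():
        targets = frozenset(t for t in str(row.get("EXCLUDED", "")).split(",") if t)
        if targets:
            excluded[str(row["Group"])] = excluded.get(
                str(row["Group"]), frozenset()) | targets
    return TissueGroupConfig(group_of=group_of, excluded_for=excluded)
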