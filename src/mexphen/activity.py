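"""Larval activity, transition, habituation and thigmotaxis phenotyping.

Works on 1 Hz activity exports (percent of changed pixels per second,
EthoVision style) recorded over a fixed protocol: 5 min habituation,
25 min light baseline, three 10 min dark and two 10 min light blocks in
alternation, 10 min re-habituation and a train of 30 mechanical taps at
1 Hz.  Per-larva summaries comprise interval means (baseline/dark/
light, computed on per-minute averages), light-dark and dark-light
transition responses (first minute after minus last minute before,
averaged across same-type transitions), tap startle statistics
(response to tap 1, means over taps 3-5 and 21-30, and their
differences from tap 1 — the habituation read-outs) and thigmotaxis
(median per-minute percentage of distance moved in the outer ring,
over moving minutes only).

QC follows the experimental pipeline: larvae whose per-minute activity
and total distance moved correlate below r = 0.9 are dropped from
thigmotaxis (suboptimal positional tracking), larvae moving fewer than
3 minutes in a condition get no thigmotaxis value there, larvae not
responding to any of the first three taps are flagged as low
responders, and trials with fewer than 3 larvae in any genotype are
removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import permutation_median_p

__all__ = [
    "ProtocolTimeline",
    "ActivityTrace",
    "TapStats",
    "ThigmotaxisResult",
    "LarvaSummary",
    "minute_means",
    "interval_means",
    "transition_response",
    "tapping_response",
    "thigmotaxis",
    "summarize_larva",
    "summarize_trial",
    "filter_trials",
    "permutation_genotype_test",
    "percent_change_vs_wt",
    "read_activity_csv",
    "read_zone_csv",
]


@dataclass(frozen=True)
class ProtocolTimeline:
    """Protocol blocks in minutes (half-open) and tap times in seconds."""

    habituation: tuple = (0, 5)
    baseline: tuple = (5, 30)
    dark_blocks: tuple = ((30, 40), (50, 60), (70, 80))
    light_blocks: tuple = ((40, 50), (60, 70))
    tap_times_s: tuple = tuple(range(5400, 5430))  # 30 taps at 1 Hz after re-habituation

    def baseline_minutes(self) -> np.ndarray:
        return np.arange(*self.baseline)

    def dark_minutes(self) -> np.ndarray:
        return np.concatenate([np.arange(a, b) for a, b in self.dark_blocks])

    def light_minutes(self) -> np.ndarray:
        return np.concatenate([np.arange(a, b) for a, b in self.light_blocks])

    @property
    def n_minutes(self) -> int:
        ends = [self.habituation[1], self.baseline[1]]
        ends += [b for _, b in self.dark_blocks] + [b for _, b in self.light_blocks]
        return max(ends)


@dataclass
class ActivityTrace:
    """One larva's 1 Hz activity plus per-minute per-zone distance."""

    larva_id: str
    genotype: str  # WT | Het | Del
    activity: np.ndarray  # %delta-pixels per second, second 0 = minute 0
    zone_tdm: Optional[pd.DataFrame] = None       # minute x {center, periphery}, mm
    zone_activity: Optional[pd.DataFrame] = None  # minute x zone, %delta-pixels
    trial: str = ""

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if np.nanmin(self.activity, initial=0.0) < 0:
            raise ValueError("activity must be non-negative")


@dataclass
class TapStats:
    act1_tap: float
    mean_tap_3_5: float
    mean_tap_21_30: float
    diff_3_5_vs_1: float
    diff_21_30_vs_1: float
    low_responder: bool


@dataclass
class ThigmotaxisResult:
    thigmotaxis_b: float
    thigmotaxis_d: float
    thigmotaxis_l: float
    qc_flags: set = field(default_factory=set)


@dataclass
class LarvaSummary:
    larva_id: str
    genotype: str
    mean_baseline: float
    mean_dark: float
    mean_light: float
    ld_transition: float
    dl_transition: float
    act1_tap: float
    mean_tap_3_5: float
    mean_tap_21_30: float
    diff_3_5_vs_1: float
    diff_21_30_vs_1: float
    thigmotaxis_b: float
    thigmotaxis_d: float
    thigmotaxis_l: float
    qc_flags: set = field(default_factory=set)
    trial: str = ""


def minute_means(activity: np.ndarray) -> np.ndarray:
    """Per-minute mean of a 1 Hz series; a trailing partial minute counts."""
    activity = np.asarray(activity, dtype=float)
    n_full = activity.size // 60
    out = activity[:n_full * 60].reshape(n_full, 60).mean(axis=1)
    if activity.size % 60:
        out = np.append(out, activity[n_full * 60:].mean())
    return out


def _mean_over_minutes(mm: np.ndarray, minutes: np.ndarray,
                       flags: set, label: str) -> float:
    present = minutes[minutes < mm.size]
    if present.size < minutes.size:
        flags.add(f"missing_minutes_{label}")
    if present.size == 0:
        return float("nan")
    return float(np.mean(mm[present]))


def interval_means(trace: ActivityTrace,
                   timeline: ProtocolTimeline = ProtocolTimeline(),
                   flags: set | None = None) -> tuple[float, float, float]:
    """(baseline, dark, light) mean activity; seconds averaged per minute first."""
    flags = set() if flags is None else flags
    mm = minute_means(trace.activity)
    b = _mean_over_minutes(mm, timeline.baseline_minutes(), flags, "baseline")
    d = _mean_over_minutes(mm, timeline.dark_minutes(), flags, "dark")
    l = _mean_over_minutes(mm, timeline.light_minutes(), flags, "light")
    return b, d, l


def transition_response(trace: ActivityTrace,
                        timeline: ProtocolTimeline = ProtocolTimeline()
                        ) -> tuple[float, float]:
    """(LD, DL) transition responses.

    LD = first dark minute minus last preceding light minute, averaged
    over light-to-dark transitions (the baseline counts as light); DL
    symmetric for dark-to-light.
    """
    mm = minute_means(trace.activity)
    ld, dl = [], []
    for start, _ in timeline.dark_blocks:
        if start >= 1 and start < mm.size:
            ld.append(mm[start] - mm[start - 1])
    for start, _ in timeline.light_blocks:
        if start >= 1 and start < mm.size:
            dl.append(mm[start] - mm[start - 1])
    if not ld or not dl:
        raise ValueError("timeline must contain at least one transition of each type")
    return float(np.mean(ld)), float(np.mean(dl))


def tapping_response(trace: ActivityTrace,
                     tap_times_s: Sequence[int] | None = None) -> TapStats:
    """Startle and habituation statistics over the tap train.

    The response to a tap is the activity in the 1 s bin starting at
    the tap (taps are 1 s apart, so bins tile the train); "responding"
    means strictly positive activity in that bin.
    """
    if tap_times_s is None:
        tap_times_s = ProtocolTimeline().tap_times_s
    taps = np.asarray(tap_times_s, dtype=int)
    if taps.max() >= trace.activity.size:
        raise ValueError("trace does not cover the tap train")
    resp = trace.activity[taps]
    act1 = float(resp[0])
    m35 = float(resp[2:5].mean())
    m2130 = float(resp[20:30].mean())
    return TapStats(
        act1_tap=act1, mean_tap_3_5=m35, mean_tap_21_30=m2130,
        diff_3_5_vs_1=act1 - m35, diff_21_30_vs_1=act1 - m2130,
        low_responder=bool(np.all(resp[:3] <= 0)),
    )


def thigmotaxis(trace: ActivityTrace,
                timeline: ProtocolTimeline = ProtocolTimeline(),
                corr_threshold: float = 0.9,
                min_moving_minutes: int = 3) -> ThigmotaxisResult:
    """Per-condition thigmotaxis (% of distance moved in the periphery).

    Per minute, thigmotaxis = 100 * TDM_periphery / (TDM_center +
    TDM_periphery); the per-condition value is the median over minutes
    of movement (zone activity > 0).  Larvae whose minute activity and
    total TDM correlate below ``corr_threshold`` are flagged
    ``tracking_mismatch`` (values withheld); conditions with fewer than
    ``min_moving_minutes`` moving minutes are flagged and get NaN.
    """
    if trace.zone_tdm is None or trace.zone_activity is None:
        raise ValueError("zone series required for thigmotaxis")
    flags: set = set()
    tdm = trace.zone_tdm
    total_tdm = tdm.sum(axis=1)
    total_act = trace.zone_activity.sum(axis=1)
    if total_tdm.std() == 0 or total_act.std() == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(total_act, total_tdm)[0, 1])
    if not np.isfinite(r) or r < corr_threshold:
        flags.add("tracking_mismatch")
        return ThigmotaxisResult(np.nan, np.nan, np.nan, flags)

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = 100.0 * tdm["periphery"] / total_tdm
    moving = total_act > 0

    def per_condition(minutes: np.ndarray, label: str) -> float:
        idx = tdm.index.intersection(minutes)
        sel = moving.loc[idx]
        if int(sel.sum()) < min_moving_minutes:
            flags.add(f"low_movement_{label}")
            return float("nan")
        return float(np.nanmedian(frac.loc[idx][sel]))

    return ThigmotaxisResult(
        thigmotaxis_b=per_condition(timeline.baseline_minutes(), "b"),
        thigmotaxis_d=per_condition(timeline.dark_minutes(), "d"),
        thigmotaxis_l=per_condition(timeline.light_minutes(), "l"),
        qc_flags=flags,
    )


def summarize_larva(trace: ActivityTrace,
                    timeline: ProtocolTimeline = ProtocolTimeline()
                    ) -> LarvaSummary:
    flags: set = set()
    b, d, l = interval_means(trace, timeline, flags)
    ld, dl = transition_response(trace, timeline)
    taps = tapping_response(trace, timeline.tap_times_s)
    if taps.low_responder:
        flags.add("low_responder")
    if trace.zone_tdm is not None and trace.zone_activity is not None:
        thig = thigmotaxis(trace, timeline)
        flags |= thig.qc_flags
    else:
        thig = ThigmotaxisResult(np.nan, np.nan, np.nan)
    return LarvaSummary(
        larva_id=trace.larva_id, genotype=trace.genotype, trial=trace.trial,
        mean_baseline=b, mean_dark=d, mean_light=l,
        ld_transition=ld, dl_transition=dl,
        act1_tap=taps.act1_tap, mean_tap_3_5=taps.mean_tap_3_5,
        mean_tap_21_30=taps.mean_tap_21_30,
        diff_3_5_vs_1=taps.diff_3_5_vs_1, diff_21_30_vs_1=taps.diff_21_30_vs_1,
        thigmotaxis_b=thig.thigmotaxis_b, thigmotaxis_d=thig.thigmotaxis_d,
        thigmotaxis_l=thig.thigmotaxis_l, qc_flags=flags,
    )


def summarize_trial(traces: Sequence[ActivityTrace],
                    timeline: ProtocolTimeline = ProtocolTimeline()
                    ) -> pd.DataFrame:
    rows = []
    for t in traces:
        s = summarize_larva(t, timeline)
        row = {k: v for k, v in vars(s).items() if k != "qc_flags"}
        row["qc_flags"] = ";".join(sorted(s.qc_flags))
        rows.append(row)
    return pd.DataFrame(rows)


def filter_trials(summaries: pd.DataFrame, min_per_genotype: int = 3,
                  require_wt_dl_negative: bool = False) -> pd.DataFrame:
    """Trial-level exclusions, applied after larva-level exclusions.

    Drops trials with fewer than ``min_per_genotype`` larvae in any
    genotype present.  ``require_wt_dl_negative`` additionally drops
    trials whose WT median DL response is >= 0 (the dark-to-light dip
    is the expected WT stimulus response); off by default.
    """
    keep = []
    for trial, g in summaries.groupby("trial"):
        counts = g.groupby("genotype").size()
        if (counts < min_per_genotype).any():
            continue
        if require_wt_dl_negative and "WT" in counts.index:
            if g.loc[g["genotype"] == "WT", "dl_transition"].median() >= 0:
                continue
        keep.append(trial)
    return summaries[summaries["trial"].isin(keep)].copy()


def permutation_genotype_test(values_by_genotype: Mapping[str, Sequence[float]],
                              n_perm: int = 100, subsample: int = 10,
                              seed: int = 0) -> float:
    """Median p over ``n_perm`` subsampled two-group rank-sum tests.

    Exactly two genotypes are compared (run each mutant genotype
    against WT separately).  Each permutation selects ``subsample``
    observations per genotype — without replacement when the group is
    large enough — and runs a two-sided Wilcoxon rank-sum test.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_genotype.items()}
    if len(groups) != 2:
        raise ValueError("exactly two genotypes expected")
    for g, v in groups.items():
        if v.size == 0:
            raise ValueError(f"genotype {g!r} has no values")
    a, b = groups.values()
    return permutation_median_p(a, b, n_perm=n_perm, subsample=subsample, seed=seed)


def percent_change_vs_wt(median_by_genotype: Mapping[str, float],
                         fallback_floor: float | None = None,
                         mutant: str = "Del") -> float:
    """Percent change of the mutant median relative to the WT median.

    When the WT median is zero the denominator is replaced by
    ``fallback_floor`` (the minimum non-zero WT median of the feature's
    category across founders, supplied by the caller).
    """
    if "WT" not in median_by_genotype:
        raise ValueError("WT median required")
    wt = float(median_by_genotype["WT"])
    mut = float(median_by_genotype[mutant])
    denom = wt
    if denom == 0:
        if not fallback_floor:
            raise ValueError("WT median is zero and no fallback floor provided")
        denom = float(fallback_floor)
    return 100.0 * (mut - wt) / denom


# ---------------------------------------------------------------------------
# CSV dialects (EthoVision-export style)

def read_activity_csv(path) -> dict[tuple, np.ndarray]:
    """Read a long-format trace CSV: trial, larva_id, time_s, activity_pct."""
    df = pd.read_csv(path)
    out = {}
    for (trial, larva), g in df.groupby(["trial", "larva_id"]):
        out[(str(trial), str(larva))] = (
            g.sort_values("time_s")["activity_pct"].to_numpy(dtype=float))
    return out


def read_zone_csv(path) -> dict[tuple, tuple[pd.DataFrame, pd.DataFrame]]:
    """Read a zone CSV: trial, larva_id, minute, zone, tdm_mm, activity_pct."""
    df = pd.read_csv(path)
    out = {}
    for (trial, larva), g in df.groupby(["trial", "larva_id"]):
        tdm = g.pivot_table(index="minute", columns="zone", values="tdm_mm")
        act = g.pivot_table(index="minute", columns="zone", values="activity_pct")
        out[(str(trial), str(larva))] = (tdm, act)
    return out
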