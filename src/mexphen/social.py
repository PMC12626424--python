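"""Trajectory-derived social and locomotion metrics for fish pairs.

From (x, y) positions of two juvenile fish at 30 fps in a circular
arena, computes the nine standard pair-assay read-outs: speed, absolute
normal and tangential acceleration (turning vs speeding up/slowing
down), distance traveled, time in the periphery (outer ring from 0.8 R
to the wall), normalized distance to the arena center, ratio-in-front
(fraction of frames with the other fish in the focal fish's frontal
half-plane; low values mean the focal fish leads), polarization (the
order parameter |mean unit velocity| of the pair) and inter-individual
distance.

Comparison scheme: individual metrics from homotypic pairs (Het-Het,
Del-Del) enter as the pair's two-fish average (one observation per
pair, "S" comparisons); in heterotypic Het-Del pairs each fish enters
labeled by genotype ("D" comparisons).  Ratio-in-front is always per
fish.  Pair metrics (polarization, neighbor distance) are compared
between pair types: Het-Het vs Het-Del ("HM") and Het-Het vs Del-Del
("HD").  All comparisons use two-sided Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .stats import wilcoxon_ranksum

__all__ = [
    "Arena",
    "TrajectoryPair",
    "Kinematics",
    "interpolate_gaps",
    "kinematics",
    "periphery_and_origin",
    "ratio_in_front",
    "polarization",
    "neighbor_distance",
    "compute_pair_metrics",
    "pair_comparison",
    "read_trajectory_csv",
    "write_trajectory_csv",
]

#: below this speed (cm/s) the heading is undefined
SPEED_THRESHOLD = 0.1

INDIVIDUAL_METRICS = ("speed", "abs_normal_accel", "abs_tangential_accel",
                      "distance_traveled", "time_in_periphery", "norm_dist_origin")
PAIR_METRICS = ("polarization", "neighbor_distance")


@dataclass(frozen=True)
class Arena:
    center: tuple = (0.0, 0.0)
    radius_cm: float = 21.0
    periphery_inner_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.radius_cm <= 0:
            raise ValueError("radius must be positive")
        if not 0 < self.periphery_inner_fraction < 1:
            raise ValueError("periphery_inner_fraction must be in (0, 1)")


@dataclass
class TrajectoryPair:
    """Positions of a fish pair: array (2, n_frames, 2) in cm, NaN = missing."""

    positions: np.ndarray
    fps: float = 30.0
    genotypes: tuple = ("Het", "Het")
    pair_id: str = ""
    arena: Arena = field(default_factory=Arena)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[0] != 2 \
                or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (2, n_frames, 2)")
        if self.positions.shape[1] < 2:
            raise ValueError("need at least 2 frames")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def pair_type(self) -> str:
        order = {"Het": 0, "Del": 1}
        a, b = sorted(self.genotypes, key=lambda g: order.get(g, 2))
        return f"{a}{b}"  # HetHet | HetDel | DelDel


@dataclass
class Kinematics:
    velocity: np.ndarray        # (T, 2) cm/s
    speed: np.ndarray           # (T,)
    accel: np.ndarray           # (T, 2) cm/s^2
    tangential: np.ndarray      # signed, NaN where heading undefined
    normal: np.ndarray          # magnitude, NaN where heading undefined


def interpolate_gaps(positions: np.ndarray, max_gap: int = 5) -> np.ndarray:
    """Linearly interpolate missing frames across gaps of <= ``max_gap``.

    Longer gaps (and leading/trailing missing stretches) stay NaN and
    are excluded from all frame-wise statistics downstream.
    """
    pos = np.array(positions, dtype=float)
    missing = np.isnan(pos).any(axis=-1)
    if not missing.any():
        return pos
    t = np.arange(pos.shape[0])
    runs = []
    start = None
    for i, m in enumerate(missing):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, pos.shape[0]))
    for a, b in runs:
        interior = a > 0 and b < pos.shape[0]
        if interior and (b - a) <= max_gap:
            for ax in range(2):
                pos[a:b, ax] = np.interp(t[a:b], [a - 1, b], [pos[a - 1, ax], pos[b, ax]])
    return pos


def kinematics(positions: np.ndarray, fps: float,
               sigma: float = 1.0,
               speed_threshold: float = SPEED_THRESHOLD) -> Kinematics:
    """Central-difference velocity and second-difference acceleration.

    Positions are optionally smoothed with a Gaussian kernel of
    ``sigma`` frames before differentiation (``sigma=0`` disables
    smoothing; closed-form checks use raw differences).  Acceleration
    is split into the component along the unit velocity (tangential,
    signed) and the perpendicular residual magnitude (normal); both are
    undefined (NaN) where speed is below ``speed_threshold``.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError("positions must have shape (n_frames, 2)")
    valid = ~np.isnan(pos).any(axis=1)
    if not valid.any():
        raise ValueError("all frames missing")
    if sigma > 0:
        sm = pos.copy()
        if valid.all():
            sm = gaussian_filter1d(pos, sigma=sigma, axis=0, mode="nearest")
        else:
            # smooth each fully-observed run independently
            idx = np.flatnonzero(valid)
            breaks = np.flatnonzero(np.diff(idx) > 1)
            for seg in np.split(idx, breaks + 1):
                if seg.size >= 3:
                    sm[seg] = gaussian_filter1d(pos[seg], sigma=sigma, axis=0,
                                                mode="nearest")
        pos = sm
    dt = 1.0 / fps
    vel = np.full_like(pos, np.nan)
    vel[1:-1] = (pos[2:] - pos[:-2]) / (2 * dt)
    acc = np.full_like(pos, np.nan)
    acc[1:-1] = (pos[2:] - 2 * pos[1:-1] + pos[:-2]) / dt ** 2
    speed = np.linalg.norm(vel, axis=1)
    with np.errstate(invalid="ignore"):
        heading = vel / speed[:, None]
        tang = np.einsum("ij,ij->i", acc, heading)
        normal = np.linalg.norm(acc - tang[:, None] * heading, axis=1)
    undef = ~(speed >= speed_threshold)
    tang[undef] = np.nan
    normal[undef] = np.nan
    return Kinematics(velocity=vel, speed=speed, accel=acc,
                      tangential=tang, normal=normal)


def periphery_and_origin(positions: np.ndarray, arena: Arena
                         ) -> tuple[int, np.ndarray]:
    """(frames in the outer ring, normalized distance-to-center series).

    The radial coordinate is clamped at R (tracking jitter may place a
    fish nominally outside the wall); the periphery starts at
    ``periphery_inner_fraction * R`` inclusive.
    """
    pos = np.asarray(positions, dtype=float)
    r = np.linalg.norm(pos - np.asarray(arena.center), axis=1)
    norm = np.minimum(r / arena.radius_cm, 1.0)
    in_periphery = norm >= arena.periphery_inner_fraction
    return int(np.nansum(in_periphery[~np.isnan(norm)])), norm


def ratio_in_front(focal_positions: np.ndarray, focal_velocity: np.ndarray,
                   other_positions: np.ndarray,
                   speed_threshold: float = SPEED_THRESHOLD) -> float:
    """Fraction of frames with the other fish in the focal frontal half-plane.

    A frame counts when the focal heading is defined (speed above
    threshold) and both positions are present; the other fish is "in
    front" when heading . (other - focal) > 0.  Low values indicate
    the focal fish leads.
    """
    fp = np.asarray(focal_positions, float)
    op = np.asarray(other_positions, float)
    v = np.asarray(focal_velocity, float)
    speed = np.linalg.norm(v, axis=1)
    offset = op - fp
    ok = (speed >= speed_threshold) & ~np.isnan(offset).any(axis=1) \
        & ~np.isnan(v).any(axis=1)
    if not ok.any():
        return float("nan")
    dot = np.einsum("ij,ij->i", v[ok], offset[ok])
    return float(np.mean(dot > 0))


def polarization(velocity_1: np.ndarray, velocity_2: np.ndarray,
                 speed_threshold: float = SPEED_THRESHOLD
                 ) -> tuple[np.ndarray, float]:
    """Per-frame heading-alignment order parameter and its median.

    For each frame with both headings defined, the magnitude of the
    mean of the two unit velocity vectors: 1 for parallel, 0 for
    antiparallel motion.
    """
    v1 = np.asarray(velocity_1, float)
    v2 = np.asarray(velocity_2, float)
    s1 = np.linalg.norm(v1, axis=1)
    s2 = np.linalg.norm(v2, axis=1)
    ok = (s1 >= speed_threshold) & (s2 >= speed_threshold)
    series = np.full(v1.shape[0], np.nan)
    with np.errstate(invalid="ignore"):
        u = v1[ok] / s1[ok, None] + v2[ok] / s2[ok, None]
    series[ok] = 0.5 * np.linalg.norm(u, axis=1)
    med = float(np.nanmedian(series)) if ok.any() else float("nan")
    return series, med


def neighbor_distance(positions_1: np.ndarray, positions_2: np.ndarray
                      ) -> tuple[np.ndarray, float]:
    """Per-frame Euclidean distance between the two fish and its median."""
    d = np.linalg.norm(np.asarray(positions_1, float)
                       - np.asarray(positions_2, float), axis=1)
    if np.all(np.isnan(d)):
        raise ValueError("no frame with both fish present")
    return d, float(np.nanmedian(d))


def compute_pair_metrics(pair: TrajectoryPair, sigma: float = 1.0,
                         max_gap: int = 5) -> pd.DataFrame:
    """All per-fish and per-pair metrics for one trajectory pair.

    Returns one row per fish with the individual metrics (speed and the
    acceleration magnitudes as medians over defined frames, distance
    traveled as the summed path length, periphery time in frames,
    normalized distance to origin as a median, ratio-in-front as a
    proportion) and the shared pair metrics attached to both rows.
    """
    pos = np.stack([interpolate_gaps(pair.positions[i], max_gap) for i in (0, 1)])
    kin = [kinematics(pos[i], pair.fps, sigma=sigma) for i in (0, 1)]
    rows = []
    pol_med = polarization(kin[0].velocity, kin[1].velocity)[1]
    nd_med = neighbor_distance(pos[0], pos[1])[1]
    for i in (0, 1):
        j = 1 - i
        steps = np.linalg.norm(np.diff(pos[i], axis=0), axis=1)
        n_peri, norm_r = periphery_and_origin(pos[i], pair.arena)
        rows.append({
            "pair_id": pair.pair_id,
            "pair_type": pair.pair_type,
            "fish": i,
            "genotype": pair.genotypes[i],
            "speed": float(np.nanmedian(kin[i].speed)),
            "abs_normal_accel": float(np.nanmedian(kin[i].normal)),
            "abs_tangential_accel": float(np.nanmedian(np.abs(kin[i].tangential))),
            "distance_traveled": float(np.nansum(steps)),
            "time_in_periphery": n_peri,
            "norm_dist_origin": float(np.nanmedian(norm_r)),
            "ratio_in_front": ratio_in_front(pos[i], kin[i].velocity, pos[j]),
            "polarization": pol_med,
            "neighbor_distance": nd_med,
        })
    return pd.DataFrame(rows)


def pair_comparison(fish_metrics: pd.DataFrame,
                    min_group: int = 2) -> pd.DataFrame:
    """Grouped rank-sum comparisons across genotypes and pair types.

    Individual metrics: "S" compares homotypic pairs (each contributes
    its two-fish average once) Het-Het vs Del-Del; "D" compares Het vs
    Del fish within heterotypic pairs.  Ratio-in-front stays per fish
    in both schemes.  Pair metrics: one value per pair, Het-Het vs
    Het-Del ("HM") and Het-Het vs Del-Del ("HD").  Groups smaller than
    ``min_group`` skip the comparison with a warning.
    """
    results = []

    def compare(metric, scheme, a, b, label_a, label_b):
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if a.size < min_group or b.size < min_group:
            warnings.warn(f"{metric}/{scheme}: group below {min_group}, skipped")
            return
        results.append({
            "metric": metric, "scheme": scheme,
            "group_a": label_a, "group_b": label_b,
            "n_a": a.size, "n_b": b.size,
            "median_a": float(np.median(a)), "median_b": float(np.median(b)),
            "p": wilcoxon_ranksum(a, b),
        })

    homo = fish_metrics[fish_metrics["pair_type"].isin(["HetHet", "DelDel"])]
    hetero = fish_metrics[fish_metrics["pair_type"] == "HetDel"]
    for metric in INDIVIDUAL_METRICS:
        pair_avg = homo.groupby(["pair_id", "pair_type"])[metric].mean().reset_index()
        compare(metric, "S",
                pair_avg.loc[pair_avg["pair_type"] == "HetHet", metric],
                pair_avg.loc[pair_avg["pair_type"] == "DelDel", metric],
                "HetHet", "DelDel")
        compare(metric, "D",
                hetero.loc[hetero["genotype"] == "Het", metric],
                hetero.loc[hetero["genotype"] == "Del", metric],
                "Het(D)", "Del(D)")
    # leadership stays per fish: homotypic fish by genotype and within Het-Del
    compare("ratio_in_front", "S",
            homo.loc[homo["genotype"] == "Het", "ratio_in_front"],
            homo.loc[homo["genotype"] == "Del", "ratio_in_front"],
            "Het(S)", "Del(S)")
    compare("ratio_in_front", "D",
            hetero.loc[hetero["genotype"] == "Het", "ratio_in_front"],
            hetero.loc[hetero["genotype"] == "Del", "ratio_in_front"],
            "Het(D)", "Del(D)")
    per_pair = fish_metrics.drop_duplicates("pair_id")
    for metric in PAIR_METRICS:
        for scheme, other in (("HM", "HetDel"), ("HD", "DelDel")):
            compare(metric, scheme,
                    per_pair.loc[per_pair["pair_type"] == "HetHet", metric],
                    per_pair.loc[per_pair["pair_type"] == other, metric],
                    "HetHet", other)
    return pd.DataFrame(results)


# ---------------------------------------------------------------------------
# I/O

def write_trajectory_csv(pair: TrajectoryPair, path) -> None:
    """Long-format CSV: frame, fish_id, x_cm, y_cm (blank when missing)."""
    frames = np.arange(pair.positions.shape[1])
    parts = []
    for i in (0, 1):
        parts.append(pd.DataFrame({"frame": frames, "fish_id": i,
                                   "x_cm": pair.positions[i, :, 0],
                                   "y_cm": pair.positions[i, :, 1]}))
    pd.concat(parts).to_csv(path, index=False)


def read_trajectory_csv(path, fps: float = 30.0,
                        genotypes: tuple = ("Het", "Het"),
                        arena: Arena | None = None,
                        pair_id: str = "") -> TrajectoryPair:
    df = pd.read_csv(path)
    n = int(df["frame"].max()) + 1
    pos = np.full((2, n, 2), np.nan)
    for i in (0, 1):
        g = df[df["fish_id"] == i]
        pos[i, g["frame"].to_numpy(int), 0] = g["x_cm"].to_numpy(float)
        pos[i, g["frame"].to_numpy(int), 1] = g["y_cm"].to_numpy(float)
    return TrajectoryPair(positions=pos, fps=fps, genotypes=genotypes,
                          pair_id=pair_id, arena=arena or Arena())
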