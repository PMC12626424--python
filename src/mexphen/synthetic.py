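"""Seeded generators for every pipeline stage's inputs.

Each generator emulates the statistical structure one analysis stage
assumes, with planted ground truth returned alongside so recovery can
be tested end to end:

* PSI tables with a planted neural-enriched event class, per-cell
  coverage-quality codes and coverage dropout;
* larval activity experiments over the full recording protocol
  (habituation, light baseline, dark/light alternation, re-habituation,
  30-tap train) with zero-inflated gamma second-to-second noise and
  genotype effects injected as multipliers on baseline level,
  transition amplitude and tap-response decay;
* fish-pair trajectories — a correlated random walk (Ornstein-
  Uhlenbeck heading noise, fixed time step 1/fps, reflection at the
  circular wall) for the leader, with the follower's heading relaxing
  toward the leader's position at strength ``follow_gain``;
* negative-binomial count matrices with a planted coordinately shifted
  pathway, host-gene and paralog shifts injectable.

Every generated entity (larva, fish, gene block) draws from its own
RNG stream derived from the master seed, so subsetting an experiment
does not change the entities that remain.  Identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .activity import ActivityTrace, ProtocolTimeline
from .social import Arena, TrajectoryPair
from .splicing import PsiTable, TissueGroupConfig

__all__ = [
    "SimConfig",
    "GenotypeEffects",
    "gen_psi_table",
    "gen_activity_experiment",
    "gen_pair_trajectories",
    "gen_expression_counts",
]

_QUALITY_CODES = np.array(["VLOW", "LOW", "OK", "SOUND"])


@dataclass(frozen=True)
class SimConfig:
    """Shared knobs of all generators; defaults are the study conditions.

    ``dpsi_effect`` is the planted neural-vs-rest PSI offset (PSI
    units), ``coverage_dropout`` the per-cell probability of an N
    (no-coverage) code, ``follow_gain`` the leader-attraction strength
    of the follower fish (1/s), ``pathway_shift`` the planted log2
    fold-change on the pathway gene set, ``dispersion`` the
    negative-binomial dispersion (var = mu + dispersion * mu^2).
    """

    seed: int = 0
    # PSI tables
    n_events: int = 300
    n_tissue_groups: int = 8
    n_samples_per_group: int = 3
    neural_fraction: float = 0.2
    dpsi_effect: float = 40.0
    coverage_dropout: float = 0.05
    psi_noise_sd: float = 3.0
    low_coverage_fraction: float = 0.1
    # larval activity
    n_larvae_per_genotype: int = 12
    tap_count: int = 30
    # trajectories
    fps: float = 30.0
    arena_radius_cm: float = 21.0
    follow_gain: float = 0.0
    n_frames: int = 18_000
    # expression
    n_genes: int = 2000
    n_lines: int = 6
    n_reps: int = 3
    pathway_shift: float = 0.0
    pathway_size: int = 50
    dispersion: float = 0.1

    def __post_init__(self) -> None:
        for name in ("neural_fraction", "coverage_dropout", "low_coverage_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_events", "n_tissue_groups", "n_samples_per_group",
                     "n_larvae_per_genotype", "tap_count", "n_frames",
                     "n_genes", "n_lines", "n_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.fps <= 0 or self.arena_radius_cm <= 0:
            raise ValueError("fps and arena_radius_cm must be positive")
        if self.follow_gain < 0:
            raise ValueError("follow_gain must be >= 0")


def _rng(config: SimConfig, domain: int, entity: int = 0) -> np.random.Generator:
    """Independent stream per (domain, entity), derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(domain, entity)))


# ---------------------------------------------------------------------------
# PSI tables

def gen_psi_table(config: SimConfig
                  ) -> tuple[PsiTable, TissueGroupConfig, pd.DataFrame]:
    """Planted-structure PSI table, its group config, and truth labels.

    Events split into ``neural`` (neural-group PSI approximately the
    background plus ``dpsi_effect``), ``background`` and
    ``low_coverage`` (too few covered groups to be eligible) classes;
    labels hold one row per event.
    """
    if config.n_tissue_groups < 5:
        warnings.warn("fewer than 5 tissue groups: default calling parameters "
                      "will return no eligible event")
    groups = ["Neural"] + [f"Tissue{i}" for i in range(1, config.n_tissue_groups)]
    samples = [f"{g}_r{j}" for g in groups for j in range(config.n_samples_per_group)]
    group_of = {s: s.rsplit("_r", 1)[0] for s in samples}

    n = config.n_events
    n_neural = int(round(config.neural_fraction * n))
    n_low = int(round(config.low_coverage_fraction * n))
    truth = np.array(["neural"] * n_neural
                     + ["low_coverage"] * min(n_low, n - n_neural)
                     + ["background"] * max(0, n - n_neural - n_low))
    psi = np.empty((n, len(samples)))
    qual = np.empty((n, len(samples)), dtype=object)
    lengths = np.empty(n, dtype=int)
    for e in range(n):
        rng = _rng(config, 0, e)
        base = rng.uniform(5, 35)
        lengths[e] = rng.choice([rng.integers(3, 28), rng.integers(28, 52),
                                 rng.integers(52, 300)])
        for j, s in enumerate(samples):
            mu = base
            if truth[e] == "neural" and group_of[s] == "Neural":
                mu = base + config.dpsi_effect
            psi[e, j] = np.clip(rng.normal(mu, config.psi_noise_sd), 0, 100)
            dropped = rng.random() < config.coverage_dropout
            qual[e, j] = "N" if dropped else rng.choice(_QUALITY_CODES)
        if truth[e] == "low_coverage":
            # leave coverage in fewer groups than the default eligibility needs
            for j, s in enumerate(samples):
                if group_of[s] not in groups[:4]:
                    qual[e, j] = "N"
        psi[e][np.array([q == "N" for q in qual[e]])] = np.nan

    events = pd.Index([f"EV{e:05d}" for e in range(n)], name="event_id")
    meta = pd.DataFrame({"gene_id": [f"g{e}" for e in range(n)],
                         "length_nt": lengths}, index=events)
    table = PsiTable(meta=meta,
                     psi=pd.DataFrame(psi, index=events, columns=samples),
                     quality=pd.DataFrame(qual, index=events, columns=samples))
    labels = pd.DataFrame({"truth": truth}, index=events)
    return table, TissueGroupConfig(group_of=group_of), labels


# ---------------------------------------------------------------------------
# larval activity

@dataclass(frozen=True)
class GenotypeEffects:
    """Multipliers applied to one genotype's activity generator."""

    baseline_mult: float = 1.0
    transition_mult: float = 1.0
    tap_start: float = 20.0
    tap_decay: float = 0.9
    periphery_bias: float = 0.65


# condition means in %delta-pixels: larvae move more in the dark
_LIGHT_MEAN = 5.0
_DARK_MEAN = 10.0
_P_ACTIVE = 0.7


def _condition_mean(minute: int, timeline: ProtocolTimeline) -> float:
    for a, b in timeline.dark_blocks:
        if a <= minute < b:
            return _DARK_MEAN
    return _LIGHT_MEAN


def gen_activity_experiment(
        config: SimConfig,
        effects: Mapping[str, GenotypeEffects] | None = None,
        genotypes: Sequence[str] = ("WT", "Het", "Del"),
        timeline: ProtocolTimeline = ProtocolTimeline(),
        trial: str = "trial1") -> list[ActivityTrace]:
    """One simulated clutch: 1 Hz traces plus per-minute zone series.

    Second-to-second activity is zero-inflated gamma around the
    condition mean (light 5, dark 10 %delta-pixels, movement
    probability 0.7), scaled by the genotype's ``baseline_mult``.  Dark
    onsets add an exponentially decaying burst and light onsets a
    matching suppression, both scaled by ``transition_mult``.  Tap
    responses start at ``tap_start`` and decay geometrically by
    ``tap_decay`` per tap (1.0 means no habituation).  Per-minute total
    distance tracks minute activity (high activity-TDM correlation)
    and splits into periphery/center by ``periphery_bias``.
    """
    effects = dict(effects or {})
    n_seconds = max(timeline.n_minutes * 60, max(timeline.tap_times_s) + 1) + 600
    n_seconds = 60 * int(np.ceil(n_seconds / 60))
    minutes = np.arange(n_seconds // 60)
    cond_mu = np.repeat([_condition_mean(m, timeline) for m in range(minutes.size)],
                        60)
    traces = []
    for gi, genotype in enumerate(genotypes):
        eff = effects.get(genotype, GenotypeEffects())
        for li in range(config.n_larvae_per_genotype):
            rng = _rng(config, 1, gi * 10_000 + li)
            mu = cond_mu * eff.baseline_mult
            moving = rng.random(n_seconds) < _P_ACTIVE
            act = np.where(moving,
                           rng.gamma(2.0, mu / (2.0 * _P_ACTIVE)), 0.0)
            # transition bursts/suppressions in the first post-stimulus minute
            for start, _ in timeline.dark_blocks:
                t0 = start * 60
                if t0 < n_seconds:
                    tt = np.arange(min(60, n_seconds - t0))
                    act[t0:t0 + tt.size] += (8.0 * eff.transition_mult
                                             * np.exp(-tt / 20.0))
            for start, _ in timeline.light_blocks:
                t0 = start * 60
                if t0 < n_seconds:
                    tt = np.arange(min(60, n_seconds - t0))
                    act[t0:t0 + tt.size] *= np.clip(
                        1.0 - 0.8 * eff.transition_mult * np.exp(-tt / 20.0), 0, 1)
            for i, ts in enumerate(timeline.tap_times_s[:config.tap_count]):
                resp = eff.tap_start * eff.tap_decay ** i
                act[ts] = max(act[ts], resp * rng.uniform(0.8, 1.2))
            act = np.clip(act, 0, None)

            mm = act[:minutes.size * 60].reshape(minutes.size, 60).mean(axis=1)
            tdm_total = 3.0 * mm + rng.normal(0, 0.1, minutes.size)
            tdm_total = np.clip(tdm_total, 0, None)
            peri = np.clip(rng.normal(eff.periphery_bias, 0.05, minutes.size), 0, 1)
            zone_tdm = pd.DataFrame({"center": tdm_total * (1 - peri),
                                     "periphery": tdm_total * peri}, index=minutes)
            zone_act = pd.DataFrame({"center": mm * (1 - peri),
                                     "periphery": mm * peri}, index=minutes)
            traces.append(ActivityTrace(
                larva_id=f"{genotype}_{li:02d}", genotype=genotype,
                activity=act, zone_tdm=zone_tdm, zone_activity=zone_act,
                trial=trial))
    return traces


# ---------------------------------------------------------------------------
# fish-pair trajectories

def gen_pair_trajectories(config: SimConfig,
                          genotypes: tuple = ("Het", "Del"),
                          pair_id: str = "pair1",
                          pair_index: int = 0) -> TrajectoryPair:
    """Leader-follower pair in a circular arena.

    Fish 0 (leader) performs a correlated random walk: constant cruise
    speed with noise and an Ornstein-Uhlenbeck heading increment.
    Fish 1 (follower) turns toward the leader's position at rate
    ``follow_gain`` (1/s) on top of its own heading noise; at gain 0
    the two walks are independent and isotropic.  Positions are
    reflected at the wall, so every frame satisfies r <= R.
    """
    rng = _rng(config, 2, pair_index)
    n = config.n_frames
    dt = 1.0 / config.fps
    R = config.arena_radius_cm
    speed = 3.0           # cm/s cruise speed
    heading_sd = 1.2      # rad/sqrt(s) OU heading noise
    pos = np.zeros((2, n, 2))
    theta = rng.uniform(0, 2 * np.pi, size=2)
    xy = rng.uniform(-R / 2, R / 2, size=(2, 2))
    for t in range(n):
        for i in (0, 1):
            if i == 1 and config.follow_gain > 0:
                to_leader = xy[0] - xy[1]
                if np.linalg.norm(to_leader) > 1e-9:
                    bearing = np.arctan2(to_leader[1], to_leader[0])
                    dtheta = np.angle(np.exp(1j * (bearing - theta[1])))
                    theta[1] += np.clip(config.follow_gain * dtheta * dt,
                                        -np.pi / 2, np.pi / 2)
            theta[i] += heading_sd * np.sqrt(dt) * rng.normal()
            v = speed * np.clip(rng.normal(1.0, 0.2), 0.2, 2.0)
            step = v * dt * np.array([np.cos(theta[i]), np.sin(theta[i])])
            nxt = xy[i] + step
            r = np.linalg.norm(nxt)
            if r > R:
                # reflect across the wall tangent and bounce the heading
                nxt *= (2 * R - r) / r
                normal_ang = np.arctan2(nxt[1], nxt[0])
                theta[i] = 2 * normal_ang + np.pi - theta[i]
                r2 = np.linalg.norm(nxt)
                if r2 > R:
                    nxt *= R / r2
            xy[i] = nxt
            pos[i, t] = xy[i]
    return TrajectoryPair(positions=pos, fps=config.fps, genotypes=genotypes,
                          pair_id=pair_id, arena=Arena(radius_cm=R))


# ---------------------------------------------------------------------------
# expression counts

def gen_expression_counts(config: SimConfig,
                          host_shift: float = 0.0,
                          paralog_shift: float = 0.0,
                          shifted_line_fraction: float = 0.6
                          ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-line WT/Del negative-binomial counts with a planted pathway.

    The first ``pathway_size`` genes form the planted set: in the first
    ``shifted_line_fraction`` of lines their Del mean is scaled by
    2**(+-pathway_shift), alternating direction line to line (some up,
    some down — a coordinated but not unidirectional program).
    ``host_shift``/``paralog_shift`` (log2) apply to each line's host
    gene and its two paralogs in Del samples.  Samples are assigned to
    two batches by replicate parity.

    Returns (counts genes x samples, sample sheet, truth dict with
    ``pathway_genes``, ``shifted_lines`` (line -> sign), ``host_gene``
    and ``paralogs`` per line).
    """
    genes = pd.Index([f"gene{g:05d}" for g in range(config.n_genes)], name="gene")
    lines = [f"line{i}" for i in range(config.n_lines)]
    base_rng = _rng(config, 3, 0)
    base_mu = np.exp(base_rng.normal(4.0, 1.2, config.n_genes))
    pathway = list(genes[:config.pathway_size])
    n_shifted = int(round(shifted_line_fraction * config.n_lines))
    shifted_lines = {lines[i]: (1 if i % 2 == 0 else -1) for i in range(n_shifted)}
    host_gene = {line: genes[config.pathway_size + 2 * i]
                 for i, line in enumerate(lines)}
    paralogs = {line: [genes[config.pathway_size + 2 * config.n_lines + 2 * i + j]
                       for j in (0, 1)] for i, line in enumerate(lines)}

    cols, col_meta = [], []
    data = {}
    for li, line in enumerate(lines):
        for genotype in ("WT", "Del"):
            for rep in range(config.n_reps):
                rng = _rng(config, 3, 1 + li * 100 + (genotype == "Del") * 50 + rep)
                mu = base_mu.copy()
                if genotype == "Del":
                    if line in shifted_lines:
                        mu[:config.pathway_size] *= 2.0 ** (
                            shifted_lines[line] * config.pathway_shift)
                    hi = genes.get_loc(host_gene[line])
                    mu[hi] *= 2.0 ** host_shift
                    for p in paralogs[line]:
                        mu[genes.get_loc(p)] *= 2.0 ** paralog_shift
                if config.dispersion > 0:
                    r = 1.0 / config.dispersion
                    counts = rng.negative_binomial(r, r / (r + mu))
                else:
                    counts = rng.poisson(mu)
                name = f"{line}_{genotype}_{rep}"
                data[name] = counts
                cols.append(name)
                col_meta.append({"sample": name, "line": line,
                                 "genotype": genotype,
                                 "batch": f"b{rep % 2}"})
    counts = pd.DataFrame(data, index=genes)[cols]
    sheet = pd.DataFrame(col_meta).set_index("sample")
    truth = {"pathway_genes": pathway, "shifted_lines": shifted_lines,
             "host_gene": host_gene, "paralogs": paralogs}
    return counts, sheet, truth
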