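# Methods

This note documents the models and procedures implemented in `mexphen`, the
parameter choices that matter, the synthetic-data generators and what they
do and do not emulate, and the numerical conventions.

## Splicing-program calling (`mexphen.splicing`)

A PSI table holds events × samples inclusion values in [0, 100] with
per-cell coverage-quality codes ordered `N < VLOW < LOW < OK < SOUND`; `N`
means insufficient coverage and any PSI at `N` is treated as missing. The
default quality floor is `VLOW`.

For a target tissue group, per event:

* a tissue group is **valid** when it has at least `min_rep` (default 1)
  samples at or above the quality floor; its mean PSI is the mean over
  those samples;
* the event is **eligible** when the target group is valid and at least
  `n_groups` (default 5) groups are valid;
* ΔPSI_target is the target mean minus the *unweighted mean of the other
  group means* (each tissue counts once, regardless of sample number);
  ΔPSI_global is the target mean minus the mean over all pooled non-target
  samples from valid groups;
* the event is **called** when |ΔPSI_target| ≥ `min_dpsi` (15) and
  |ΔPSI_global| ≥ `min_dpsi_glob` (25). By default the call additionally
  requires ΔPSI_target > 0: a neural *program* is an inclusion gain, and
  depletion events are not neural exons. The flag `require_enrichment`
  turns the direction requirement off, restoring the pure |ΔPSI| reading.
* groups listed as excluded for the target (tissues with known partial
  inclusion overlap, e.g. endocrine pancreas for a neural target) are
  removed from both the eligibility count and both comparison means.

Regulator response takes the ΔPSI (mutant − control) of every available
loss-of-function comparison and classifies by the minimum: `affected` when
min ΔPSI < −15, `no_coverage` when no comparison was covered. Conservation
classes use the ortholog presence and the target-species neural ΔPSI with
the ≥ 15 threshold. Exon length classes: 3–27 (microexon), 28–51, > 51 nt;
lengths below 3 nt are invalid events.

Missing-value imputation (`impute_group_means`) exists for heatmap-style
visualisation only and never feeds the caller.

Tie behaviour: an event whose target group equals an excluded group name is
simply compared without that group; the target itself is never dropped.

## Larval activity (`mexphen.activity`)

The protocol timeline is fixed in half-open minutes: habituation [0, 5),
light baseline [5, 30), dark [30, 40) ∪ [50, 60) ∪ [70, 80), light
[40, 50) ∪ [60, 70), then re-habituation and 30 taps at 1 Hz starting at
second 5400. Seconds are averaged per minute first; interval means average
the minute means, so within-minute reordering cannot change them.

Transitions: per light→dark transition, LD = first dark minute − last
preceding light minute (the baseline counts as light); DL symmetric.
Same-type transitions are averaged.

Taps: the response to a tap is the activity in the single 1 s bin starting
at the tap (taps are 1 s apart, so bins tile the train); "responding"
means strictly positive activity. Larvae silent on all of taps 1–3 are
flagged low responders and excluded from tap statistics downstream.
Habituation read-outs are `act1 − mean(taps 3–5)` and
`act1 − mean(taps 21–30)`.

Thigmotaxis: per minute, 100 · TDM_periphery / (TDM_center +
TDM_periphery); the per-condition value is the **median over minutes of
movement** (zone activity > 0), chosen over a ratio of sums because the
per-larva statistic reported in this assay is a median and the median is
robust to single-minute tracking glitches. Larvae whose per-minute
activity/TDM Pearson correlation is below 0.9 are excluded (positional
tracking inconsistent with the pixel-based activity); a condition with
fewer than 3 moving minutes yields no value. The printed low-movement rule
is ambiguous between "moving < 3 min" and "immobile < 3 min"; we exclude
larvae with fewer than 3 minutes of movement per condition (a larva that
never moves carries no positional information).

Trial-level QC: trials with fewer than 3 larvae in any genotype are
dropped after larva-level exclusions. An optional rule dropping trials
whose WT median DL response is ≥ 0 (WT larvae are expected to dip when
lights come on) is off by default.

The genotype test is the median p of `n_perm` = 100 two-sided Wilcoxon
rank-sum tests, each on 10 observations subsampled per genotype (without
replacement when the group allows). With group sizes at the subsample this
reduces to a single rank-sum test and is exactly calibrated; with larger
groups the median-p is a stability summary and is conservative as a test —
it is reported as a ranking/screening statistic, not a calibrated p-value.
Percent change versus WT divides by the WT median, substituting a
caller-supplied category floor when that median is zero.

## Social behavior (`mexphen.social`)

Positions are linearly interpolated across gaps of ≤ 5 frames; longer gaps
stay missing and drop out of frame-wise statistics. Positions are smoothed
with a Gaussian kernel (σ = 1 frame, configurable; σ = 0 for closed-form
checks), velocity is the central difference, acceleration the second
difference. The tangential component is a·v̂ and the normal component the
magnitude of the residual; both are undefined below 0.1 cm/s, where the
heading is meaningless.

Ratio-in-front counts frames where heading · (other − focal) > 0 — a
half-plane, not a cone, since no view angle is part of the definition; a
cone angle is exposed in configuration. Polarization for a pair is
|½(û₁ + û₂)| per frame (the standard order parameter specialised to
N = 2: 1 parallel, 0 antiparallel, √2/2 orthogonal), summarised by its
median. The periphery is r ≥ 0.8 R inclusive, with r clamped at R against
tracking jitter. Per-fish summaries use medians (speed, accelerations,
normalized radius), the summed path length for distance traveled, and raw
frame counts for periphery time (the fraction is recoverable from the
frame total).

Comparison scheme: individual metrics from homotypic pairs enter as the
pair's two-fish average (one observation per pair, avoiding double
counting of near-identical values); heterotypic pairs contribute each fish
labeled by genotype. Ratio-in-front stays per fish in both schemes — it is
the one metric whose two within-pair values are complementary rather than
redundant. Pair metrics compare Het-Het against Het-Del and against
Del-Del. All comparisons are unpaired two-sided Wilcoxon rank-sum tests;
the within-pair Het-vs-Del comparison is treated as unpaired to match the
rank-sum framework.

## Transcriptome compensation (`mexphen.expression`)

Degradation correction is a pass-through hook (`correct_degradation`)
accepting externally corrected counts; correcting degradation bias itself
is upstream tooling, not part of this package.

Stabilization: a robust library size per sample is the median ratio of its
counts to the geometric mean of the library-normalized profiles (genes
expressed in every sample); the size factor is that library size per
million and the stabilized value log2(count/sf + 1) — a log2 robust-CPM.
Building the reference on normalized profiles makes the transform exactly
equivariant to per-sample scaling. This is a monotone variance-stabilizing
approximation; downstream statistics use only differences of stabilized
values, for which the exact transform family is immaterial.

Batch adjustment fits WT samples only: per gene and batch, the WT
batch-mean deviation from the WT grand mean; the batch's across-gene mean
effect is subtracted in full and the gene-specific deviations around it
are shrunk by an empirical-Bayes factor τ²/(τ² + σ²) with τ² the excess of
their across-gene variance over the expected sampling variance. Shrinking
the deviations toward the batch mean (rather than everything toward zero)
removes a constant batch offset completely while still damping noisy
gene-level estimates; fitting on WT only guarantees genotype effects are
never absorbed.

Per line, Δ = mean(Del) − mean(WT) per gene. Host-gene and paralog changes
are flagged when their Δ percentile within the line's distribution is
≤ 10 or ≥ 90. The joint score is Σ_lines |Δ|, ranked descending with ties
broken by gene identifier.

Preranked GSEA: the running sum steps up by |score|^w (w = 1, normalized
over set members) at hits and down by 1/(N−k) at misses, bridge-normalized
by (N−k)/N so the unweighted statistic is the classic two-sample KS
distance (a top-k set peaks at 1 − k/N). The null permutes gene labels
(equivalently, draws k random positions), matching a preranked design;
NES = ES / mean |null ES| of the matching sign and p is the matching-sign
null tail with add-one correction, BH-adjusted across sets. Set universe
is the ranking; sets are intersected with it before the size filter
(min 5, max 2000). The positive-only mode keeps sets with ES > 0 — the
right test for the non-negative Σ|Δ| score. Per-line re-scoring of cluster
unions uses the signed Δ ranking two-sidedly, since per-line responses go
in both directions.

GO clustering: Jaccard distance 1 − |A∩B|/|A∪B| between enriched terms
(padj < 0.01), complete-linkage hierarchical clustering, tree cut at 0.9
(members of a cluster share > 10% of genes), clusters kept when any member
has p < 0.001, represented by their most significant term; the union gene
set is what gets re-scored per line.

## Resampling statistics (`mexphen.stats`)

Rank-sum tests use the exact null distribution when the pooled sample is
≤ 20 without ties, otherwise the normal approximation with tie and
continuity correction. The bootstrap-Wilcoxon procedure draws, per
iteration, 50 points per group with replacement (per experiment stratum
when strata are given — resampling respects the replicate structure) and
reports the median of the 10,000-test p distribution. Draws are with
replacement even when groups are large: the procedure is a bootstrap, and
sampling without replacement at the subsample size would change the
statistic's meaning with group size. BH adjustment is the standard step-up
with enforced monotonicity. A rank-based two-way fixed-effects ANOVA
(genotype + founder) is provided for two-founder designs as a pragmatic
omnibus test. No multiple-testing correction is applied across behavioral
features by default — nominal p-values are reported as effect screens —
with a global BH switch available.

Star bands are `*** p < 1e-4`, `** p < 1e-3`, `* p < 1e-2`. (Published
legends of this assay family sometimes print the inverted intervals
"0.01 < p ≤ 0.001"; we read them as the standard nested bands.)

## Synthetic-data generators (`mexphen.synthetic`)

All generators draw one RNG stream per generated entity (event, larva,
pair, sample) from the master seed, so subsetting an experiment leaves the
remaining entities byte-identical; identical configs give byte-identical
outputs.

* **PSI tables**: background PSI uniform in [5, 35] per event, Gaussian
  noise (SD 3 PSI), planted neural events add `dpsi_effect` (default 40)
  in the neural group; per-cell dropout to `N` with probability
  `coverage_dropout`; a low-coverage class keeps fewer valid groups than
  eligibility requires.
* **Activity**: zero-inflated gamma seconds (movement probability 0.7,
  gamma shape 2) around condition means of 5 (light) and 10 (dark)
  %Δpixels — larvae move more in the dark; dark onsets add an
  exponentially decaying burst, light onsets a matching suppression
  (τ = 20 s); tap responses start at 20 and decay geometrically (0.9 per
  tap by default). Genotype effects are multipliers on baseline level,
  transition amplitude and tap start/decay, plus a periphery-bias
  parameter (default 0.65) splitting per-minute distance between zones.
  Noise models are chosen to match the supports of the real exports
  (non-negative, zero-inflated seconds); the defaults are a plausible
  wild-type regime, not a fit to any particular recording.
* **Trajectories**: fixed time step 1/fps; the leader is a correlated
  random walk (cruise 3 cm/s with 20% speed noise, heading noise
  1.2 rad/√s) reflected at the circular wall (radius 21 cm, the assay
  arena); the follower additionally turns toward the leader's position at
  rate `follow_gain` (1/s). Gain 0 gives two independent isotropic walks —
  the leadership null — and increasing gain produces monotonically
  stronger front-back asymmetry and tighter pairs.
* **Counts**: per-gene means log-normal (log-mean 4, log-SD 1.2), negative
  binomial with dispersion 0.1 (var = μ + 0.1 μ²); a planted pathway of 50
  genes shifted by ±`pathway_shift` log2 units in Del samples of 60% of
  lines, alternating direction line to line — coordinated but not
  unidirectional, as observed for compensatory programs; host-gene and
  paralog shifts injectable; two batches by replicate parity.

What the generators do **not** emulate: real tissue autocorrelation and
shared regulatory structure across PSI events; circadian and
inter-clutch variability in activity; fish body posture, wall-following
biomechanics and tracking-identity errors; count overdispersion
heterogeneity and transcript-degradation bias. Passing tests therefore
demonstrate the correctness and calibration of the *pipeline* under its
assumed statistical structure, not performance on any real recording.

## Problem sizes and calibration checks

The acceptance computations use desk-scale sizes chosen as the package's
own defaults: 150–300 events, 10–12 larvae per genotype, 3,000–18,000
frames per pair, 600–2,000 genes, 100–2,000 permutations, 200 null
simulations for calibration. Type-I calibration of the permutation test is
assessed in the paper's own design (10 per genotype, subsample 10), where
the median-p reduces to a single exact rank-sum test; the bootstrap
median-p is checked to never exceed the nominal rate (it is conservative
by construction when groups exceed the subsample).

## Known limitations

* The calling path assumes one target group per run; multi-target scans
  loop over targets.
* The bootstrap/permutation median-p statistics are screening summaries;
  their null distribution is only uniform in the degenerate
  subsample-equals-group case.
* The EB batch adjustment assumes additive batch effects on the stabilized
  scale and at least one WT sample per batch.
* GSEA leading-edge reporting uses the peak position convention
  (positive ES: hits before the peak; negative: after).
* Trajectory kinematics are reported only where the heading is defined;
  near-stationary fish contribute no acceleration or leadership frames.
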