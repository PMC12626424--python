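# mexphen

Quantitative analysis chain for phenotyping neural **microexon** programs in
zebrafish: calling tissue-enriched exons from PSI matrices, larval
activity/habituation/thigmotaxis phenotyping, pair-trajectory social-behavior
metrics, and cross-line transcriptomic compensation analysis — with seeded
synthetic-data generators so every stage is testable end to end without any
external download.

## The scientific problem

Neural microexons (3–27 nt alternative exons) are switched on in neurons by
the Srrm3/Srrm4 splicing regulators. Losing the regulators causes severe
phenotypes; losing one microexon usually does not. Asking *why* requires a
chain of quantitative analyses:

1. **Program calling.** From an events × samples percent-spliced-in matrix
   (PSI ∈ [0, 100]) with per-cell coverage codes (`N < VLOW < LOW < OK <
   SOUND`), an exon is neural-enriched when, over tissue groups with a valid
   mean (≥ 1 sample at VLOW or better, ≥ 5 valid groups),
   ΔPSI_target = mean(neural) − mean(other group means) ≥ 15 **and**
   ΔPSI_global = mean(neural) − mean(pooled other samples) ≥ 25.
   Events respond to regulator loss when the lowest ΔPSI (mutant − control)
   across comparisons is < −15; length classes (3–27, 28–51, > 51 nt) are
   tested for association with the response by a two-sided Fisher exact test.
2. **Larval phenotyping.** From 1 Hz activity exports (% Δpixels) over a
   fixed protocol (5′ habituation, 25′ light baseline, dark/light
   alternation, 30 taps at 1 Hz): per-larva interval means, transition
   responses (first minute after − last minute before a light change), tap
   habituation (response to tap 1 minus means over taps 3–5 and 21–30), and
   thigmotaxis (median per-minute % of distance moved in the outer ring,
   moving minutes only). Genotype effects use the median p of 100
   subsampled Wilcoxon rank-sum tests (10 observations per genotype).
3. **Social behavior.** From pair trajectories at 30 fps in a circular
   arena: speed, normal/tangential acceleration, distance traveled,
   periphery time (r ≥ 0.8 R), normalized distance to center, ratio-in-front
   (leadership), pair polarization |½(û₁ + û₂)| and inter-individual
   distance, compared across homotypic/heterotypic pair schemes.
4. **Compensation.** Per deletion line, Del − WT differences on a
   variance-stabilized scale (robust size factors + log2), WT-fitted
   empirical-Bayes batch adjustment, host-gene/paralog decile flags, and —
   to find pathways responding across many lines — a positive preranked
   GSEA on Σ_lines |Δ| with a gene-permutation null, Jaccard clustering of
   enriched GO terms (complete linkage, tree cut 0.9), and per-line NES of
   the cluster unions on signed Δ rankings.

## Worked example

```sh
python analysis/01_simulate_inputs.py
python analysis/02_neural_program.py
```

prints (abridged):

```
caller: 60 called, 60 planted, 60 recovered (100.0%)

length-class composition of the 708 neural exons:
            count  percent
micro_3_27    246     34.7
mid_28_51     139     19.6
long_gt51     323     45.6

regulator loss-of-function response (dPSI < -15):
              affected  covered  percent_affected
micro_3_27         191      243              78.6
mid_28_51           82      136              60.3
long_gt51          122      317              38.5

microexons vs long exons, affected vs not: odds ratio 5.87,
two-sided Fisher p = 8.36e-22
```

The caller recovers every planted neural event from a synthetic PSI table at
a 40-PSI effect; the composition and response tables run the package's
reporting operations on the published per-class counts of the 708 zebrafish
neural exons, reproducing the published percentages and the strong bias of
regulator sensitivity toward microexons (5.9-fold odds, p ≈ 8.4e-22).
Steps `03`–`05` phenotype a simulated larval clutch, analyze simulated fish
pairs, and run the compensation chain; each prints the effects it planted
and the statistics recovering them, and writes its tables under `results/`.

A thin CLI mirrors the stages:
`mexphen simulate|splice-call|activity|social|expression --help`.

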