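# broadcna

Analysis pipeline for studying early tumor evolution through **autosomal
broad copy-number alterations** (CNAs spanning more than 3,000,000 bp,
assigned to chromosome arms) in segmented copy-number cohorts such as
TCGA-BRCA.

The pipeline:

1. **segio** — reads SEG-style tumor/normal profiles (1-based inclusive
   coordinates), deduplicates samples per patient by priority rules (FFPE,
   later creation/shipment dates, other-project use), and splits segments at
   GRCh38 centromeres so every alteration lies within a single arm.
2. **calling** — approximates each sample's copy-neutral baseline (the
   minimum-SD group of segments covering a majority of autosomal base
   pairs), derives cohort gain/loss offsets from the pooled broad segments
   of the normal panel (Tukey-fence outlier removal), widens them per sample
   by the baseline spread, applies a subclonality filter (deviations below
   1/8 of the most extreme deviation) and a consecutive-alteration split
   rule (1/4 of the extreme), and emits arm-level broad-CNA calls plus
   per-patient counts.
3. **frequency** — builds the patients × (arm, direction) event matrix and
   computes patient-level, event-level, mutation, and subtype frequency
   profiles, stratified by per-patient broad-CNA count.
4. **resample** — simulates patients whose event counts match a target
   subset by inverse-CDF draws from a reference frequency distribution and
   compares frequency vectors with Kendall tau-b, including convergence
   curves over expanding count intervals (1..5, 1..10, ...).
5. **trends** — fits locally weighted regression (tricube kernel, AICc span
   selection) to per-count patient frequencies and proposes an acquisition
   order from half-rise counts.
6. **synthcohort** — generates tumor/normal cohorts with known ground truth
   (per-sample baseline shift, purity-diluted alteration heights,
   segment-level noise, staged acquisition order, small normal CNAs) so
   every stage is testable without external data.

## CLI

```sh
# synthetic cohort with ground truth
broadcna synthcohort --seed 1 --n-patients 100 --outdir out/synth

# broad-CNA calling against the normal panel
broadcna call --seg out/synth/tumors.seg --normals out/synth/normals.seg \
    --arm-map out/synth/arm_map.tsv --metadata out/synth/metadata.tsv \
    --mutations out/synth/mutations.tsv --outdir out/called

# frequency profiles of the 1-10 broad-CNA subset
broadcna freq --matrix out/called/matrix.tsv --lo 1 --hi 10 \
    --mode patient --out out/patient_freq.tsv

# event-count-conditioned simulation and convergence curves
broadcna simulate --matrix out/called/matrix.tsv --seed 1 --out out/sim.tsv
broadcna converge --matrix out/called/matrix.tsv --seed 1 \
    --intervals 5:40:5 --out out/converge.tsv

# trends and acquisition-order proposal
broadcna trends --matrix out/called/matrix.tsv --outdir out/trends

# everything end-to-end with a manifest
broadcna run --seed 1 --n-patients 50 --outdir out/full
```

All outputs are plain TSV/JSON; reruns with the same seed are bit-identical.

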