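# Methods

This document records the statistical and numerical model implemented by
`enviromics`: what each stage computes, every default parameter and why,
what the synthetic generators do and do not emulate, and the deliberate
resolutions of under-specified corners.

## Study design

`StudyDesign` encodes a paired layout: the same donor labels recur in
every treatment arm (each donor's organoids are split across arms), so
donor is a blocking factor. The canonical arms are seven — `vehicle`
first, then `WIN`, `IL17a`, `cortisol`, `nicotine`, `ethanol`,
`endomorphin` — and `vehicle` is always the control. Blank runs are
extraction controls carrying no analyte signal.

## Targeted metabolite quantification (`quant`)

For each library analyte (name, ion adduct, theoretical m/z, polarity,
expected RT):

1. **m/z window** — relative half-width of `ppm_tol` (default 5 ppm)
   around the theoretical m/z, evaluated as the half-open interval
   `[mz·(1−tol), mz·(1+tol))`. Half-open so a centroid falling exactly on
   a boundary belongs to exactly one of two adjacent windows.
2. **Consensus apex** — per study-sample run, the apex is the RT of the
   maximum in-window centroid within ±`search_window` (default 30 s,
   i.e. ±0.5 min) of the library RT; the consensus is the **median** of
   those per-run apexes over runs with any signal. Blanks never vote.
   The median is robust to a minority of runs locking onto background.
3. **Peak height** — the maximum in-window centroid intensity within
   ±`apex_tol` (default 7.5 s) of the consensus apex. Ties resolve to
   the earliest RT (deterministic). Height, not area: heights of
   centroided Gaussian peaks are what the generators record exactly, and
   the blank-threshold rule is defined on heights.
4. Runs whose polarity never matches the analyte raise
   `PolarityMismatchError` rather than silently reporting zero.

The two-stage tolerance scheme (wide search window to *find* the peak,
narrow apex tolerance to *measure* it) decouples retention-time drift of
the chromatography from the integration width of a single peak.

## Metabolome statistics (`metabostats`)

- **Detection threshold** per analyte:
  `max(sn_multiple × mean(blank heights), floor)` with `sn_multiple = 3`
  and `floor = 10,000` (arbitrary intensity units). At least one blank is
  required. A height **equal** to the threshold counts as detected
  (inclusive boundary).
- **Imputation** — non-detections are replaced by the threshold itself.
  This is conservative for fold changes (shrinks them toward zero) and
  keeps every test defined.
- **Differential** — per analyte, group vs control log2 fold change of
  arm means plus a two-sample pooled-variance t-test (Welch optional) on
  the imputed values; significance is the **strict** rule `p < 0.05`.
  Degenerate conventions: n < 2 in either arm → `p = NaN` with a warning;
  both arms constant → `p = 1` (equal means) or `p = 0`.
- **Infinite fold changes** — if *every* control sample is undetected
  while the treated arm has signal, the log2FC is `+Inf` with reason
  `control_undetected` (the GTP pattern: an infinite ratio via control
  non-detection); the mirrored case gives `−Inf`. Volcano exports place
  these at a signed sentinel abscissa (±10) and flag them, so they stay
  plottable without pretending to a finite estimate.
- **Clustering** — heatmap leaf order via complete-linkage agglomerative
  clustering on Euclidean distances of the imputed matrix (rows and
  columns independently). Constant matrices warn and keep the
  deterministic linkage order.
- Benjamini–Hochberg adjusted p-values are exported alongside raw ones;
  the headline significance rule remains raw `p < 0.05` to match the
  primary analysis convention.

## Proteome statistics (`protstats`)

Input is a protein × sample intensity matrix (linear scale, `NaN` =
missing); reporter-ion extraction and search-engine FDR are upstream
concerns. Processing order:

1. **Complete-case filter** — keep proteins quantified in every sample;
   no imputation. This is the "quantifiable in all samples" population.
2. **log2, then quantile normalization** — every column's sorted values
   are replaced by the row means of the column-sorted matrix; tied
   values receive the mean of the tied reference positions via linear
   interpolation on average ranks. Invariants (tested): all sorted
   columns identical to ≤ 1e−9, idempotence, and the exact 2×2 example
   `[[1,4],[3,2]] → [[1.5,3.5],[3.5,1.5]]`.
3. **QC** — per-group coefficients of variation on the **linear** scale
   (sd/mean per protein), median CV per group, and squared Pearson
   correlations between samples on the **log2** scale.
4. **Differential** — omnibus one-way ANOVA per protein (vectorized);
   Dunnett many-to-one post-hoc vs vehicle only where the omnibus passes
   `p < alpha`; a protein is differential in a group iff both pass.
   SciPy's Dunnett implementation integrates a multivariate t by
   quasi-Monte-Carlo, so a fixed `random_state` is threaded through for
   reproducibility. A separate pairwise t-test analysis (group vs
   control only) provides the per-group differential counts; it uses the
   same t-test primitive as the metabolite module, so identical numbers
   give identical p-values across modules (tested).

## Cytometry (`cytometry`)

**DNA-content deconvolution** (Dean–Jett–Fox style). Histogram of 256
bins over `[0, 1.1 × 99.5th percentile]`. Model: Gaussian G1 and G2/M
peaks with the G2/M mean constrained to 1.8–2.2 × the G1 mean (the
physical near-doubling of DNA content), and an S-phase component that is
a uniform density between the two means convolved with the peak width
(analytically, a difference of normal CDFs). Fitting is variable
projection: component amplitudes are profiled out by non-negative least
squares at every step of a bounded least-squares refinement over
(μ₁, σ₁, μ₂, σ₂) — a purely sequential fit leaves the G2/M estimate
biased toward the S plateau. The **sub-G1 fraction** (apoptotic
fragmentation proxy) is counted directly from raw events below
μ₁ − 3σ₁, not from the model, so it cannot be absorbed by a mis-fit
component; the remaining mass is split by the fitted amplitudes. All
quantities scale with the data (scale equivariance is tested). A
relative fit residual above 0.15 sets `low_confidence`.

**Quadrant gating.** Per-channel thresholds are the 0.999 quantile of an
unstained sample (≥ 1,000 events required); events are assigned to the
four quadrants by **strict** `>` on the cleaved-PARP and phospho-H2AX
channels. "PARP-positive overall" = single-positive + double-positive.
Group fold changes are ratios of group-mean percentages over the control
mean, with one-way ANOVA plus Dunnett on the per-sample percentages; a
zero control mean leaves the fold change `NaN` and flagged `undefined`
rather than infinite, since a percentage of exactly zero is a sampling
event, not a structural absence.

## Synthetic generators (`synthetic`)

Design goal: every generated dataset carries exact ground truth, and
each run's content depends only on `(seed, sample_id)` — adding samples
to a study never changes existing ones (RNG keyed by
`[seed, crc32(sample_id)]`).

**Metabolome runs.** Gaussian chromatographic peaks of fixed FWHM
(default 12 s) on polarity-alternating scan grids (2 s spacing; negative
scans offset by half a step, emulating polarity switching). The apex RT
(library RT + Gaussian jitter, sd 1.5 s) is snapped to the matching
polarity's scan grid so the sampled maximum equals the recorded
ground-truth height **exactly**. Peak heights carry mean-corrected
log-normal noise (default CV 5%); observed m/z jitters by 1.5 ppm per
scan. Background centroids are uniform below one third of the detection
floor, so neither samples nor blanks can trigger detection by accident;
blanks carry background only. Analyte pairs that would co-elute within
2× the m/z tolerance raise a warning. Default truths cover 18 polar
metabolites with depletion effects on the study's scale (log2 −0.13 to
−2.72) and one analyte absent from the control arms.

**Proteome matrices.** Log-normal intensities around per-protein base
levels (log2 ~ N(20, 2)), additive per-donor log2 offsets (sd 0.15,
shared across arms — the paired-design signature), log2 group effects on
a chosen subset of proteins (magnitude floored at 0.2 so every spike is
nominally detectable, each hitting 1–3 treated arms), multiplicative
noise (CV 5%) and missing-completely-at-random cells (default rate 1%,
which leaves roughly three quarters of proteins complete across 28
samples, matching the intended complete-case population size).

**Cytometry events.** DNA content: multinomial class sizes over
(sub-G1, G1, S, G2/M); G1 ~ N(μ, cv·μ), G2/M ~ N(2μ, 2cv·μ), S uniform
on (μ, 2μ) plus G1-width Gaussian noise, sub-G1 uniform below μ(1−3cv).
Damage panel: four bivariate log-normal clusters with negative/positive
centres two decades apart (10 vs 1000) and 0.2-decade spread, so any
mid-gate threshold sits ≥ 3 cluster SDs from every centre and the
generator's per-event quadrant labels are effectively unambiguous.
Presets encode the study-scale magnitudes: control fractions
(0.05, 0.60, 0.20, 0.15), a 2.29× sub-G1 increase in the WIN arm,
control rates of 1.58% PARP+ and 0.4% double-positive, and per-arm
PARP+ fold increases spanning 1.71–14.56.

**Not emulated:** isotope patterns, chimeric/overlapping peaks beyond
the co-elution warning, retention-time drift within a run, detector
saturation, TMT reporter-ion interference, compensation/spillover in
cytometry, doublets, and FCS binary format (event tables are CSV — the
gating logic is format-independent).

## Pipeline and reproducibility

`PipelineConfig` (YAML-serializable) carries the design, all tolerances
and stage constants; `validate_config` returns a list of violations
(alpha range, apex tolerance vs search window, post-hoc name, gate
quantile, event-count minimums). `run_all` executes
generate → quantify → statistics for all three assays, writes every
table with a fixed float format (`%.10g`) and JSON with sorted keys, and
fingerprints all artifacts with SHA-256; identical config + seed gives
byte-identical outputs. Derived RNG streams use spawn-key lists
(`[seed, stage, group, sample]`), never arithmetic on the seed. The CLI
exposes synthetic end-to-end runs; user data flows through the stage
subcommands, which compose exactly the same library calls.

## Validation strategy

The acceptance suite (`tests/test_acceptance.py`, with the same
quantities regenerated standalone by `scripts/acceptance.py`) checks: printed-count arithmetic
(4,857/5,120 → 94.86%); equality of the extraction and gating
implementations with brute-force enumeration on randomized inputs;
enumerated boundary cases of the threshold/imputation rules; null
calibration of all three test families (t-test and ANOVA call rates
0.05 ± 0.01 on ≥ 2,000 null features; Dunnett family-wise error within
two binomial standard errors of nominal over 400 null families);
sign recovery of −0.30 log2 spikes at n = 5 and CV 5% (≥ 80% required;
observed ≈ 100%); the absent-in-control infinite-fold-change flag under
repeated seeds; cell-cycle fraction recovery within ±0.03 per
compartment over 20 seeds with the sub-G1 fold within ±15% of the
configured 2.29; quantile-normalization invariants; and byte-identical
pipeline determinism.
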