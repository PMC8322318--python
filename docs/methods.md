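# Methods

This note documents the models, estimators and design choices behind
relicmeth, in the order the pipeline runs, together with what the synthetic
data does and does not emulate.

## Measurement model and background correction

Observed probe intensity is modelled as the normal + exponential (normexp)
convolution X = S + B with true signal S ~ Exponential(α) and background
B ~ Normal(μ, σ²).  The out-of-band (OOB) values of type I probes are
background-only by design, so per sample and per colour channel we estimate
μ and σ as the mean and standard deviation of the OOB values and
α = max(mean(in-band) − μ, α_floor).  Estimation is by moments, not maximum
likelihood: simple, fully testable, and adequate for this pipeline; it is an
approximation of the noob family of corrections, which fit the same
convolution.  Floors σ_floor = α_floor = 1 intensity unit guard degenerate
inputs (e.g. constant OOB fixtures).

Corrected intensity is the posterior mean
E[S | X = x] = m + σ·φ(m/σ)/Φ(m/σ), m = x − μ − σ²/α, evaluated via
`log φ − log Φ` for stability deep in the lower tail; results that still
underflow are floored at 10⁻⁶ (the function is then non-strictly monotone at
the floor, which the tests acknowledge).  A quadrature oracle (numerical
integration of the posterior density) verifies the closed form to four
significant digits across the working range.

## Detection p-values (out-of-band empirical null)

A probe is "detected" when its raw in-band total M + U is implausibly large
under background.  The null statistic must match the test statistic: M + U
is a *sum of two* background draws under the null, so the null set is the
per-probe OOB **totals** M_oob + U_oob (not the individual OOB values),
pooled per colour channel — the null for channel c comes from type I probes
designed for the opposite channel, whose OOB lies in c; type II probes are
tested against the combined null.  With the pseudo-count empirical p-value
p = (1 + #{null ≥ total}) / (N + 1), ties counting as ≥, a pure-background
sample is detected at the nominal rate (the calibration test holds the
detected fraction at 1 % ± 0.3 % for p < 0.01).  Detection always uses raw
intensities; betas always use corrected intensities — the standard division
of labour between detection masking and background correction.

## Betas and the strict filter

β = M/(M + U + offset) with offset 100 (the de-facto convention of standard
array pipelines; configurable).  The strict filter retains type I probes
with p < 0.01, then removes X/Y and SNP-associated CpGs.  Type II probes are
excluded outright: their two-channel read-out needs a dye-bias correction
that is anchored on normalization control probes, and in the degraded regime
those probes carry no usable signal.  Undetected betas are explicit missing
values, never 0 or 0.5.

## Synthetic reference panel

The generator emulates a compiled multi-study reference of nine tissues
(default 15 samples per tissue, 135 profiles, an ~2:1 train/validation
split — a half-scale stand-in for a ~300-profile compilation, sized so
tenfold cross-validation runs without fold reduction).

* **Baseline CpGs** draw a fixed per-probe beta from the bimodal mixture
  0.5·Beta(0.5, 8) + 0.5·Beta(8, 0.5), giving the characteristic peaks near
  0 and 1 (≥ 60 % of baseline CpG means fall outside [0.2, 0.8]).
* **Marker CpGs** (50 per tissue, autosomal non-SNP type I) have mean 0.15
  in the target tissue and 0.85 elsewhere, alternating direction.  Fifty per
  tissue keeps, at the severe-degradation preset, an expected ~8 surviving
  markers per tissue — the regime in which a top-5-per-tissue signature is
  still built from genuinely informative CpGs, as the method requires.
* **Age CpGs** follow β = clip(intercept + slope·age), slope ±0.01 per year
  with intercepts 0/1 so betas traverse [0.2, 0.8] over ages 20–80.  Their
  noise (logit sd 1.5, vs 0.3 for all other CpGs) is deliberately large: a
  reduced clock refitted on a handful of these CpGs then shows moderate
  train/validation R² — the reported operating regime of severely reduced
  clocks — rather than an unrealistically clean fit.
* **Sex structure**: females have background-only Y probes (betas missing,
  zero signal); males carry X at half intensity and Y autosomally.  The
  allosome counts (800 probes each) are sized so the detection-rate sex
  ratio is stable even at ~17 % detection.
* Per-sample noise is added on the logit scale and clipped to
  [0.001, 0.999], keeping betas in range with roughly symmetric noise near
  0.5.

## Inverse measurement model and degradation

Betas become intensities by splitting an Exponential(α = 10 000) true signal
as M = β·T, U = (1−β)·T and adding truncated-Normal(500, 100²) background to
every measured value (truncation, not rejection: negative fluorescence is
clipped, a < 10⁻⁶ event at the defaults).  OOB values are pure background
draws.  The signal scale is set so an intact sample detects > 95 % of type I
probes, as a good array does; with an exponential signal a few per cent of
probes always draw near-zero signal, which is why the default is 10 000
rather than a smaller value.

**Degradation** is a single parameter f = signal_fraction: each probe
independently *survives* with probability f (keeping its full-scale signal)
and is otherwise background-only.  A pure-attenuation alternative
(T ~ Exp(α·f)) was implemented first and rejected on evidence: by
memorylessness, the probes that pass detection then sit just above the
detection bound, and their corrected betas are affinely compressed toward
mid-range (measured slope ≈ 0.26, r ≈ 0.74 against the generating betas) —
whereas real degraded specimens show clean low/high methylation peaks in the
*detected* subset and beta correlations ≈ 0.94 with fresh tissue.  The
survival mixture reproduces exactly that: overall intensities collapse, but
the surviving minority carries near-pristine betas (measured r ≈ 0.97).

Two presets fix the study conditions: `TH` (f = 0.192, calibrated once so
~17 % of type I probes are detected — the observed regime of a recoverable
specimen, where ~24k of the platform's ~142k type I assays passed
filtering — with terminal damage p0 = 0.045) and `ACB` (f = 0.001, p0 =
0.012, where only the ~1 % detection false-positive floor remains and the
pipeline correctly stops after filtering).

## Deconvolution

Marker score for CpG c and tissue t: |mean_t − mean_rest| − λ·(sd_t +
sd_rest)/2 with λ = 1 (the two ingredients — mean difference and
within-group variability — combined in the simplest subtractive form;
one-vs-rest is the simplest reading of a per-tissue mean difference).
Selection runs stratified tenfold cross-validation on the training split,
aggregates per-fold rankings by mean rank (more stable than selection
frequency at these sample sizes), breaks ties lexicographically by probe id,
and reduces the fold count with an explicit warning when a tissue has fewer
training samples than folds.  Candidates are restricted to the query's
retained CpG set, mirroring the select-within-detected logic of the method.

The reference matrix holds per-tissue training means of the selected
(deduplicated) CpGs; mixtures are solved by active-set NNLS
(scipy.optimize.nnls), proportions are the coefficients normalised to sum
one, and a total coefficient mass < 10⁻⁶ flags the result undetermined.
Reference rows with missing sample betas are dropped pairwise, never
imputed — the same intersect-then-deconvolve handling used for external
atlases, which are additionally regrouped post hoc (e.g. blood subtypes →
"Leukocytes") by summing class proportions.  A 0.001-step simplex grid
search (with analytically optimal per-point scale) serves as the independent
oracle for 2- and 3-tissue problems.

## Reduced age model

The clock CpG list is an input (for synthetic runs, the planted age CpGs
stand in for a full multi-tissue signature; the presets plant 100 of them so
that a realistic handful survives filtering).  The model is plain OLS of
chronological age on the betas of the clock ∩ retained intersection — no
log-linear age transform — with errors on rank-deficient designs (naming
the collinear CpGs) and on n_train ≤ k + 1.  R² and RMSE on the validation
split travel with the model; predictions are clipped at zero with a flag.

Degraded-sample predictions are noisy and biased a few years *upward*: at
p < 0.01, roughly 1 % of dead probes pass detection, so ~5 % of the
surviving clock CpGs are background false-positives whose corrected betas
fall below 0.5 — which reads as "old" on CpGs that lose methylation with
age — pulling predictions toward the panel's mean age.  This is an honest
property of the strict-filter-then-retrain strategy, quantified by the
acceptance checks (mean prediction ≈ 34 years for a true age of 28 at the
severe-degradation preset, within the model's own ±2·RMSE validation band
in ≈ 95 of 100 runs).

## Sex inference

d_X and d_Y are detected fractions over all type I probes on X and Y
(before allosome removal, consistent with the pipeline's type I basis);
r = d_X/(d_X + d_Y).  The cutoffs (female ≥ 0.75, male ≤ 0.6, indeterminate
between) are package defaults for a rule that is inherently qualitative;
they are configurable and always echoed in the output.  At least 20 probes
per allosome are required.

## Embedding

Top-variance CpG selection (complete cases only, lexicographic tie-break)
followed by classical Torgerson MDS on Euclidean distances: double-centred
squared-distance matrix, top-2 eigenpairs, coordinates centred.  For data of
intrinsic dimension ≤ 2 the embedding reproduces the distance matrix to
10⁻⁶.  This deliberately replaces per-pair top-gene distance variants of
MDS plotting with one global top-variance set — simpler, deterministic, and
matching the "top-N most variable CpGs" framing.  Whether the query sample
participates in variance ranking is a flag (default: included).

## Damage profiles

freq_CtoT(i) = #{ref C, read T at 5′ offset i} / #{ref C at i}, with counts
retained for binomial standard errors and missing (not zero) frequencies
where the denominator is empty; mirrored G→A is included.  The read
simulator applies p(i) = p0·δ^(i−1) (δ = 0.5 preset — the fast geometric
decay typical of terminal deamination; only the position-1 rates are
externally anchored).  Indels/soft-clips are out of scope of the simplified
read table.

## Pipeline fallback policy

A degraded run may not support every stage.  Deconvolution requires at least
k × n_tissues retained candidate CpGs *and* ≥ 10 shared reference rows (the
candidate-count gate is what stops the near-total-loss preset, whose ~1 %
false-positive floor would otherwise feed pure noise into marker selection);
the age stage requires a non-empty clock intersection.  Skipped stages are
recorded with reasons in the report and the run still exits 0.  All
randomness derives from the single config seed; reports are reproducible
modulo the timestamp field.

## Known limitations

* The generator does not emulate: probe-specific affinity differences,
  spatial/batch effects, bisulfite-conversion failure, microbial background
  sequence, replicate beads, or real linkage between SNP flags and beta
  distributions.  Passing tests therefore demonstrate the pipeline's
  statistical machinery, not robustness to every artefact of real arrays.
* Moment-based normexp parameters underestimate α (in-band means average
  the β and 1−β signal shares); the conditional-expectation correction is
  exact only given those parameters.
* The NNLS reference assumes the query is a non-negative combination of the
  panel tissues; unrepresented tissue types load onto their nearest
  neighbours.
* Real IDAT ingestion is a declared adapter hook, not part of the tested
  surface; all tested I/O uses the project's TSV dialect.
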