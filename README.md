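# relicmeth

DNA-methylation BeadChip analysis for severely degraded specimens — with a
synthetic array simulator so the whole pipeline runs and is testable without
any external data.

## The problem

Infinium-style methylation arrays (450K/EPIC) measure, for each CpG, a
methylated and an unmethylated fluorescence intensity and summarise them as a
beta value β = M / (M + U + offset) ∈ [0, 1].  On DNA from ancient or
mummified tissue the signal is extremely low: most probes never rise above
optical background, standard quality control fails outright, and conventional
tools for tissue classification, age prediction and sex inference cannot be
applied as shipped.  Yet a *minority* of probes may still carry real signal.
This package implements the rescue strategy for exactly that situation:

1. **Empirical detection filtering (pOOBAH).**  Type I probes are read in one
   colour channel, leaving the other channel "out-of-band" (OOB) —
   background-only by design.  A probe's raw in-band total M + U is ranked
   against the pooled per-probe OOB totals of the sample, giving an empirical
   detection p-value p = (1 + #{null ≥ total}) / (N + 1).  Probes with
   p < 0.01 are kept.
2. **normexp background correction (single-sample, noob-style).**  Observed
   intensity is modelled as exponential true signal plus normal background
   X = S + B, S ~ Exp(α), B ~ N(μ, σ²); μ, σ are estimated from the OOB
   values, α from the in-band excess, and each intensity is replaced by
   E[S | X = x] = m + σ·φ(m/σ)/Φ(m/σ), m = x − μ − σ²/α.
3. **Stringent subsetting.**  Only type I probes are carried forward (dye
   bias between channels affects type II probes and cannot be corrected
   without usable control-probe signal); X/Y-chromosome and SNP-associated
   CpGs are removed.
4. **Reference-based tissue deconvolution (NNLS).**  Tissue-marker CpGs are
   selected *within the retained set* from a labelled reference panel (score
   |Δmean| − λ·pooled-sd, tenfold cross-validated, top 5 per tissue); the
   reference matrix A holds per-tissue mean betas, and the sample's mixture
   is x̂ = argmin_{x≥0} ‖Ax − b‖₂ with proportions x̂/Σx̂.
5. **Reduced epigenetic clock.**  The CpGs of a multi-tissue age clock are
   intersected with the retained set and a fresh ordinary-least-squares model
   age ~ β is fitted on the reference panel's training split (no age
   transform); diagnostics (R² on train/validation) travel with the model.
6. **Sex from detection rates.**  On a female array the Y probes carry only
   background, so the detected fraction d_X far exceeds d_Y;
   r = d_X/(d_X + d_Y) ≥ 0.75 calls female, r ≤ 0.6 male.
7. **Damage profiling.**  Position-wise C→T misincorporation frequencies at
   5′ read ends (the ancient-DNA deamination signature), from a simplified
   aligned-read table, plus a read simulator with geometric damage decay
   p(i) = p0·δ^(i−1).

The synthetic-data module generates reference panels (bimodal baseline betas,
planted tissue-marker CpGs, planted age-linear CpGs, sex structure on X/Y)
and pushes betas through an inverse measurement model to two-channel
intensities, including a one-parameter degradation model (each probe survives
with probability f, else background only).  Two named presets reproduce the
two degradation regimes the pipeline is designed around: `"TH"` (~17 % of
type I probes detected — recoverable) and `"ACB"` (near-total loss —
analysis stops after filtering, by design).

## Worked example

```python
import relicmeth as rm

cfg = rm.default_config(preset="TH_synthetic", seed=0)   # degraded female lung, age 28
report = rm.run_pipeline(cfg)
```

The report for this run contains (values printed by the code above):

```
retained CpGs: 405 of 6000
typeI/typeII detected: 501 505
top tissue proportions: [('lung', 0.89), ('kidney', 0.085), ('heart', 0.021)]
sex: female ratio 0.930 (d_X=0.200, d_Y=0.015)
age: 43.6 years (clock CpGs used: 18; R2 train 0.84 / validation 0.75)
damage pos-1 C>T: 0.0415 (config 0.045)
```

Reading this: of 6,000 simulated probes only ~17 % of type I assays passed
the detection filter, and 405 autosomal non-SNP type I CpGs survive the
strict filter.  Deconvolution over markers selected from those 405 CpGs
still identifies lung as the dominant tissue (proportion 0.89).  The X
chromosome is detected at 13× the rate of Y — a clear female call.  Of the
100 planted clock CpGs, 18 survived filtering; the reduced model retrained
on them predicts 43.6 years for this seed against a true age of 28 —
within its own validation residual band (±2·RMSE), and across 100 seeds the
mean prediction is ≈ 34 years: degraded-sample age estimates are noisy and
biased a few years upward, mostly by detection false-positives inside the
reduced clock.  The damage profile recovers the configured terminal
deamination rate.

The same stages are scriptable from the shell:

```bash
relicmeth run --preset TH_synthetic --seed 0 --out report.json
relicmeth simulate --seed 1 --out panel/
relicmeth preprocess --intensities s.tsv --manifest m.tsv --out out/
relicmeth damage --reads reads.tsv --maxpos 25 --out profile.tsv
```

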