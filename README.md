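# hrvband

Band-limited heart-rate-variability (HRV) analysis and treatment-response
prediction for small two-timepoint clinical cohorts.

`hrvband` implements the full analysis chain used when resting HRV is
evaluated as a biomarker of antidepressant treatment response: from a raw
single-lead ECG (or a pre-extracted R-R interval file) through
artifact-corrected inter-beat-interval (IBI) series to the Porges–Bohrer
band-limited log-variance metric **V̂**, and on to the group statistics of a
responder vs non-responder study — descriptive comparisons,
repeated-measures ANCOVA, Tukey post hocs, and logistic/ROC prediction of
response from baseline HRV. A synthetic-data module generates IBI series,
rendered ECG traces and whole cohorts with controlled statistical
structure, so every stage is testable without patient data.

## The metric

For a corrected IBI series the vagally mediated HRV index V̂ is

1. linear interpolation of the heart-period series at 10 Hz,
2. a 241-point linear-phase FIR bandpass restricted to the spontaneous
   respiration band **0.12–0.40 Hz**,
3. the variance of the band-limited signal within each 30-s epoch,
4. the natural log of each epoch variance, averaged across epochs
   (a 3-min recording gives six epochs),

reported in ln(ms²). The band restriction isolates respiratory sinus
arrhythmia and suppresses slower (baroreflex, thermoregulatory) variance
sources; the log transform normalises the variance distribution. RMSSD and
pNN50 are provided as time-domain companions. Upstream, R-peaks are
detected with a derivative-energy (Pan–Tompkins-style) detector, intervals
are measured to the nearest millisecond, and rhythm artifacts — intervals
deviating more than 300 ms from their local median — are corrected by
integer division (missed beats) or summation (spurious beats), conserving
total elapsed time exactly.

Downstream, responders are defined by a ≥30% reduction in the Beck
Depression Inventory (BDI) at one month; HRV change is analysed with a
mixed between-within ANCOVA (group × time with age and gender covariates,
Type III sums of squares, partial η² per error stratum) and baseline HRV
is evaluated as a predictor via logistic regression (odds ratio with Wald
95% CI) and a tie-corrected rank AUC with a Youden-J operating point.

## Worked example

```python
import hrvband as hb

# a 3-min resting series: 800 ms mean heart period, 0.25 Hz respiratory
# modulation of 50 ms amplitude, no jitter
ibi = hb.generate_ibi(hb.IbiGenSpec(rsa_amp_ms=50.0, noise_sd_ms=0.0))
res = hb.vhat(ibi)
print(f"vhat = {res.vhat:.3f} ln(ms^2) over {res.n_epochs} epochs; "
      f"RMSSD = {res.rmssd:.1f} ms")
# vhat = 6.854 ln(ms^2) over 6 epochs; RMSSD = 41.5 ms

# a default 8-responder / 10-non-responder cohort, analysed end to end
cohort = hb.generate_cohort(hb.CohortGenSpec(seed=7))
tables = hb.run_pipeline(hb.PipelineConfig(), cohort)
roc = tables["roc"].iloc[0]
print(f"AUC = {roc['auc']:.3f}, OR per ln(ms^2) = {roc['or_point']:.3f}")
# AUC = 0.900, OR per ln(ms^2) = 0.133
```

The sinusoid's analytic band variance is amp²/2 = 1250 ms² (ln ≈ 7.13);
the measured 6.854 reflects the known sinc² amplitude loss of chord
(linear) interpolation at the ~0.8 s beat spacing (see
`docs/methods.md`). The AUC of 0.90 says that in this particular cohort
draw a randomly chosen responder has lower baseline HRV than a randomly
chosen non-responder nine times out of ten; the odds ratio below 1 points
the same way (each additional ln(ms²) of baseline HRV lowers the odds of
response).

The same flows are scriptable from a shell:

```bash
hrvband simulate --out-dir demo --seed 3 --recordings
hrvband hrv --ibi demo/ibi_S001_baseline.txt
hrvband analyze --cohort demo/cohort.tsv --out-dir demo/results
```

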