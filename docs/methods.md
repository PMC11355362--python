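# Methods

## Scope and model

`hrvband` analyses resting heart-period data from small two-timepoint
treatment cohorts. Its core quantity is the band-limited log variance of
the inter-beat-interval (IBI) series, V̂: the variance of the heart-period
signal restricted to the spontaneous-breathing band (0.12–0.40 Hz, i.e.
7.2–24 breaths/min in adults), log-transformed and averaged over 30-s
epochs. Within that band the dominant variance source is respiratory
sinus arrhythmia, which is vagally mediated, so V̂ behaves as an index of
parasympathetic cardiac control; the log transform corrects the strong
right skew of variance estimates. Units are ln(ms²).

The statistical layer assumes the standard responder-study design: a
binary response classification (≥30% symptom-score reduction at
follow-up), a two-level within factor (baseline, one month), a two-level
between factor (responder, non-responder), and continuous/dichotomous
covariates (age, gender).

## Signal processing choices

**Interpolation (10 Hz, linear).** The heart-period signal is defined by
anchoring each interval's value at the beat that terminates it and
interpolating linearly, holding the edge values constant so the grid
covers the full record. This is the conventional construction for
band-limited HRV metrics. Its known cost: linear interpolation is chord
approximation between beats ~IBI seconds apart, which attenuates an
in-band component at frequency *f* by the factor sinc²(*f*·IBI) in
amplitude. For a 0.25 Hz modulation at 800 ms heart period that is a
variance factor of 0.766, i.e. V̂ sits ≈0.27 ln units below the analytic
ln(amp²/2) of the underlying modulation. The package reports the faithful
(uncompensated) value, as the established implementations of this metric
do; tests of analytic recovery account for the factor explicitly.
Relative comparisons — group differences, change over time, amplitude
ratios — are unaffected at fixed heart rate and breathing frequency.

**Filter (241-tap FIR, 0.12–0.40 Hz).** A linear-phase Hamming
windowed-sinc bandpass at 10 Hz sampling. The length and band are fixed
protocol values; the design method is an implementation choice, and any
design meeting the contract — passband deviation ≤0.5 dB at band centre,
≥20 dB attenuation at 0.05 Hz and 0.8 Hz — is equivalent for this
analysis. The measured design achieves ~50 dB at 0.05 Hz and ~63 dB at
0.8 Hz with 0.001 dB centre ripple. The whole record is filtered once
(reflection-padded by one filter length, symmetric kernel applied
centred so group delay cancels) and then segmented into epochs; filtering
per epoch would put the ~24-s transient inside every 30-s epoch.

**Epoching.** `floor(span / 30 s)` consecutive epochs; a 180-s recording
yields six. An epoch with zero variance raises an error rather than
returning −∞: a constant heart period does not occur in valid recordings,
so it is treated as a data problem, not a value.

**R-peak detection.** The recording protocol this pipeline mirrors used a
commercial detector; peaks here come from an amplitude-normalised
derivative-energy detector (band-pass 5–40 Hz, differentiate, square,
120-ms smoothing, adaptive threshold, 250-ms refractory period), refined
to the raw-signal maximum. Detection is scale-invariant by construction.
Two quality gates reject non-cardiac input: candidate peaks must stand
≥10× above the median background energy (pure noise shows a contrast
near 1.6, clean signal ≥50 even at 0 dB SNR), and the beat sequence must
be physiologically regular (median interval 250–2000 ms, IQR/median
< 0.5). On synthetic ECG at 1 kHz and moderate SNR, recovered beat times
are within ±2 ms of ground truth, which is the resolution the
millisecond-rounded interval measurement needs.

**Artifact detection and correction (300 ms threshold).** An interval is
flagged when it deviates from the median of its five nearest unflagged
neighbours by more than 300 ms. The deviation-from-local-median form (as
opposed to successive differences) keeps the artifact itself out of the
reference; flagging proceeds worst-first so one artifact cannot mask
another, and lowering the threshold flags a superset. Correction follows
the classical integer-division/summation scheme: a flagged long interval
is split into k = round(interval / local median) equal parts (k ≥ 2,
missed beat); a run of flagged short intervals is summed, absorbing an
adjacent interval when the run is only a fragment of one true beat
(spurious detection). Integer-millisecond arithmetic makes total-time
conservation exact; every action is appended to a correction log, which
replaces the protocol's manual-inspection step in a library setting. Up
to three detect/correct passes are attempted before the series is
declared unresolvable. On seeded synthetic series with planted artifacts,
detection recall is ~100% and the corrected interval count matches the
original within ±1.

## Statistics

**Student's t and χ².** The t is pooled-variance (not Welch) and accepts
(mean, sd, n) summaries so printed tables can be checked without raw
data; the 2×2 χ² is Pearson without continuity correction. Both choices
reproduce the published baseline-table statistics exactly at their
printed precision (e.g. age |t| = 1.99, where Welch would give 1.96).
Three published rows (BDI, BMI, fluoxetine-equivalents) do not reproduce
from their own printed summaries under either pooled or Welch forms
(recomputed 0.62 / 0.05 / 0.54 vs printed 0.59 / 0.02 / 0.41) and are
treated as unverifiable rather than targets.

**Mixed ANCOVA.** With two timepoints the between-within model decomposes
exactly: per-subject means (y₁+y₂)/2 carry the between stratum (group,
age, gender), per-subject differences y₂−y₁ the within stratum (time and
its interactions). Covariates are centred, factors effect-coded (±1), so
each single-df Type III sum of squares is the drop-one-column SS and the
"time" main effect is the within-stratum intercept at the covariate
means. Partial η² = SS/(SS + SS_error) within each stratum. Against an
independent mixed-ANOVA implementation (pingouin) the F statistics agree
to 1e-6 without covariates, and without covariates F(group) equals the
squared pooled t of subject means identically. Under null simulation at
n = 8/10 the interaction test rejects at 0.052 (5000 reps), inside the
0.03–0.07 calibration band. A singular design (e.g. a single-gender
cohort) raises an error naming the aliased term.

**Tukey post hocs.** The six pairwise contrasts among the four
group-by-time cells use the covariate-adjusted cell means
s_g ∓ d_g/2. Each contrast's variance combines the two orthogonal strata
(the between part from the subject-mean model, the within part from the
difference model — they are uncorrelated under the model); p-values use
the studentized-range distribution with k = 4 on the residual df. The
published protocol does not state its error-term choice; this
two-stratum construction keeps within-subject contrasts at their paired
precision, and familywise error under the full null measures ≈5%.

**Logistic/ROC.** The logistic fit is plain maximum likelihood with Wald
SEs and CIs (matching standard software output); complete separation is
flagged, not silently reported. AUC is the tie-corrected Mann–Whitney
rank statistic, identical to the brute-force concordant-pair fraction;
the operating point maximises Youden's J with ties broken toward higher
specificity. Lower baseline HRV predicts response, so scores enter
negated by default. The published operating point (75% sensitivity, 92%
specificity) cannot be a whole-number fraction of 10 non-responders and
is therefore not reproducible from any data; only the AUC's sampling
distribution is checked (mean 0.814 over 2000 cohorts drawn from the
printed group moments, consistent with the single observed 0.844 and
with the closed form Φ(Δ/√(σ₁²+σ₂²)) ≈ 0.81).

## Synthetic data

The IBI generator produces interval k = mean + A_rsa·sin(2πf_rsa·t_k) +
A_lf·sin(2πf_lf·t_k) + ε_k with i.i.d. Gaussian jitter on interval
durations (not beat times), which keeps the band variance of the
sinusoidal component analytically known for recovery tests. Defaults —
180 s, 800 ms mean, 0.25 Hz / 40 ms respiratory modulation, 5 ms jitter —
describe a resting adult. The ECG renderer places a fixed narrow biphasic
QRS-like pulse at each beat with additive Gaussian noise at a stated SNR;
morphology is deliberately minimal because only R-peak timing enters the
pipeline. Artifact injection merges adjacent intervals (missed beat) or
splits one unequally (spurious beat), conserving time and recording
ground-truth positions.

The cohort generator draws per-group bivariate-normal HRV at the two
timepoints. Its defaults are the published group structure: 8 responders
(baseline 5.37 ± 0.93 → 6.04 ± 0.72 ln(ms²)) vs 10 non-responders
(6.52 ± 0.91 → 6.04 ± 0.80), ages 51 ± 9.4 vs 59.2 ± 8.05, and the
corresponding BDI trajectories, with follow-up BDI generated as
baseline × (1 − r) and the per-subject reduction r truncated to keep
group membership consistent with the ≥30% rule. The within-subject
HRV correlation ρ defaults to 0.7, the value implied by the published
paired-contrast standard errors (SE 0.239 at n = 8 ⇒ sd(diff) ≈ 0.68 ⇒
ρ ≈ 0.70 given the per-timepoint SDs); the HRV–BDI cross-correlation is
unconstrained by any published value and defaults to 0. What the
generator does **not** emulate: non-sinusoidal and drifting respiration,
heart-rate–dependent RSA amplitude, true ectopic morphology, or any
systematic covariate–outcome coupling — so passing tests demonstrate
that the machinery is correct under the stated model, not that the
clinical effect would replicate.

Under these defaults the responder baseline→month-1 Tukey contrast
(planted change +0.67, paired SE ≈ 0.24 at n = 8, Tukey k = 4 critical
t ≈ 2.9) has roughly 40% power — a reminder that a single significant
small-sample contrast (the published p = 0.038) sits close to the
decision boundary and would not be expected to replicate in a majority
of same-sized cohorts.

## Numerical conventions and limitations

- Intervals from ECG are rounded to the nearest millisecond; synthetic
  series keep float precision except through artifact injection, which
  works at millisecond resolution so conservation is exact in integers.
- Epoch variance uses the population (1/n) form; descriptive SDs use
  n−1. Sample-size problems (n = 1 SD, empty groups, one class absent)
  raise errors or warn explicitly rather than returning NaN.
- The 30% responder boundary is inclusive; the generator leaves a small
  margin around it so float rounding cannot flip group membership.
- Simulation sizes (5000 null reps, 500 alternative cohorts, 2000 ROC
  cohorts, 100 artifact series) give Monte-Carlo SEs comfortably below
  the decision bands they feed and run in about a minute in total.
- Not implemented by design: full spectral HRV (LF/HF, total power),
  nonlinear indices, respiration-gated analysis, multi-lead ECG
  morphology, and binary vendor file formats.
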