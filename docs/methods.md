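# Methods

This note documents the models, estimators and numerical choices behind
`aerostress`, in the package's own terms. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. The synthetic sortie generator

### RR-interval model

Beat times are generated iteratively from an additive-sinusoid interval
model. At beat time *t*:

    RR(t) = m + A_LF · sin(φ_LF) + A_HF · sin(φ_HF) + ε,   ε ~ N(0, σ²)

with the low-frequency (Mayer-wave band) oscillator at f_LF = 0.1 Hz and
the high-frequency oscillator phase-locked to the breathing rate
(respiratory sinus arrhythmia). Phases advance by 2π·f·RR between beats,
so both oscillators stay continuous when the stress condition switches
mid-sortie. Noise is clipped at ±m/2 and the interval floored at m/4, so
intervals are always positive. This is deliberately not an
integral-pulse-frequency-modulation model: the additive form makes the
LF/HF structure of the tachogram analytically controllable, which is what
the spectral indicators need for verifiable ground truth. The cost is
realism at the waveform level (see §6).

ECG is synthesized by template superposition: one Gaussian QRS-like
deflection (σ = 12 ms) per beat, with optional sinusoidal baseline drift
and 50 Hz mains interference to exercise the cleaning stage.
Respiration is a quasi-sinusoid at the breathing frequency whose
broadband noise scales with the breathing amplitude, so a shallow
breather has uniformly lower spectral band power. Acceleration is white
Gaussian baseline (SD 0.05 a.u.) on three axes with Gaussian manoeuvre
peaks (amplitude ≈ 2 a.u. ≈ 40 robust SDs) injected inside planned
manoeuvre windows on rotating axes.

### Stress conditions

The paired condition profiles are the study conditions; they are fixed
defaults, not tuning knobs:

| parameter | low stress | high stress | rationale |
|---|---|---|---|
| mean RR (ms) | 860 | 750 | heart rate rises under stress |
| LF amplitude (ms) | 25 | 26 | LF roughly preserved |
| HF amplitude (ms) | 40 | 32 | vagal withdrawal lowers RSA |
| breath rate (bpm) | 15.0 | 14.2 | slower breathing under load |
| breath amplitude (a.u.) | 1.0 | 0.75 | shallower breathing |
| RR jitter SD (ms) | 15 | 15 | broadband HRV floor |

These produce the full expected sign pattern — Mean HR, LF/HF, LFn higher
under high stress; Mean RR, RMSSD, pNN20/50, HFn, SD1/SD2, Mean Rsp and
EB1–EB4 lower — with moderate standardized effects (|d| ≈ 0.6–2 at study
scale) rather than trivial separation. Two values deserve comment:

- **Breathing rates sit inside the 0.2–0.3 Hz band.** If the two
  conditions' respiratory fundamentals straddle a band edge (e.g. 17 vs
  13 breaths/min, 0.283 vs 0.217 Hz), natural rate variability pushes the
  spectral peak across 0.2 or 0.3 Hz for a fraction of slices, and a
  single such slice dominates a band's group mean and can flip its sign.
  Rates of 15.0 and 14.2 bpm keep both fundamentals interior to EB3, and
  the modulated breathing frequency is additionally truncated to
  [0.205, 0.295] Hz, so the EB contrasts are purely amplitude-driven.
- **SDNN is left near-null.** In this model SDNN² = A_LF²/2 + A_HF²/2 +
  σ², so SDNN can only rise under stress if the LF gain outweighs the HF
  loss — which would blow LF/HF separation far past "moderate". The
  generator therefore does not force an SDNN direction, and the
  direction-recovery tests assert the 14 indicators listed above only.

### Between-slice variability

Real slices differ because pilots and moments differ. Each sortie draws a
multiplicative lognormal factor per parameter (SD 0.15) plus a slow
sinusoidal within-sortie drift (SD 0.07, period 400–900 s, random phase).
The breathing-rate factor uses 0.3× these spreads to respect the band
truncation above. The same factors apply to both conditions within a
sortie (same pilot), so directions are preserved while group overlap
becomes realistic. `jittered_profile` exposes the same distribution for
building proper null studies (both groups drawn from one distribution),
which is how the type-I calibration test is constructed.

### Study layout

The default study has 32 sorties of 22 min, each with two 200-s manoeuvre
windows (8–10 peaks, ≤ 25 s apart) placed with ±20 s jitter in equal
blocks of the timeline; the level-flight gaps always exceed 200 s so
every complement interval hosts at least one 3-min slice. This yields 64
critical and 96 non-critical ground-truth segments (the balanced design
subsamples detected non-critical segments longest-first to the critical
count) and ≈ 290 slices, roughly balanced between labels. Sampling rates
default to ECG 250 Hz, respiration 25 Hz, acceleration 25 Hz — plausible
wearable rates, all configurable. These sizes keep a full study under
~10 s on one CPU while leaving ≥ 100 slices per group for the screening
and modelling stages.

## 2. Segmentation

Peak detection is scale-free: per axis, the deviation from a 30-s rolling
median is divided by the axis MAD (×1.4826); the per-sample score is the
maximum over axes and peaks are local maxima above *k* with ≥ 1 s
separation (larger excursion wins ties). The default threshold is
**k = 6**: for a Gaussian baseline the per-sample false-alarm rate at
k = 3 is ≈ 0.27%, i.e. hundreds of spurious peaks over a 22-min sortie at
25 Hz — enough to merge an entire sortie into one "critical" run —
whereas k = 6 gives a negligible false-alarm rate while injected
manoeuvre peaks sit near 40 robust SDs. Runs of ≥ 5 peaks with gaps
≤ 30 s become critical segments padded by 10 s; peak-free intervals
shrunk by a 10-s guard and ≥ 180 s long become non-critical segments.
Segments shorter than 180 s host no slice and are dropped with a warning.
All intervals are half-open `[start, end)` in seconds from sortie start.

## 3. Preprocessing

ECG cleaning is a zero-phase band-pass (Butterworth high-pass 0.5 Hz
order 4, low-pass 40 Hz order 10) plus an IIR notch at 50 Hz (Q = 30).
The steep corners keep the passband flat, which makes cleaning
near-idempotent — applying it twice changes the interior of a template
ECG by well under 1% of the signal SD. Zero-phase filtering still rings
for a few seconds at a boundary that cuts through a QRS complex; the
idempotency test therefore asserts the full-range property on
boundary-smooth in-band signals and the interior property (10-s guard) on
template ECGs.

R-peaks: the squared derivative is smoothed over 100 ms, candidates are
maxima above 0.25× the 99th percentile of that envelope with ≥ 300 ms
separation, and each candidate is refined to the local ECG maximum within
±50 ms. Intervals outside 300–2000 ms are removed and counted. The
detector is validated purely by round-trip tests (known RR → ECG → clean
→ detect, max error ≤ 1 sample period).

Respiration cleaning is a linear detrend plus an order-4 Butterworth
low-pass at 1 Hz.

## 4. Indicators

All 21 indicators are computed from first principles with the population
(1/n) variance convention, under which SD1 = SDSD/√2 holds exactly and is
asserted in tests. Mean HR is the mean of instantaneous rates 60000/RR_i
(not 60000/mean RR); the two differ by Jensen's inequality and the choice
follows common HRV practice. pNNx uses strict `>` on |ΔRR|. For the
spectral indices the tachogram (RR_i at each interval's closing beat
time) is cubic-spline interpolated onto a 4 Hz grid and analysed with a
Welch periodogram (120-s Hann windows, 50% overlap, mean detrend); band
powers are trapezoid-integrated over half-open bands. LFn and HFn are
normalized by LF + HF — so they sum to one and LFn/HFn = LF/HF — rather
than by a total that includes very-low-frequency power; the ellipse area
uses the constant π (S = π·SD1·SD2). Breaths are counted as signal peaks
≥ 1 s apart with prominence ≥ 0.25 SD; Mean Rsp = 60·(breaths)/duration.
Undefined ratios (HF = 0, SD2 = 0, < 2 breaths) are reported as missing,
never as infinities, and screening drops missing values with a logged
count. Every indicator is checked against an independent plain-loop /
direct-FFT recomputation to 1e-9 on random RR series.

## 5. Screening and models

The test-selection gate runs per-group Shapiro–Wilk and mean-centred
Levene at α = 0.05: Student's pooled t-test only if all three pass, else
Welch. With three independent 5% gates, even perfectly normal
homoscedastic data selects Student's test only ≈ 86% of the time — the
calibration test asserts the simulated fraction rather than a higher
figure. Cohen's d always uses the pooled SD, which preserves the
equal-n identity d = t·√(2/n) regardless of which test ran. No
multiple-testing correction is applied across the 21 indicators; this
mirrors the per-indicator reporting convention and is a deliberate,
documented caveat — at α = 0.05 about one null indicator per study will
be selected by chance.

Slices are the cross-validation unit (stratified 5-fold, pooled confusion
matrices). Slices from one sortie share physiology, so slice-level folds
carry within-sortie leakage; an honest subject-level generalization claim
would need sortie-grouped folds, which the `cross_validate` API supports
by pre-filtering the feature table. Metrics are recomputed from the
pooled matrix and asserted consistent to 0.01 pt.

The stack uses scikit-learn's `StackingClassifier`: meta-features are the
bases' out-of-fold class probabilities from an internal stratified 5-fold
(never in-fold predictions), transformed to clipped log-odds before the
logistic-regression meta-learner — the natural link, making the
meta-model linear in each base's evidence; bases are refit on the full
training partition. XGBoost's round count (100) is a package choice; the
other hyperparameters are fixed as listed in the README. Grid search is
exhaustive by CV accuracy with ties broken toward fewer estimators, then
shallower trees. Determinism: a single master seed derives one sub-seed
per stage via `numpy.random.SeedSequence([master, stage_index])`, so
(config, seed) fully determine every artifact and stages can be rerun in
isolation.

Stacking performance is assessed over a battery of 10 replicated studies
(generator seeds 0–9): on any single study the best base and the stack
are within a slice or two of each other, and the median over independent
replicates is the stable comparison.

## 6. What passing tests do and do not show

The generator emulates the statistical structure the analysis assumes:
band-limited RR oscillations with stress-dependent amplitudes, amplitude-
scaled respiration, burst-structured acceleration and lognormal
between-slice heterogeneity. It does not emulate: realistic ECG
morphology (no P/T waves, no morphology change under load), motion and
electrode artifacts beyond additive drift/mains, G-force physiology,
non-stationary arrhythmic events, or respiratory-cardiac coupling beyond
a fixed phase-locked oscillator. Consequently, green tests certify that
the pipeline's estimators are correct and calibrated and that the method
recovers a known autonomic signature at moderate effect sizes — they do
not certify classifier accuracy or indicator sensitivity on real flight
recordings, where artifact handling and between-pilot variability
dominate. The slice-level-fold caveat above applies to any accuracy
figure computed here.
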