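# Methods

## The measurement chain being modelled

A seat-integrated sensor suite records three synchronized channels
while a subject sits: a single-lead ECG (mV), the summed force of four
load cells — the ballistocardiogram, BCG (N) — and a two-wavelength
reflectance photoplethysmogram, PPG (arbitrary optical units), sampled
at a common rate (default 1000 Hz).  The ECG provides the timing
reference; the BCG carries ejection timing and ejection strength; the
PPG carries pulse-arrival timing and blood-oxygen colour information.
From one sitting the chain estimates systolic/diastolic blood pressure,
SpO₂, stroke volume and cardiac output.

Estimation models:

* **Blood pressure.**  The aortic pulse transit time is
  `PTT = t_foot − t_J`: from the BCG J wave (aortic ejection) to the
  PPG pulse foot at the thigh (end of the aorta).  Starting the
  interval at the J wave rather than the ECG R peak excludes the
  pre-ejection period, which is electromechanical delay, not transit.
  With the aortic-length estimate `L = 0.285·height` (coefficient
  configurable), `PWV = L/PTT`, and each pressure is linear in PWV:
  `BP = a·PWV + b`.  The slopes `a` are population values (defaults
  12 and 8 mm Hg per m/s for systolic and diastolic); the offsets `b`
  are per subject, chosen so the model is exact at the mean of one
  cuff-referenced calibration session.  A per-subject offset also
  absorbs the individual central-vs-brachial pressure difference.
  A config switch (`bp_feature = "inv_ptt"`) regresses on `1/PTT`
  instead of PWV; the two differ only by the factor `L`.
* **SpO₂.**  The ensemble PPG pulse of each wavelength yields an AC
  (peak minus pre-systolic minimum) and a DC (raw optical level); the
  ratio of ratios `R = (AC_red/DC_red)/(AC_ir/DC_ir)` maps to
  saturation through `SpO₂ = s·R + o`.  The slope is a population
  constant (default −33.3 %/R); the offset is subject specific because
  thigh tissue varies between people far more than finger or earlobe
  tissue, so a single-point calibration per subject is required for
  absolute readings.  Without it, only relative changes `s·ΔR` are
  reported.
* **Stroke volume.**  The ensemble BCG J−K amplitude scales with
  ejection strength: `SV = c₀ + c₁·(J−K)` with population coefficients
  fit by least squares on a training cohort with reference SV values.
  This linear form is a deliberate, documented stand-in for more
  elaborate BCG stroke-volume algorithms; it is the simplest model that
  makes amplitude→volume coupling testable end to end.
  `CO = SV·HR/1000` with HR from the accepted RR intervals.

## The synthetic-data generator

`synthcardio` is the same chain run in reverse.  Given a subject's
"truth" parameters (their true pressure↔PWV lines, R-curve offset, SV
gain/intercept, PEP, aortic length) and a set of true vitals, it places
waveform features so that ideal processing recovers the vitals exactly:

* R peaks at `RR = 60/HR` plus Gaussian jitter (`hrv_sd`, default
  0.03 s in studies);
* a BCG H-I-J-K-L complex (Gaussian sum) whose J peak sits at
  `t_R + PEP` (PEP fixed at 0.08 s within a recording) and whose J−K
  amplitude equals `(SV − c₀ᵗ)/c₁ᵗ`;
* a PPG pulse on both wavelengths whose foot sits at `t_J + PTT`, with
  `PTT = L/PWV` and `PWV` from the *systolic* truth line — one transit
  time per beat must explain both pressures, so the diastolic truth is
  a second line over the same PTT;
* red/IR AC/DC ratios such that the ratio of ratios satisfies the
  subject's R-curve at the true SpO₂ (IR perfusion fixed at AC/DC =
  0.04; red follows from R).

Beat morphologies are parameterised synthetic templates chosen for
controllability, not anatomical realism: a Gaussian-sum PQRST complex;
Gaussian BCG waves (I and K symmetric at ±50 ms around J, widths
14–18 ms); and a PPG pulse whose rise is a parabolic ease-in joined to
a linear segment and an ease-out (C¹ everywhere).  The PPG rise is
built so that the tangent of its linear segment extrapolates through
zero exactly at the nominal foot: the intersecting-tangents detector is
then exact on the clean pulse and stays sub-millisecond after
band-limiting, which a corner-discontinuous template does not achieve.

Noise model: per-channel white Gaussian noise (defaults 0.02 mV ECG,
0.05 N BCG, 0.02 a.u. PPG) plus a respiration-like sinusoidal baseline
wander (0.15–0.35 Hz).  Artifacts: `motion_burst` (broadband noise on
BCG and PPG), `dropout` (all channels zeroed), `ectopic_beat` (a
premature QRS inserted into the ECG).  Annotations carry every true
event time (R peaks, J waves, PPG feet, artifact windows), enabling
detector scoring against ground truth.

What the generator does **not** emulate: real BCG/PPG morphology
(dicrotic notches, wave reflections), PEP variability within a
recording, beat-to-beat amplitude variability, sensor nonlinearity,
contact-pressure effects, skin-pigment or low-perfusion optics, and
pathological rhythms beyond single ectopy.  Passing tests therefore
demonstrate that the *processing chain is correct and well conditioned*
— that it recovers what the signals encode, rejects what the quality
rules target, and meets the compliance margins under the stated noise —
not that the device would meet them on human subjects.

Cohort generation samples demographics from truncated normals matched
to published cohort tables (age/weight/height mean and SD per
validation cohort, subjects above 180 kg excluded), derives BMI (never
sampled) and aortic length from height, and draws per-subject truth
parameters: BP offsets (SD 5 / 4 mm Hg), a common ±4 % relative jitter
on both BP slopes, R-curve offset (SD 4 %), SV gain (SD 1.6 mL/N).
Session-to-session physiology in simulated studies: per-subject
baselines (SBP 118 ± 8 mm Hg, SV 75 ± 12 mL, SpO₂ 97 ± 1 %, HR
74.3 ± 10 bpm, bounded to 47.8–113.2) with session drifts (6 mm Hg,
5 mL, 0.6 %, 4 bpm); reference instruments carry their own noise
(cuff 2 mm Hg, oximeter 0.4 %, echo 3 mL).  These defaults produce
estimator error with roughly 2× margin inside the AAMI/ISO bounds, so
compliance checks exercise a realistic, not degenerate, regime.

## Processing defaults and numerical choices

* **Filtering** — zero-phase (forward-backward) Butterworth, order 2
  per pass: ECG 0.5–40 Hz, BCG 0.5–40 Hz, PPG 0.3–20 Hz.  Corners were
  chosen so that band-limiting neither biases the J−K amplitude by more
  than ~1 % nor moves the detected PPG foot by more than one sample at
  1 kHz; narrower low-pass corners visibly attenuate the BCG complex
  and blunt the pulse foot.  PPG band-passing removes the optical DC,
  so the DC level is measured on the raw channel over the accepted-beat
  span and carried alongside the ensemble.
* **R-peak detection** — derivative-energy detector: band-pass
  5–25 Hz, differentiate, square, 150 ms moving integration, peak
  threshold at 0.15× the 99th percentile, 200 ms refractory, detection
  refined to the dominant deflection of the band-passed ECG.  The
  200 ms refractory keeps premature ectopic beats detectable at high
  heart rates (a longer dead time silently swallows them, and an
  undetected ectopic cannot be rejected downstream).
* **Abnormal-interval rule** — an RR interval is abnormal when it
  deviates from the running median RR (centered 11-interval window) by
  more than 20 %; both bounding beats are rejected.  Timing is never
  altered, making the filter idempotent.  Fewer than 3 beats rejects
  everything.
* **Recording quality gate** — accept iff ≥ 20 accepted beats, an
  accepted-beat span ≥ 30 s, and at most 20 % of 1 s BCG windows with
  RMS above 4× the median window RMS (the motion test).
* **Ensemble averaging** — window −0.2 to +0.8 s around R, truncated
  to the minimum accepted RR; beats whose window reaches within 1.5 s
  of either end of the recording are excluded, because zero-phase IIR
  filtering leaves slowly decaying edge transients (the 0.5 Hz
  high-pass is the culprit) that otherwise bias the ensemble.
* **Fiducials** — J is the global maximum of the BCG ensemble in
  0.05–0.40 s after R (earliest sample on ties), I/K the nearest local
  minima on either side; extrema are refined to sub-sample precision
  with a three-point parabola.  The PPG foot uses intersecting
  tangents: the horizontal through the pre-systolic minimum meets the
  tangent at maximum upslope; the result is continuous and invariant to
  vertical offsets.  The PPG foot (rather than peak or maximum-slope
  point) is the chosen peripheral timing feature: it is the least
  sensitive to pulse-shape change.
* **Quality-gated emission** — each vital can be withheld individually
  (NaN plus a flag) without failing the recording: no BP without a
  positive PTT; no SpO₂ unless both wavelengths pass an AC-to-ensemble-
  noise ratio of 5; systolic BP additionally requires the stricter
  ratio 15, reflecting its higher sensitivity to foot-timing error.
  `sbp > dbp` is checked and flagged if violated.

## Validation statistics

Differences are device minus reference.  Bland-Altman SD uses the
sample (n−1) divisor; `A_RMS` uses the n divisor, so
`A_RMS² = bias² + SD²·(n−1)/n` holds exactly.  Limits of agreement are
`±1.96·SD` (or `1.96·A_RMS` under a zero-mean assumption).  AAMI
blood-pressure compliance requires |bias| ≤ 5 mm Hg and SD ≤ 8 mm Hg;
ISO pulse-oximetry compliance requires `A_RMS ≤ 3.5 %`.  BMI strata use
half-open bins `[low, high)` with default edges 18.5 / 25 / 30 kg/m².
The slope-variation statistic for two calibration-curve slopes is
`100·|s₁−s₂|/|mean(s₁,s₂)|`, rounded to the nearest integer for
reporting; the mean denominator is one of three defensible choices
(mean, smaller slope, literature slope) that agree within rounding for
slopes this close.

## Study design

`simulate_study` writes one directory per subject with one file set per
session plus a manifest; `run_validation_study` calibrates each subject
on its first session (configurable), fits the population SV model on
the calibration sessions pooled across subjects (training stays
disjoint from the evaluated sessions), processes the remaining sessions
blind, and reports per-measure Bland-Altman statistics, compliance
verdicts and BMI strata with the full configuration embedded.
`run_sv_study` mirrors the echo-referenced design instead: every
subject contributes a single recording, the model is fit on one cohort
and evaluated on a disjoint one.

Problem sizes used by the acceptance script — a 12 × 10 BP/SpO₂ study
(60 s recordings at 1 kHz), a 30-subject training plus 149-subject test
SV cohort, 100 recordings for the gating rates — match the published
cohort sizes where those exist and run in about a minute on one CPU.

## Known limitations

* The SV model is an explicit linear stand-in; absolute SV accuracy on
  real data would hinge on a richer feature set and calibration.
* The generator's noise is stationary and Gaussian; real seat
  recordings are dominated by posture shifts and contact changes whose
  statistics differ, so the motion gate's thresholds would need
  re-tuning on real data.
* Only the summed load-cell force is simulated; per-cell processing
  (e.g. postural weight distribution) is out of scope.
* Absolute SpO₂ below ~85 % and hypoxic skin-pigment effects are
  outside the simulated and calibrated range.
* The BCG amplitude scale is nominal newtons with an arbitrary
  template scale; no hardware force calibration is implied.
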