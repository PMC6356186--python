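# seatvitals

Cuffless cardiovascular monitoring from a seat-integrated sensor suite —
simulated end to end, so every processing stage can be developed and
validated against known ground truth.

A seat that records a single-lead **ECG**, a summed load-cell
**ballistocardiogram (BCG)** and a two-wavelength reflectance
**photoplethysmogram (PPG)** can estimate, per sitting:

* **Blood pressure** from pulse transit time: the interval from the BCG
  J wave (aortic ejection) to the PPG pulse foot gives the aortic PTT;
  with an aortic-length estimate `L = 0.285·height`, the pulse-wave
  velocity is `PWV = L / PTT`, and pressure follows the linear model
  `BP = a·PWV + b` with population slopes `a` and a per-subject offset
  `b` fixed by a single cuff-referenced calibration session.
* **SpO₂** from the ratio of ratios
  `R = (AC_red/DC_red) / (AC_ir/DC_ir)` through the linear R-curve
  `SpO₂ = s·R + o` with a population slope `s = −33.3 %/R` and a
  subject-specific offset `o` from a single-point calibration.
* **Stroke volume and cardiac output** from the ensemble-averaged BCG
  J−K amplitude: `SV = c₀ + c₁·(J−K)` with population coefficients fit
  on a training cohort, and `CO = SV·HR/1000`.

Because no public recordings exist for such a device, the package ships
a forward simulator (`synthcardio`) that generates coupled ECG/BCG/PPG
recordings whose waveform features *encode* configurable true vitals —
beat timings, J-wave amplitude, PPG foot delay and AC/DC ratios are all
placed by inverting the estimation models above — plus channel noise,
baseline wander, motion bursts, dropouts and ectopic beats.  Estimates
are scored with the device-validation statistics used for this class of
instrument: Bland-Altman bias/SD with limits of agreement `±1.96·SD`,
the pulse-oximetry RMS error `A_RMS`, AAMI blood-pressure criteria
(|bias| ≤ 5 mm Hg, SD ≤ 8 mm Hg) and the ISO pulse-oximetry bound
(`A_RMS ≤ 3.5 %`), with BMI stratification.

Intended for researchers prototyping BCG/PPG vital-sign algorithms and
for anyone who needs a controlled, fully-annotated test bench for
cuffless blood-pressure or pulse-oximetry processing chains.

## Worked example

Calibrate a subject on one session, then process a later session in
which the simulated systolic pressure has risen from 120 to 132 mm Hg:

```python
import dataclasses
from seatvitals import (SubjectProfile, TrueVitals, NoiseSpec, PipelineConfig,
                        generate_recording, calibrate_subject, process_recording)
from seatvitals import synthcardio as sc

subject = SubjectProfile(subject_id="S001", age=25, sex="M",
                         height=175.2, weight=75.0, aortic_length=0.285 * 1.752)
config = PipelineConfig()

# calibration session: cuff and pulse-oximeter references fix the offsets
cal = generate_recording(subject, TrueVitals(sbp=120, dbp=80, sv=70, spo2=97, hr=74.3),
                         duration=60, fs=1000, noise_spec=NoiseSpec(), seed=1)
refs = {"ref_sbp": 120.0, "ref_dbp": 80.0, "ref_spo2": 97.0}
model, _ = calibrate_subject(cal, refs, subject.height, config)
model = dataclasses.replace(model, sv_intercept=10.0, sv_gain=20.0)

# later session: the subject's blood pressure has risen
sbp = 132.0
pwv = sc.true_pwv(subject, sbp)
dbp = subject.bp_slope_d * pwv + subject.bp_offset_d
later = generate_recording(subject, TrueVitals(sbp=sbp, dbp=dbp, sv=78, spo2=96, hr=68),
                           duration=60, fs=1000, noise_spec=NoiseSpec(), seed=2)
est, quality = process_recording(later, model, config)
print(f"SBP  {est.sbp:6.1f} mmHg  (true 132.0)")
```

Output:

```
accepted beats : 67/67
PTT    84.4 ms   PWV  5.92 m/s
SBP   131.3 mmHg  (true 132.0)
DBP    87.5 mmHg  (true 88.0)
SpO2   96.1 %     (true 96.0)
SV     77.5 mL    (true 78.0)
CO     5.27 L/min  HR  68.0 bpm
```

The transit time shortened (higher pressure → stiffer, faster aorta),
and the calibrated linear model recovers the shifted pressures to
within a fraction of a mm Hg of the encoded truth; SpO₂, stroke volume
and cardiac output are recovered from the same 60 s recording.

## Command line

```sh
seatvitals simulate --subjects 12 --sessions 10 --duration 60 --seed 1 --out cohort/
seatvitals calibrate cohort/S000/sess00 --height 174.2 --out cal_S000.txt
seatvitals process   cohort/S000/sess01 --calibration cal_S000.txt
seatvitals validate  cohort/
```

`validate` calibrates every subject on its first session, processes the
rest blind, and reports Bland-Altman statistics, AAMI/ISO verdicts and
BMI strata.  Recordings are plain columnar CSV
(`time_s, ecg_mv, bcg_n, ppg_red, ppg_ir`) with a key-value `.meta`
sidecar, a `.events.csv` annotation file and a `.truth` ground-truth
file per session.

## Layout

| module | role |
| --- | --- |
| `seatvitals.synthcardio` | subject cohorts, coupled-waveform generator, artifacts, recording I/O |
| `seatvitals.sigproc` | R-peak detection, abnormal-interval beat filtering, recording quality gates, ensemble averaging, BCG/PPG fiducials |
| `seatvitals.vitals` | PTT/PWV, per-subject BP and SpO₂ calibration, SV/CO estimation |
| `seatvitals.valstats` | Bland-Altman, LoA/A_RMS conversions, AAMI/ISO verdicts, BMI strata |
| `seatvitals.pipeline` / `seatvitals.cli` | end-to-end orchestration, study simulation/validation, command line |

See `docs/methods.md` for the models, defaults and their rationale.
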