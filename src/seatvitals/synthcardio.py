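"""Synthetic coupled ECG/BCG/PPG recordings with known ground-truth vitals.

The generator is a forward model of the seat measurement chain, run in
reverse: given a subject's calibration truth and a set of true vitals it
places waveform features so that the downstream estimators, applied to
the clean signals, would recover the vitals exactly.

Encoding, per beat at ECG R-peak time ``t_R``:

* the BCG I-J-K complex is a fixed morphology whose J peak sits at
  ``t_R + PEP`` and whose J−K amplitude equals
  ``(SV − sv_intercept) / sv_gain`` (newtons);
* the PPG pulse foot (both wavelengths) sits at ``t_J + PTT`` where
  ``PTT = aortic_length / PWV`` and ``PWV = (SBP − offset_s) / slope_s``
  from the subject's systolic pressure-velocity truth (diastolic pressure
  is tied to the same transit time through a second linear map);
* the red/infrared AC/DC ratios are set so the ratio of ratios R
  satisfies ``SpO2 = slope_pop·R + r_curve_offset``.

Beat morphologies are parameterised synthetic templates (Gaussian-sum
ECG complex, Gaussian I-J-K BCG complex, linear-rise/cosine-fall PPG
pulse) chosen for controllability, not anatomical realism.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import log

# --------------------------------------------------------------------------
# population / template constants
# --------------------------------------------------------------------------

#: population R-curve slope, % SpO2 per unit R (literature value)
POPULATION_R_SLOPE = -33.3

#: PPG DC optical levels per wavelength, arbitrary units
PPG_DC = {"red": 8.0, "ir": 10.0}
#: infrared perfusion: AC/DC ratio of the IR channel (red follows from R)
PPG_AC_RATIO_IR = 0.04
#: PPG pulse foot-to-peak rise and peak-to-baseline fall times, s
PPG_RISE_S = 0.12
PPG_FALL_S = 0.25
#: half-width of the parabolic ease-in/ease-out joints of the pulse rise, s
PPG_EASE_S = 0.02

#: ECG morphology: (delay from R, width sigma, amplitude mV) per wave
ECG_WAVES = (
    (-0.16, 0.025, 0.12),   # P
    (-0.025, 0.010, -0.15), # Q
    (0.0, 0.011, 1.0),      # R
    (0.025, 0.010, -0.25),  # S
    (0.28, 0.050, 0.30),    # T
)

#: BCG I-J-K morphology: (delay from J, sigma s, relative amplitude)
BCG_WAVES = (
    (-0.10, 0.016, 0.25),   # H
    (-0.05, 0.015, -0.50),  # I
    (0.0, 0.016, 1.0),      # J
    (0.05, 0.015, -0.50),   # K
    (0.10, 0.018, 0.20),    # L
)

WEIGHT_LIMIT_KG = 180.0  # cohort exclusion bound


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectProfile:
    """Demographics plus the generator-side calibration truth for one subject.

    ``bp_slope_*``/``bp_offset_*`` define the subject's true linear
    pressure↔PWV maps (mm Hg = slope·PWV + offset); ``sv_gain_truth`` and
    ``sv_intercept_truth`` the true SV↔(J−K amplitude) map;
    ``r_curve_offset`` the subject's SpO2 R-curve intercept in %.
    """

    subject_id: str
    age: float                 # years
    sex: str                   # "M" / "F"
    height: float              # cm
    weight: float              # kg
    aortic_length: float       # m
    pep: float = 0.08          # s, pre-ejection period
    r_curve_offset: float = 127.0          # %
    bp_slope_s: float = 12.0   # mm Hg per m/s
    bp_offset_s: float = 60.0  # mm Hg
    bp_slope_d: float = 8.0
    bp_offset_d: float = 40.0
    sv_gain_truth: float = 20.0       # mL per N of J−K amplitude
    sv_intercept_truth: float = 10.0  # mL

    def __post_init__(self) -> None:
        if self.height <= 0 or self.weight <= 0:
            raise ValueError("height and weight must be positive")
        if self.weight > WEIGHT_LIMIT_KG:
            raise ValueError(f"weight {self.weight} kg exceeds the {WEIGHT_LIMIT_KG} kg exclusion bound")
        if self.aortic_length <= 0 or self.pep <= 0:
            raise ValueError("aortic_length and pep must be positive")
        if self.sv_gain_truth <= 0:
            raise ValueError("sv_gain_truth must be positive")

    @property
    def bmi(self) -> float:
        """kg/m², derived from height and weight, never sampled."""
        return self.weight / (self.height / 100.0) ** 2


@dataclass(frozen=True)
class TrueVitals:
    """Ground-truth vitals one recording encodes."""

    sbp: float           # mm Hg
    dbp: float           # mm Hg
    sv: float            # mL
    spo2: float          # %
    hr: float            # bpm
    hrv_sd: float = 0.0  # s, RR jitter SD

    def __post_init__(self) -> None:
        if not self.sbp > self.dbp:
            raise ValueError(f"sbp ({self.sbp}) must exceed dbp ({self.dbp})")
        if not (0 < self.spo2 <= 100):
            raise ValueError(f"spo2 must be in (0, 100], got {self.spo2}")
        if not (30 <= self.hr <= 220):
            raise ValueError(f"hr must be within [30, 220] bpm, got {self.hr}")
        if self.sv < 0 or self.hrv_sd < 0:
            raise ValueError("sv and hrv_sd must be non-negative")


@dataclass
class Recording:
    """Synchronized multichannel recording plus ground-truth annotations.

    ``annotations`` is a DataFrame with columns ``event_type`` (r_peak,
    bcg_j, ppg_foot, ectopic_r, artifact_*), ``time_s`` and ``duration_s``
    (NaN for instantaneous events).
    """

    fs: float
    ecg: np.ndarray        # mV
    bcg: np.ndarray        # N (sum of the four load cells)
    ppg_red: np.ndarray    # a.u.
    ppg_ir: np.ndarray     # a.u.
    duration: float        # s
    subject_id: str
    annotations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["event_type", "time_s", "duration_s"])
    )

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = int(round(self.fs * self.duration))
        for name in ("ecg", "bcg", "ppg_red", "ppg_ir"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.size != n:
                raise ValueError(f"channel {name} has {arr.size} samples, expected {n}")
        t = self.annotations["time_s"].to_numpy(dtype=float) if len(self.annotations) else np.array([])
        if t.size and (t.min() < 0 or t.max() > self.duration):
            raise ValueError("annotation times must lie within [0, duration]")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        return {"ecg": self.ecg, "bcg": self.bcg,
                "ppg_red": self.ppg_red, "ppg_ir": self.ppg_ir}[name]

    def event_times(self, event_type: str) -> np.ndarray:
        m = self.annotations["event_type"] == event_type
        return np.sort(self.annotations.loc[m, "time_s"].to_numpy(dtype=float))

    def copy(self) -> "Recording":
        return Recording(
            fs=self.fs, ecg=self.ecg.copy(), bcg=self.bcg.copy(),
            ppg_red=self.ppg_red.copy(), ppg_ir=self.ppg_ir.copy(),
            duration=self.duration, subject_id=self.subject_id,
            annotations=self.annotations.copy(),
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Per-channel additive white noise SD plus sinusoidal baseline wander."""

    ecg_sd: float = 0.02       # mV
    bcg_sd: float = 0.05       # N
    ppg_sd: float = 0.02       # a.u., each wavelength
    ecg_wander: float = 0.05   # mV
    bcg_wander: float = 0.15   # N
    ppg_wander: float = 0.05   # a.u.
    wander_freq: Tuple[float, float] = (0.15, 0.35)  # Hz range (respiration-like)

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and v < 0:
                raise ValueError(f"{f.name} must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class DemographicsSpec:
    """Mean/SD of each sampled demographic field plus truncation bounds."""

    age_mean: float = 22.5
    age_sd: float = 2.9
    weight_mean: float = 77.6
    weight_sd: float = 12.9
    height_mean: float = 173.9
    height_sd: float = 9.5
    male_fraction: float = 0.8
    age_bounds: Tuple[float, float] = (18.0, 95.0)
    weight_bounds: Tuple[float, float] = (40.0, WEIGHT_LIMIT_KG)
    height_bounds: Tuple[float, float] = (140.0, 210.0)

    def __post_init__(self) -> None:
        if min(self.age_sd, self.weight_sd, self.height_sd) < 0:
            raise ValueError("demographic SDs must be non-negative")
        if not (0 <= self.male_fraction <= 1):
            raise ValueError("male_fraction must be in [0, 1]")


#: validation-cohort demographics (mean (SD) of age yr / weight kg / height cm)
COHORTS: Dict[str, DemographicsSpec] = {
    "dbp": DemographicsSpec(22.5, 2.8, 76.1, 13.5, 173.6, 9.3, 9 / 12),
    "sbp": DemographicsSpec(22.6, 2.9, 76.7, 13.9, 175.2, 7.9, 9 / 11),
    "sv_normative": DemographicsSpec(24.5, 5.6, 73.3, 21.1, 171.8, 7.6, 22 / 38),
    "sv_clinic": DemographicsSpec(55.7, 16.4, 81.3, 19.5, 170.6, 10.3, 59 / 111),
    "spo2": DemographicsSpec(22.5, 2.9, 77.6, 12.9, 173.9, 9.5, 10 / 11),
}

#: SDs of the per-subject calibration-truth parameters sampled by
#: :func:`generate_cohort` (means are the SubjectProfile defaults)
SUBJECT_TRUTH_SD = {
    "r_curve_offset": 4.0,     # %
    "bp_offset_s": 5.0,        # mm Hg
    "bp_offset_d": 4.0,        # mm Hg
    "bp_slope_rel": 0.04,      # fractional jitter on both BP slopes
    "sv_gain_truth": 1.6,      # mL/N
}

AORTIC_LENGTH_COEFF = 0.285    # m aorta per m height


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: Tuple[float, float], size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(mean))
    x = rng.normal(mean, sd, size)
    # resample out-of-bounds draws; bounds sit several SD out so this converges fast
    for _ in range(100):
        bad = (x < bounds[0]) | (x > bounds[1])
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(x, *bounds)


def generate_cohort(
    n_subjects: int,
    demographics_spec: Optional[DemographicsSpec] = None,
    seed: int = 0,
    truth_sd: Optional[Dict[str, float]] = None,
) -> List[SubjectProfile]:
    """Sample a cohort of subjects with demographics and calibration truth.

    Demographics are drawn from truncated normals per ``demographics_spec``;
    BMI is derived from height and weight, never sampled.  Per-subject
    calibration truth (BP offsets, slope jitter, R-curve offset, SV gain)
    is drawn around the population defaults with SDs from ``truth_sd``.
    Reproducible for a fixed seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    spec = demographics_spec or COHORTS["spo2"]
    tsd = dict(SUBJECT_TRUTH_SD)
    if truth_sd:
        tsd.update(truth_sd)
    if any(v < 0 for v in tsd.values()):
        raise ValueError("truth SDs must be non-negative")
    rng = np.random.default_rng(seed)
    age = _truncated_normal(rng, spec.age_mean, spec.age_sd, spec.age_bounds, n_subjects)
    weight = _truncated_normal(rng, spec.weight_mean, spec.weight_sd, spec.weight_bounds, n_subjects)
    height = _truncated_normal(rng, spec.height_mean, spec.height_sd, spec.height_bounds, n_subjects)
    sex = np.where(rng.random(n_subjects) < spec.male_fraction, "M", "F")
    slope_jit = rng.normal(0.0, tsd["bp_slope_rel"], n_subjects)
    offs_s = rng.normal(60.0, tsd["bp_offset_s"], n_subjects)
    offs_d = rng.normal(40.0, tsd["bp_offset_d"], n_subjects)
    r_off = rng.normal(127.0, tsd["r_curve_offset"], n_subjects)
    sv_gain = np.clip(rng.normal(20.0, tsd["sv_gain_truth"], n_subjects), 5.0, None)
    cohort = []
    for i in range(n_subjects):
        cohort.append(SubjectProfile(
            subject_id=f"S{i:03d}",
            age=float(age[i]), sex=str(sex[i]),
            height=float(height[i]), weight=float(weight[i]),
            aortic_length=AORTIC_LENGTH_COEFF * float(height[i]) / 100.0,
            r_curve_offset=float(r_off[i]),
            bp_slope_s=12.0 * (1.0 + float(slope_jit[i])),
            bp_offset_s=float(offs_s[i]),
            bp_slope_d=8.0 * (1.0 + float(slope_jit[i])),
            bp_offset_d=float(offs_d[i]),
            sv_gain_truth=float(sv_gain[i]),
        ))
    return cohort


# --------------------------------------------------------------------------
# closed-form feature maps (shared by the generator and by tests)
# --------------------------------------------------------------------------

def true_pwv(subject: SubjectProfile, sbp: float) -> float:
    """Pulse-wave velocity implied by systolic pressure, m/s."""
    return (sbp - subject.bp_offset_s) / subject.bp_slope_s


def true_ptt(subject: SubjectProfile, sbp: float) -> float:
    """Transit time aortic_length/PWV implied by systolic pressure, s."""
    pwv = true_pwv(subject, sbp)
    if pwv <= 0:
        raise ValueError(
            f"non-positive PWV ({pwv:.3f} m/s) implied by sbp={sbp} with "
            f"offset {subject.bp_offset_s}, slope {subject.bp_slope_s}"
        )
    return subject.aortic_length / pwv


def true_jk_amplitude(subject: SubjectProfile, sv: float) -> float:
    """BCG J−K amplitude in newtons encoding a stroke volume."""
    jk = (sv - subject.sv_intercept_truth) / subject.sv_gain_truth
    if jk <= 0:
        raise ValueError(f"sv={sv} mL implies non-positive J−K amplitude for {subject.subject_id}")
    return jk


def true_r_value(subject: SubjectProfile, spo2: float) -> float:
    """Ratio-of-ratios R encoding an SpO2 on the subject's R-curve."""
    r = (spo2 - subject.r_curve_offset) / POPULATION_R_SLOPE
    if r <= 0:
        raise ValueError(f"spo2={spo2}% with offset {subject.r_curve_offset} implies non-positive R")
    return r


# --------------------------------------------------------------------------
# waveform templates
# --------------------------------------------------------------------------

def _add_gaussians(signal: np.ndarray, fs: float, centers: np.ndarray,
                   waves: Sequence[Tuple[float, float, float]], scale: float = 1.0) -> None:
    """Add a Gaussian-sum complex at each center time, in place."""
    n = signal.size
    for delay, sigma, amp in waves:
        half = int(round(5 * sigma * fs))
        tt = np.arange(-half, half + 1) / fs
        kernel = scale * amp * np.exp(-0.5 * (tt / sigma) ** 2)
        for c in centers:
            i0 = int(round((c + delay) * fs)) - half
            lo, hi = max(i0, 0), min(i0 + kernel.size, n)
            if lo < hi:
                signal[lo:hi] += kernel[lo - i0: hi - i0]


def _bcg_unit_jk(fs: float) -> float:
    """J−K amplitude of the unit BCG complex on the sampling grid."""
    pad = 0.3
    n = int(round(2 * pad * fs)) + 1
    sig = np.zeros(n)
    _add_gaussians(sig, fs, np.array([pad]), BCG_WAVES)
    t = np.arange(n) / fs - pad
    j_amp = sig[np.argmax(sig)]
    k_mask = (t > 0.01) & (t < 0.12)
    k_amp = sig[np.where(k_mask)[0][np.argmin(sig[k_mask])]]
    return float(j_amp - k_amp)


def _ppg_pulse(fs: float) -> Tuple[int, np.ndarray]:
    """Unit PPG pulse sampled on the fs grid; returns (foot sample offset, samples).

    The rise is a parabolic ease-in of half-width PPG_EASE_S joined to a
    linear segment and a parabolic ease-out to the peak; the tangent of
    the linear segment extrapolates through zero exactly at τ = 0, so
    the intersecting-tangents foot of the clean pulse is its nominal
    foot time.  The fall is a half-cosine, C1 everywhere.
    """
    w = PPG_EASE_S
    pk = PPG_RISE_S
    v = w
    b = pk - 2 * v          # end of the linear segment
    s = 1.0 / (b + v)       # upslope giving unit peak amplitude
    n0 = int(round(w * fs))
    n1 = int(round((pk + PPG_FALL_S) * fs))
    tau = np.arange(-n0, n1 + 1) / fs
    y = np.zeros_like(tau)
    a = (tau >= -w) & (tau < w)
    y[a] = s * (tau[a] + w) ** 2 / (4 * w)
    m = (tau >= w) & (tau < b)
    y[m] = s * tau[m]
    c = (tau >= b) & (tau < pk)
    u = tau[c] - b
    y[c] = s * (b + u - u * u / (4 * v))
    d = tau >= pk
    y[d] = 0.5 * (1.0 + np.cos(np.pi * np.minimum((tau[d] - pk) / PPG_FALL_S, 1.0)))
    return n0, y


def _add_pulses(signal: np.ndarray, fs: float, feet: np.ndarray, amp: float) -> None:
    n0, shape = _ppg_pulse(fs)
    pulse = amp * shape
    n = signal.size
    for tf in feet:
        i0 = int(round(tf * fs)) - n0
        lo, hi = max(i0, 0), min(i0 + pulse.size, n)
        if lo < hi:
            signal[lo:hi] += pulse[lo - i0: hi - i0]


# --------------------------------------------------------------------------
# recording generation
# --------------------------------------------------------------------------

def generate_recording(
    subject: SubjectProfile,
    vitals: TrueVitals,
    duration: float = 60.0,
    fs: float = 1000.0,
    noise_spec: Optional[NoiseSpec] = None,
    seed: int = 0,
) -> Recording:
    """Generate one recording whose waveform features encode ``vitals``.

    R peaks are placed at RR = 60/hr plus Gaussian jitter of SD
    ``vitals.hrv_sd``; BCG, PPG timing and amplitude features follow the
    closed-form maps above; channel noise and baseline wander follow
    ``noise_spec``.  Annotations carry all true event times.
    """
    if duration < 10:
        raise ValueError("duration must be >= 10 s")
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    noise = noise_spec if noise_spec is not None else NoiseSpec()
    rng = np.random.default_rng(seed)

    # closed-form per-recording features (raise with diagnostics if impossible)
    ptt = true_ptt(subject, vitals.sbp)
    jk = true_jk_amplitude(subject, vitals.sv)
    r_value = true_r_value(subject, vitals.spo2)
    if subject.pep + ptt > 0.6:
        raise ValueError(f"pep+ptt = {subject.pep + ptt:.3f} s leaves no room for the PPG pulse")

    # beat train
    mean_rr = 60.0 / vitals.hr
    r_times = []
    t = 0.5
    tail = PPG_RISE_S + PPG_FALL_S + subject.pep + ptt + 0.05
    while t < duration - tail:
        r_times.append(t)
        t += mean_rr + (rng.normal(0.0, vitals.hrv_sd) if vitals.hrv_sd > 0 else 0.0)
    r_times = np.array(r_times)
    if r_times.size < 2:
        raise ValueError("duration too short for at least two beats at this heart rate")

    n = int(round(fs * duration))
    ecg = np.zeros(n)
    bcg = np.zeros(n)
    ppg_red = np.full(n, PPG_DC["red"])
    ppg_ir = np.full(n, PPG_DC["ir"])

    _add_gaussians(ecg, fs, r_times, ECG_WAVES)
    bcg_scale = jk / _bcg_unit_jk(fs)
    j_times = r_times + subject.pep
    _add_gaussians(bcg, fs, j_times, BCG_WAVES, scale=bcg_scale)

    foot_times = j_times + ptt
    ac_ir = PPG_AC_RATIO_IR * PPG_DC["ir"]
    ac_red = r_value * PPG_AC_RATIO_IR * PPG_DC["red"]
    _add_pulses(ppg_ir, fs, foot_times, ac_ir)
    _add_pulses(ppg_red, fs, foot_times, ac_red)

    # noise + baseline wander
    tgrid = np.arange(n) / fs
    for sig, sd, wamp in ((ecg, noise.ecg_sd, noise.ecg_wander),
                          (bcg, noise.bcg_sd, noise.bcg_wander),
                          (ppg_red, noise.ppg_sd, noise.ppg_wander),
                          (ppg_ir, noise.ppg_sd, noise.ppg_wander)):
        if wamp > 0:
            f = rng.uniform(*noise.wander_freq)
            phi = rng.uniform(0, 2 * np.pi)
            sig += wamp * np.sin(2 * np.pi * f * tgrid + phi)
        if sd > 0:
            sig += rng.normal(0.0, sd, n)

    ann = pd.DataFrame({
        "event_type": (["r_peak"] * r_times.size + ["bcg_j"] * r_times.size
                       + ["ppg_foot"] * r_times.size),
        "time_s": np.concatenate([r_times, j_times, foot_times]),
        "duration_s": np.nan,
    })
    return Recording(fs=fs, ecg=ecg, bcg=bcg, ppg_red=ppg_red, ppg_ir=ppg_ir,
                     duration=duration, subject_id=subject.subject_id, annotations=ann)


# --------------------------------------------------------------------------
# artifact injection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Artifact:
    kind: str         # motion_burst | ectopic_beat | dropout
    onset: float      # s
    duration: float   # s (ignored for ectopic_beat)
    magnitude: float  # noise SD (motion), QRS scale (ectopic), unused (dropout)

    def __post_init__(self) -> None:
        if self.kind not in ("motion_burst", "ectopic_beat", "dropout"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")


def inject_artifacts(recording: Recording, artifact_spec: Sequence[Artifact],
                     seed: int = 0) -> Recording:
    """Return a copy of ``recording`` with the listed artifacts applied.

    motion_burst adds broadband noise to BCG and both PPG channels;
    ectopic_beat inserts a premature ECG QRS complex at the onset time;
    dropout zeroes all channels in the window.  Annotation rows labelled
    ``artifact_<kind>`` (and ``ectopic_r`` for the premature beat) are
    appended.  Overlapping windows are allowed.
    """
    out = recording.copy()
    if not artifact_spec:
        return out
    rng = np.random.default_rng(seed)
    fs = out.fs
    new_rows = []
    for a in artifact_spec:
        end = a.onset + (0.0 if a.kind == "ectopic_beat" else a.duration)
        if a.onset < 0 or end > out.duration:
            raise ValueError(f"artifact window [{a.onset}, {end}] outside recording [0, {out.duration}]")
        i0, i1 = int(round(a.onset * fs)), int(round(end * fs))
        if a.kind == "motion_burst":
            for sig in (out.bcg, out.ppg_red, out.ppg_ir):
                sig[i0:i1] += rng.normal(0.0, a.magnitude, i1 - i0)
        elif a.kind == "dropout":
            for sig in (out.ecg, out.bcg, out.ppg_red, out.ppg_ir):
                sig[i0:i1] = 0.0
        elif a.kind == "ectopic_beat":
            _add_gaussians(out.ecg, fs, np.array([a.onset]),
                           [w for w in ECG_WAVES if abs(w[0]) < 0.05],
                           scale=a.magnitude if a.magnitude > 0 else 1.0)
            new_rows.append({"event_type": "ectopic_r", "time_s": a.onset, "duration_s": np.nan})
        new_rows.append({"event_type": f"artifact_{a.kind}", "time_s": a.onset,
                         "duration_s": (np.nan if a.kind == "ectopic_beat" else a.duration)})
    out.annotations = pd.concat([out.annotations, pd.DataFrame(new_rows)], ignore_index=True)
    return out


# --------------------------------------------------------------------------
# recording file I/O: columnar CSV + key-value sidecar + event CSV
# --------------------------------------------------------------------------

def save_recording(rec: Recording, stem: Union[str, Path]) -> None:
    """Write ``<stem>.csv`` (channels), ``<stem>.meta`` and ``<stem>.events.csv``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({
        "time_s": rec.time, "ecg_mv": rec.ecg, "bcg_n": rec.bcg,
        "ppg_red": rec.ppg_red, "ppg_ir": rec.ppg_ir,
    })
    df.to_csv(stem.with_suffix(".csv"), index=False, float_format="%.6f")
    meta = f"fs = {rec.fs}\nsubject_id = {rec.subject_id}\nduration = {rec.duration}\n"
    stem.with_suffix(".meta").write_text(meta)
    rec.annotations.to_csv(stem.with_suffix(".events.csv"), index=False)


def load_recording(stem: Union[str, Path]) -> Recording:
    """Read a recording written by :func:`save_recording`."""
    stem = Path(stem)
    meta = {}
    for line in stem.with_suffix(".meta").read_text().splitlines():
        if "=" in line:
            k, _, v = line.partition("=")
            meta[k.strip()] = v.strip()
    df = pd.read_csv(stem.with_suffix(".csv"))
    events_path = stem.with_suffix(".events.csv")
    ann = (pd.read_csv(events_path) if events_path.exists()
           else pd.DataFrame(columns=["event_type", "time_s", "duration_s"]))
    return Recording(
        fs=float(meta["fs"]),
        ecg=df["ecg_mv"].to_numpy(), bcg=df["bcg_n"].to_numpy(),
        ppg_red=df["ppg_red"].to_numpy(), ppg_ir=df["ppg_ir"].to_numpy(),
        duration=float(meta["duration"]), subject_id=meta["subject_id"],
        annotations=ann,
    )
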