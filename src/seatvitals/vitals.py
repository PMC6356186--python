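"""Calibrated vitals estimation from fiducial features.

Blood pressure: the aortic pulse transit time (BCG J wave to PPG foot)
and an aortic-length estimate give a pulse-wave velocity; pressure is
linear in PWV with population slopes and a per-subject offset fixed by
a single calibration session against a cuff reference.

SpO2: the ratio of ratios R = (AC_red/DC_red)/(AC_ir/DC_ir) maps to
saturation through a linear R-curve whose slope is a population value
(default −33.3 %/R) and whose offset is subject specific, fixed by a
single-point calibration.  Without calibration only relative changes
slope·ΔR are meaningful.

Stroke volume: linear in the ensemble BCG J−K amplitude with population
coefficients fit on a training set; cardiac output is SV·HR/1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .sigproc import FiducialSet


class CalibrationError(RuntimeError):
    """Raised when an estimate is requested from an uncalibrated model."""


@dataclass
class CalibrationModel:
    """Per-subject calibration state for all estimators.

    BP and SpO2 parts are None until their calibration has run; the SV
    part holds population coefficients and may be shared across subjects.
    """

    calibrated_for: Optional[str] = None
    aortic_length: Optional[float] = None   # m
    bp_slope_s: Optional[float] = None      # mm Hg per (m/s)
    bp_slope_d: Optional[float] = None
    bp_offset_s: Optional[float] = None     # mm Hg
    bp_offset_d: Optional[float] = None
    spo2_slope: Optional[float] = None      # % per unit R, negative
    spo2_offset: Optional[float] = None     # %
    sv_intercept: Optional[float] = None    # mL
    sv_gain: Optional[float] = None         # mL per N

    def __post_init__(self) -> None:
        if self.aortic_length is not None and self.aortic_length <= 0:
            raise ValueError("aortic_length must be positive")
        if self.spo2_slope is not None and self.spo2_slope >= 0:
            raise ValueError("spo2_slope must be negative")
        # gain 0 is the degenerate constant estimator; negative gains are invalid
        if self.sv_gain is not None and self.sv_gain < 0:
            raise ValueError("sv_gain must be non-negative")

    # --- key-value file round trip --------------------------------------
    def to_text(self) -> str:
        lines = []
        for k, v in self.__dict__.items():
            if v is not None:
                lines.append(f"{k} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "CalibrationModel":
        kwargs: Dict[str, object] = {}
        for line in text.splitlines():
            if "=" not in line:
                continue
            k, _, v = line.partition("=")
            k, v = k.strip(), v.strip()
            kwargs[k] = v if k == "calibrated_for" else float(v)
        return cls(**kwargs)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path: Union[str, Path]) -> "CalibrationModel":
        return cls.from_text(Path(path).read_text())


@dataclass(frozen=True)
class VitalsEstimate:
    """One recording's estimates; NaN where quality gates withheld a value."""

    ptt: float = float("nan")     # s
    pwv: float = float("nan")     # m/s
    r_value: float = float("nan")
    sbp: float = float("nan")     # mm Hg
    dbp: float = float("nan")     # mm Hg
    spo2: float = float("nan")    # %
    sv: float = float("nan")      # mL
    co: float = float("nan")      # L/min
    hr: float = float("nan")      # bpm
    flags: Tuple[str, ...] = ()


# --------------------------------------------------------------------------
# geometry and transit time
# --------------------------------------------------------------------------

def estimate_aortic_length(height: float, coeff: float = 0.285) -> float:
    """Aortic length in metres from standing height in cm (length = coeff·height)."""
    if not (100 <= height <= 230):
        raise ValueError(f"height {height} cm outside the supported 100–230 cm range")
    length = coeff * height / 100.0
    if length <= 0:
        raise ValueError("aortic length must be positive (check coeff)")
    return length


def compute_ptt_pwv(bcg_j_time: float, ppg_foot_time: float,
                    aortic_length: float) -> Tuple[float, float]:
    """PTT = foot − J (s) and PWV = aortic_length / PTT (m/s)."""
    ptt = ppg_foot_time - bcg_j_time
    if ptt <= 0:
        raise ValueError(f"non-positive PTT ({ptt:.4f} s): foot precedes the BCG J wave")
    return ptt, aortic_length / ptt


# --------------------------------------------------------------------------
# blood pressure
# --------------------------------------------------------------------------

def calibrate_bp(calib_features: Sequence[Tuple[float, float, float]],
                 population_slopes: Tuple[float, float],
                 model: Optional[CalibrationModel] = None,
                 subject_id: Optional[str] = None) -> CalibrationModel:
    """Fix per-subject BP offsets from a single calibration session.

    ``calib_features`` are (pwv, cuff_sbp, cuff_dbp) tuples; slopes are
    held at the population values and the offsets are chosen so the
    model is exact at the session means:
    ``offset = mean(cuff) − slope·mean(pwv)``.
    """
    if len(calib_features) == 0:
        raise ValueError("calibration requires at least one (pwv, sbp, dbp) tuple")
    arr = np.asarray(calib_features, dtype=float)
    slope_s, slope_d = population_slopes
    mean_pwv = arr[:, 0].mean()
    off_s = arr[:, 1].mean() - slope_s * mean_pwv
    off_d = arr[:, 2].mean() - slope_d * mean_pwv
    model = model or CalibrationModel()
    return replace(model, bp_slope_s=float(slope_s), bp_slope_d=float(slope_d),
                   bp_offset_s=float(off_s), bp_offset_d=float(off_d),
                   calibrated_for=subject_id or model.calibrated_for)


def estimate_bp(model: CalibrationModel, pwv: float) -> Tuple[float, float]:
    """(systolic, diastolic) mm Hg from PWV via the calibrated linear maps."""
    if model.bp_slope_s is None or model.bp_offset_s is None:
        raise CalibrationError("BP model is uncalibrated; per-subject calibration is required")
    sbp = model.bp_slope_s * pwv + model.bp_offset_s
    dbp = model.bp_slope_d * pwv + model.bp_offset_d
    return float(sbp), float(dbp)


# --------------------------------------------------------------------------
# SpO2
# --------------------------------------------------------------------------

def compute_r_value(ac_red: float, dc_red: float, ac_ir: float, dc_ir: float) -> float:
    """Ratio of ratios R = (AC_red/DC_red) / (AC_ir/DC_ir)."""
    for name, v in (("ac_red", ac_red), ("dc_red", dc_red), ("ac_ir", ac_ir), ("dc_ir", dc_ir)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (ac_red / dc_red) / (ac_ir / dc_ir)


def calibrate_spo2(r_cal: float, spo2_ref: float, slope: float = -33.3,
                   model: Optional[CalibrationModel] = None,
                   subject_id: Optional[str] = None) -> CalibrationModel:
    """Fix the subject's R-curve offset: ``offset = spo2_ref − slope·r_cal``."""
    if slope >= 0:
        raise ValueError("R-curve slope must be negative")
    if not (0 < spo2_ref <= 100):
        raise ValueError("spo2_ref must be in (0, 100]")
    model = model or CalibrationModel()
    return replace(model, spo2_slope=float(slope),
                   spo2_offset=float(spo2_ref - slope * r_cal),
                   calibrated_for=subject_id or model.calibrated_for)


def estimate_spo2(model: CalibrationModel, r: float) -> float:
    """Absolute SpO2 % = slope·R + offset, clipped to (0, 100]."""
    if model.spo2_slope is None or model.spo2_offset is None:
        raise CalibrationError("SpO2 model is uncalibrated; absolute SpO2 needs a single-point calibration")
    return float(np.clip(model.spo2_slope * r + model.spo2_offset, 1e-9, 100.0))


def relative_spo2_change(delta_r: float, slope: float = -33.3) -> float:
    """ΔSpO2 = slope·ΔR: the calibration-free relative mode."""
    if slope >= 0:
        raise ValueError("R-curve slope must be negative")
    return slope * delta_r


# --------------------------------------------------------------------------
# stroke volume and cardiac output
# --------------------------------------------------------------------------

def fit_sv_model(jk_amplitudes: Sequence[float], sv_refs: Sequence[float],
                 model: Optional[CalibrationModel] = None) -> CalibrationModel:
    """Fit the population SV = intercept + gain·(J−K amplitude) map by least squares."""
    jk = np.asarray(jk_amplitudes, dtype=float)
    sv = np.asarray(sv_refs, dtype=float)
    if jk.size != sv.size or jk.size < 2:
        raise ValueError("need >= 2 paired (jk, sv) training points")
    gain, intercept = np.polyfit(jk, sv, 1)
    if gain <= 0:
        raise ValueError(f"fitted SV gain is non-positive ({gain:.3f} mL/N); training data unusable")
    model = model or CalibrationModel()
    return replace(model, sv_intercept=float(intercept), sv_gain=float(gain))


def estimate_sv(fiducials: Union[FiducialSet, float], model: CalibrationModel) -> float:
    """Stroke volume mL = intercept + gain·(J−K amplitude); clipped at 0."""
    if model.sv_gain is None or model.sv_intercept is None:
        raise CalibrationError("SV model has no coefficients")
    jk = fiducials.jk_amplitude if isinstance(fiducials, FiducialSet) else float(fiducials)
    if jk is None:
        raise ValueError("BCG fiducials are missing; no SV can be estimated")
    sv = model.sv_intercept + model.sv_gain * jk
    return float(max(sv, 0.0))


def compute_co(sv: float, hr: float) -> float:
    """Cardiac output L/min = SV (mL) × HR (bpm) / 1000."""
    if sv < 0:
        raise ValueError("sv must be non-negative")
    if hr <= 0:
        raise ValueError("hr must be positive")
    return sv * hr / 1000.0
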