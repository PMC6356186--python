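"""Pipeline configuration and logging.

A single :class:`PipelineConfig` carries every tunable of the processing
chain — filter bands, beat-quality thresholds, fiducial search windows and
the population calibration slopes — so that a run is fully reproducible
from (inputs, config, seed).  The config serialises losslessly to a flat
``key = value`` text format.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple, Union

log = logging.getLogger("seatvitals")


def setup_logging(level: int = logging.INFO, logfile: Union[str, Path, None] = None) -> None:
    """Configure package logging to stderr and optionally to a file."""
    log.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
        log.addHandler(h)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
        log.addHandler(fh)


@dataclass
class PipelineConfig:
    """All tunables of the simulation→estimation→validation chain.

    Filter bands are (low, high) corner frequencies in Hz of zero-phase
    Butterworth filters.  ``bp_population_slopes`` are the population
    PWV→pressure slopes in mm Hg per (m/s) for (systolic, diastolic);
    per-subject offsets come from single-session calibration.
    ``spo2_slope`` is the population R-curve slope in % per unit R.
    """

    fs: float = 1000.0                      # Hz
    # -- channel filtering (zero-phase Butterworth, order = filter_order)
    ecg_band: Tuple[float, float] = (0.5, 40.0)
    bcg_band: Tuple[float, float] = (0.5, 40.0)
    ppg_band: Tuple[float, float] = (0.3, 20.0)
    filter_order: int = 2
    # -- beat interval quality
    rr_tolerance: float = 0.20              # fractional deviation from running median
    rr_median_window: int = 11              # beats in the running-median window
    # -- recording-level quality gates
    min_beats: int = 20                     # minimum accepted beats
    min_span_s: float = 30.0                # minimum span of accepted beats, s
    max_motion_fraction: float = 0.2        # max fraction of high-power BCG windows
    motion_window_s: float = 1.0
    motion_rms_factor: float = 4.0          # window RMS > factor*median RMS => motion
    # -- ensemble averaging window around the R peak
    ensemble_pre_s: float = 0.2
    ensemble_post_s: float = 0.8
    # beats whose window reaches into this many seconds at either end of the
    # recording are excluded: zero-phase IIR filtering leaves edge transients
    edge_guard_s: float = 1.5
    # -- fiducial search windows, s relative to R
    j_search_s: Tuple[float, float] = (0.05, 0.40)
    foot_search_s: Tuple[float, float] = (0.08, 0.55)
    # -- PPG signal-quality gates (ensemble AC over residual ensemble noise);
    #    systolic BP uses the stricter gate
    min_ac_snr: float = 5.0
    min_ac_snr_sbp: float = 15.0
    # -- estimation
    aortic_length_coeff: float = 0.285      # m of aorta per m of height
    ptt_wavelength: str = "ir"              # PPG wavelength supplying the foot
    bp_population_slopes: Tuple[float, float] = (12.0, 8.0)  # mmHg/(m/s), (sys, dia)
    bp_feature: str = "pwv"                 # "pwv" or "inv_ptt"
    spo2_slope: float = -33.3               # % per unit R
    # -- reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ecg_band", "bcg_band", "ppg_band"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi):
                raise ValueError(f"{name} must satisfy 0 <= low < high, got ({lo}, {hi})")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (0 < self.rr_tolerance < 1):
            raise ValueError("rr_tolerance must be in (0, 1)")
        if self.bp_feature not in ("pwv", "inv_ptt"):
            raise ValueError("bp_feature must be 'pwv' or 'inv_ptt'")
        if self.ptt_wavelength not in ("ir", "red"):
            raise ValueError("ptt_wavelength must be 'ir' or 'red'")
        if self.spo2_slope >= 0:
            raise ValueError("spo2_slope must be negative")

    # --- flat key=value serialisation -----------------------------------
    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(repr(x) for x in v)
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        kv = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in kv:
                continue
            raw = kv[f.name]
            origin = getattr(f.type, "__origin__", None)
            if f.type in ("Tuple[float, float]",) or origin is tuple or "Tuple" in str(f.type):
                kwargs[f.name] = tuple(float(x) for x in raw.split(","))
            elif f.type in ("int",) or f.type is int:
                kwargs[f.name] = int(raw)
            elif f.type in ("float",) or f.type is float:
                kwargs[f.name] = float(raw)
            else:
                kwargs[f.name] = raw
        return cls(**kwargs)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path: Union[str, Path]) -> "PipelineConfig":
        return cls.from_text(Path(path).read_text())
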