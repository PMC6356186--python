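"""Signal processing: beats, quality gating, ensembles and fiducials.

The processing chain mirrors how a seat recording becomes features:

1. R peaks are detected on the ECG (derivative-energy detector with a
   refractory period) and serve as the alignment reference.
2. Beats whose adjacent RR intervals deviate from a running median are
   removed, since diastolic-duration changes shift beat-by-beat BP/SV.
3. A recording-level quality check may reject the whole recording
   (too few beats, too short a usable span, too much motion power).
4. Accepted beats are ensemble averaged per channel around R.
5. Fiducials are read off the ensembles: BCG I/J/K waves and the J−K
   amplitude; PPG foot by intersecting tangents; PPG AC and DC levels.

All filtering is zero-phase (forward-backward Butterworth) so fiducial
timing is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import PipelineConfig, log
from .synthcardio import Recording


class SignalQualityError(RuntimeError):
    """Raised when a recording or ensemble is unusable for estimation."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class BeatSeries:
    """Detected beats with per-beat acceptance flags."""

    r_times: np.ndarray                  # s, strictly increasing
    accepted: np.ndarray                 # bool per beat
    rejection_reason: List[Optional[str]]
    flags: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        if self.r_times.size and np.any(np.diff(self.r_times) <= 0):
            raise ValueError("r_times must be strictly increasing")
        if not (self.r_times.size == self.accepted.size == len(self.rejection_reason)):
            raise ValueError("per-beat arrays must have equal length")

    @property
    def rr(self) -> np.ndarray:
        """RR intervals, s; length is one less than the number of beats."""
        return np.diff(self.r_times)

    @property
    def n_beats(self) -> int:
        return int(self.r_times.size)

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())


@dataclass(frozen=True)
class QualityReport:
    recording_accepted: bool
    n_beats_total: int
    n_beats_accepted: int
    reasons: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_beats_accepted > self.n_beats_total:
            raise ValueError("accepted beats cannot exceed total beats")


@dataclass
class EnsembleWaveform:
    """Pointwise mean of accepted beats aligned on the R peak.

    ``noise_sd`` is the residual noise SD of the ensemble mean (mean
    across-beat SD divided by sqrt(n_beats)); ``dc_level`` is the raw
    (unfiltered) channel mean over the accepted-beat span, carried for
    PPG channels so that the optical DC survives band-pass filtering.
    """

    channel: str
    rel_time: np.ndarray     # s relative to R
    amplitude: np.ndarray
    n_beats: int
    noise_sd: float = 0.0
    dc_level: float = 0.0

    def __post_init__(self) -> None:
        if self.n_beats < 1:
            raise ValueError("an ensemble needs at least one beat")
        if self.rel_time.size != self.amplitude.size:
            raise ValueError("rel_time and amplitude must have equal length")


@dataclass(frozen=True)
class Fiducial:
    time: float       # s relative to R
    amplitude: float  # channel units


@dataclass
class FiducialSet:
    """Timing/amplitude features extracted from one recording's ensembles."""

    bcg_i: Optional[Fiducial] = None
    bcg_j: Optional[Fiducial] = None
    bcg_k: Optional[Fiducial] = None
    jk_amplitude: Optional[float] = None          # N
    ppg_foot_time: Dict[str, float] = field(default_factory=dict)   # per wavelength
    ac: Dict[str, float] = field(default_factory=dict)              # a.u.
    dc: Dict[str, float] = field(default_factory=dict)              # a.u.
    ac_snr: Dict[str, float] = field(default_factory=dict)          # AC / ensemble noise
    flags: List[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.bcg_i and self.bcg_j and self.bcg_k:
            if not (self.bcg_i.time < self.bcg_j.time < self.bcg_k.time):
                raise ValueError("BCG fiducials must be ordered I < J < K in time")
        if self.jk_amplitude is not None and self.jk_amplitude < 0:
            raise ValueError("J−K amplitude must be non-negative")
        for wl, d in self.dc.items():
            if d <= 0:
                raise ValueError(f"DC level for {wl} must be positive")


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------

def bandpass(x: np.ndarray, fs: float, band: Tuple[float, float], order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass (low corner 0 means low-pass only)."""
    lo, hi = band
    nyq = fs / 2.0
    if hi >= nyq:
        hi = 0.99 * nyq
    if lo <= 0:
        sos = sps.butter(order, hi / nyq, btype="low", output="sos")
    else:
        sos = sps.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x)


_CHANNEL_BAND = {"ecg": "ecg_band", "bcg": "bcg_band", "ppg_red": "ppg_band", "ppg_ir": "ppg_band"}


def filter_channel(rec: Recording, channel: str, config: PipelineConfig) -> np.ndarray:
    return bandpass(rec.channel(channel), rec.fs, getattr(config, _CHANNEL_BAND[channel]),
                    config.filter_order)


# --------------------------------------------------------------------------
# R-peak detection
# --------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, fs: float, config: Optional[PipelineConfig] = None) -> BeatSeries:
    """Derivative-energy QRS detector with a 200 ms refractory period.

    The ECG is band-passed to the QRS band (5–25 Hz), differentiated,
    squared and integrated over a 150 ms moving window; energy peaks at
    least 200 ms apart above an amplitude threshold mark beats, and each
    beat time is refined to the local extremum of the band-passed ECG.
    Flat or NaN input yields an empty, flagged series.
    """
    config = config or PipelineConfig()
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < 2 * fs:
        raise ValueError("need at least 2 s of ECG")
    if np.isnan(ecg).all() or np.nanstd(ecg) == 0:
        return BeatSeries(np.array([]), np.array([], dtype=bool), [], flags=["flat_or_nan_input"])
    x = np.nan_to_num(ecg, nan=0.0)
    filt = bandpass(x, fs, (5.0, min(25.0, 0.45 * fs)), order=2)
    energy = np.convolve(np.gradient(filt) ** 2, np.ones(int(round(0.150 * fs))), mode="same")
    thr = 0.15 * np.percentile(energy, 99)
    if thr <= 0:
        return BeatSeries(np.array([]), np.array([], dtype=bool), [], flags=["flat_or_nan_input"])
    peaks, _ = sps.find_peaks(energy, height=thr, distance=int(round(0.200 * fs)))
    # refine each detection to the dominant deflection of the band-passed ECG
    half = int(round(0.08 * fs))
    r_idx = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, x.size)
        seg = filt[lo:hi]
        r_idx.append(lo + (np.argmax(seg) if abs(seg.max()) >= abs(seg.min()) else np.argmin(seg)))
    r_idx = np.unique(np.asarray(r_idx, dtype=int))
    # enforce refractory after refinement
    keep = []
    for i in r_idx:
        if not keep or (i - keep[-1]) / fs >= 0.200:
            keep.append(i)
    r_times = np.array(keep, dtype=float) / fs
    n = r_times.size
    return BeatSeries(r_times, np.ones(n, dtype=bool), [None] * n)


# --------------------------------------------------------------------------
# beat-interval quality
# --------------------------------------------------------------------------

def filter_abnormal_beats(beats: BeatSeries, tolerance: float = 0.20,
                          window: int = 11) -> BeatSeries:
    """Reject beats bounding abnormal RR intervals.

    An interval is abnormal when it deviates from the running median RR
    (centered window of ``window`` intervals) by more than ``tolerance``
    as a fraction of that median; both beats bounding an abnormal
    interval are rejected.  Timing is never altered, so the operation is
    idempotent.  Fewer than 3 beats rejects everything ("too_few").
    """
    n = beats.n_beats
    if n < 3:
        return BeatSeries(beats.r_times, np.zeros(n, dtype=bool), ["too_few"] * n,
                          flags=list(beats.flags))
    rr = beats.rr
    med = pd.Series(rr).rolling(window, center=True, min_periods=1).median().to_numpy()
    abnormal = np.abs(rr - med) > tolerance * med
    accepted = beats.accepted.copy()
    reasons: List[Optional[str]] = list(beats.rejection_reason)
    for j in np.where(abnormal)[0]:
        for b in (j, j + 1):  # beats bounding interval j
            accepted[b] = False
            if reasons[b] is None:
                reasons[b] = "abnormal_interval"
    return BeatSeries(beats.r_times, accepted, reasons, flags=list(beats.flags))


# --------------------------------------------------------------------------
# recording-level quality
# --------------------------------------------------------------------------

def motion_power_fraction(rec: Recording, config: PipelineConfig) -> float:
    """Fraction of 1 s BCG windows whose RMS exceeds a multiple of the median RMS."""
    bcg = filter_channel(rec, "bcg", config)
    w = int(round(config.motion_window_s * rec.fs))
    n_win = bcg.size // w
    if n_win == 0:
        return 0.0
    rms = np.sqrt(np.mean(bcg[: n_win * w].reshape(n_win, w) ** 2, axis=1))
    med = np.median(rms)
    if med == 0:
        return 0.0
    return float(np.mean(rms > config.motion_rms_factor * med))


def assess_recording(rec: Recording, beats: BeatSeries,
                     config: Optional[PipelineConfig] = None) -> QualityReport:
    """Recording-level accept/reject decision.

    Accepts iff the accepted-beat count and their time span meet minimums
    and the fraction of high-motion-power BCG windows stays below the
    limit.  Always returns a report; never raises.
    """
    config = config or PipelineConfig()
    reasons: List[str] = []
    acc_times = beats.r_times[beats.accepted]
    if beats.n_accepted < config.min_beats:
        reasons.append("too_few_beats")
    span = float(acc_times[-1] - acc_times[0]) if acc_times.size >= 2 else 0.0
    if span < config.min_span_s:
        reasons.append("too_short")
    if motion_power_fraction(rec, config) > config.max_motion_fraction:
        reasons.append("motion")
    if reasons:
        log.info("recording %s rejected: %s", rec.subject_id, ",".join(reasons))
    return QualityReport(
        recording_accepted=not reasons,
        n_beats_total=beats.n_beats,
        n_beats_accepted=beats.n_accepted,
        reasons=tuple(reasons),
    )


# --------------------------------------------------------------------------
# ensemble averaging
# --------------------------------------------------------------------------

def ensemble_average(rec: Recording, beats: BeatSeries, channel: str,
                     window: Optional[Tuple[float, float]] = None,
                     config: Optional[PipelineConfig] = None) -> EnsembleWaveform:
    """Pointwise mean across accepted beats, aligned on the R peak.

    The channel is band-pass filtered first; the window (s before R,
    s after R) is truncated to the minimum accepted RR so adjacent beats
    do not leak in.  For PPG channels the raw-channel mean over the
    accepted span is stored as ``dc_level`` (band-passing removes DC).
    Zero accepted beats raises :class:`SignalQualityError`.
    """
    config = config or PipelineConfig()
    if window is None:
        window = (config.ensemble_pre_s, config.ensemble_post_s)
    acc = beats.r_times[beats.accepted]
    if acc.size == 0:
        raise SignalQualityError("no accepted beats to ensemble average")
    pre, post = window
    if acc.size >= 2:
        post = min(post, float(np.min(np.diff(acc))))
    filt = filter_channel(rec, channel, config)
    npre, npost = int(round(pre * rec.fs)), int(round(post * rec.fs))
    guard = int(round(config.edge_guard_s * rec.fs))
    segs = []
    for t in acc:
        i = int(round(t * rec.fs))
        if i - npre >= guard and i + npost <= filt.size - guard:
            segs.append(filt[i - npre: i + npost])
    if not segs:
        raise SignalQualityError("no beat window fits inside the recording")
    mat = np.vstack(segs)
    amp = mat.mean(axis=0)
    noise_sd = float(np.mean(mat.std(axis=0, ddof=1)) / np.sqrt(mat.shape[0])) if mat.shape[0] > 1 else 0.0
    dc_level = 0.0
    if channel.startswith("ppg"):
        raw = rec.channel(channel)
        i0 = max(int(round((acc[0] - pre) * rec.fs)), 0)
        i1 = min(int(round((acc[-1] + post) * rec.fs)), raw.size)
        dc_level = float(np.mean(raw[i0:i1]))
    rel_time = np.arange(-npre, npost) / rec.fs
    return EnsembleWaveform(channel=channel, rel_time=rel_time, amplitude=amp,
                            n_beats=mat.shape[0], noise_sd=noise_sd, dc_level=dc_level)


# --------------------------------------------------------------------------
# fiducials
# --------------------------------------------------------------------------

def _parabolic_refine(t: np.ndarray, y: np.ndarray, i: int) -> Tuple[float, float]:
    """Sub-sample extremum via a parabola through (i-1, i, i+1)."""
    if i <= 0 or i >= y.size - 1:
        return float(t[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(t[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    dt = t[1] - t[0]
    return float(t[i] + delta * dt), float(y1 - 0.25 * (y0 - y2) * delta)


def locate_bcg_fiducials(ens: EnsembleWaveform,
                         config: Optional[PipelineConfig] = None) -> FiducialSet:
    """Locate the I, J, K waves on a BCG ensemble.

    J is the global maximum within the search window after R (earliest
    sample on ties); I is the local minimum preceding J and K the local
    minimum following it, both refined to sub-sample precision.
    """
    config = config or PipelineConfig()
    if ens.channel != "bcg":
        raise ValueError("BCG fiducials require a BCG ensemble")
    t, y = ens.rel_time, ens.amplitude
    lo, hi = config.j_search_s
    win = np.where((t >= lo) & (t <= hi))[0]
    if win.size == 0:
        raise SignalQualityError("J search window outside ensemble")
    j_idx = win[int(np.argmax(y[win]))]
    mins = sps.argrelmin(y, order=2)[0]
    before = mins[mins < j_idx]
    after = mins[mins > j_idx]
    fs_out = FiducialSet()
    if before.size == 0 or after.size == 0:
        fs_out.flags.append("bcg_fiducials_undefined")
        return fs_out
    i_idx, k_idx = int(before[-1]), int(after[0])
    fs_out.bcg_j = Fiducial(*_parabolic_refine(t, y, int(j_idx)))
    fs_out.bcg_i = Fiducial(*_parabolic_refine(t, y, i_idx))
    fs_out.bcg_k = Fiducial(*_parabolic_refine(t, y, k_idx))
    fs_out.jk_amplitude = fs_out.bcg_j.amplitude - fs_out.bcg_k.amplitude
    fs_out.validate()
    return fs_out


def locate_ppg_foot(ens: EnsembleWaveform,
                    config: Optional[PipelineConfig] = None) -> float:
    """PPG pulse foot by intersecting tangents, s relative to R.

    The foot is the intersection of the horizontal line through the
    pre-systolic minimum with the tangent at the point of maximum
    upslope; the result is continuous (sub-sample) and invariant to a
    vertical offset of the whole waveform.
    """
    config = config or PipelineConfig()
    if not ens.channel.startswith("ppg"):
        raise ValueError("PPG foot requires a PPG ensemble")
    t, y = ens.rel_time, ens.amplitude
    lo, hi = config.foot_search_s
    win = np.where((t >= lo) & (t <= hi))[0]
    if win.size < 5:
        raise SignalQualityError("foot search window outside ensemble")
    pk = win[int(np.argmax(y[win]))]
    ac_rough = float(y[pk] - np.min(y[win[0]:pk + 1])) if pk > win[0] else 0.0
    if ac_rough <= max(5.0 * ens.noise_sd, 1e-12):
        raise SignalQualityError("non-pulsatile PPG ensemble (AC ~ 0)")
    dt = t[1] - t[0]
    dy = np.gradient(y, dt)
    up_seg = np.arange(win[0], pk + 1)
    iu = up_seg[int(np.argmax(dy[up_seg]))]
    im = up_seg[int(np.argmin(y[up_seg[up_seg <= iu]]))]
    slope = dy[iu]
    if slope <= 0:
        raise SignalQualityError("no rising edge before PPG peak")
    t_up, y_up = _parabolic_refine(t, dy, int(iu))  # refine upslope location
    y_at_up = float(np.interp(t_up, t, y))
    baseline = float(y[im])
    return float(t_up - (y_at_up - baseline) / slope)


def measure_ppg_ac_dc(ens: EnsembleWaveform,
                      config: Optional[PipelineConfig] = None) -> Tuple[float, float]:
    """AC (peak minus pre-systolic minimum) and DC (raw optical level).

    The AC is read from the band-passed ensemble pulse; the DC is the
    raw-channel mean carried on the ensemble, since band-passing removes
    the optical baseline.  A non-positive DC is non-physical and raises.
    """
    config = config or PipelineConfig()
    if not ens.channel.startswith("ppg"):
        raise ValueError("AC/DC requires a PPG ensemble")
    t, y = ens.rel_time, ens.amplitude
    lo, hi = config.foot_search_s
    win = np.where((t >= lo) & (t <= hi))[0]
    pk = win[int(np.argmax(y[win]))] if win.size else int(np.argmax(y))
    base = float(np.min(y[win[0]:pk + 1])) if win.size and pk > win[0] else float(np.min(y))
    ac = float(y[pk] - base)
    dc = ens.dc_level
    if dc <= 0:
        raise ValueError(f"non-physical DC level {dc}")
    return ac, dc
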