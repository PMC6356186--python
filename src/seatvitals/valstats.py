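"""Device-validation statistics.

Agreement between a device estimate and a gold-standard reference is
summarised the way the medical-device literature does it: Bland-Altman
bias and SD of the paired differences with limits of agreement (LoA)
at ``bias ± 1.96·SD``, the pulse-oximetry RMS accuracy statistic
``A_RMS = sqrt(mean(d²))``, and pass/fail verdicts against the numeric
criteria of the AAMI blood-pressure standard (|bias| ≤ 5 mm Hg and
SD ≤ 8 mm Hg) and the ISO pulse-oximetry standard (A_RMS ≤ 3.5 %).

Conventions: the SD of the differences uses the sample (n−1) divisor,
A_RMS uses the n divisor, so ``arms² == bias² + sd²·(n−1)/n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

LOA_FACTOR = 1.96
AAMI_MAX_ABS_BIAS = 5.0   # mm Hg
AAMI_MAX_SD = 8.0         # mm Hg
ISO_MAX_ARMS = 3.5        # % SpO2

#: default BMI strata, half-open [low, high) in kg/m^2
DEFAULT_BMI_BINS: List[Tuple[float, float]] = [
    (-math.inf, 18.5),
    (18.5, 25.0),
    (25.0, 30.0),
    (30.0, math.inf),
]


@dataclass(frozen=True)
class BlandAltmanResult:
    """Summary of paired device-minus-reference differences."""

    n: int
    bias: float
    sd: float
    arms: float

    @property
    def loa_halfwidth(self) -> float:
        return LOA_FACTOR * self.sd

    @property
    def loa_interval(self) -> Tuple[float, float]:
        return (self.bias - self.loa_halfwidth, self.bias + self.loa_halfwidth)


@dataclass(frozen=True)
class ComplianceVerdict:
    """Pass/fail against a named standard; passes iff all margins >= 0."""

    standard: str
    passed: bool
    margins: Dict[str, float]

    @property
    def margin(self) -> float:
        return min(self.margins.values())


def bland_altman(seat: Sequence[float], gold: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman statistics of ``seat − gold`` paired differences.

    bias = mean(d); sd = sample SD(d) (ddof=1); arms = sqrt(mean(d²)).
    """
    seat = np.asarray(seat, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if seat.shape != gold.shape or seat.ndim != 1:
        raise ValueError(f"seat and gold must be equal-length 1-D, got {seat.shape} vs {gold.shape}")
    n = seat.size
    if n < 2:
        raise ValueError("need at least 2 paired values")
    d = seat - gold
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    arms = float(np.sqrt(np.mean(d * d)))
    return BlandAltmanResult(n=n, bias=bias, sd=sd, arms=arms)


def loa_from_arms(arms: float) -> float:
    """Convert an RMS accuracy to a zero-mean limits of agreement: 1.96·arms."""
    if arms < 0:
        raise ValueError("arms must be non-negative")
    return LOA_FACTOR * arms


def check_compliance(result: BlandAltmanResult, standard: str) -> ComplianceVerdict:
    """Check a Bland-Altman summary against AAMI_BP or ISO_SPO2 criteria."""
    if standard == "AAMI_BP":
        margins = {
            "bias": AAMI_MAX_ABS_BIAS - abs(result.bias),
            "sd": AAMI_MAX_SD - result.sd,
        }
    elif standard == "ISO_SPO2":
        margins = {"arms": ISO_MAX_ARMS - result.arms}
    else:
        raise ValueError(f"unknown standard {standard!r}; expected 'AAMI_BP' or 'ISO_SPO2'")
    return ComplianceVerdict(standard=standard, passed=all(m >= 0 for m in margins.values()), margins=margins)


def stratify(
    records: Sequence[Tuple[float, float]],
    bins: Sequence[Tuple[float, float]] = None,
) -> List[dict]:
    """Per-BMI-stratum Bland-Altman statistics.

    ``records`` are (difference, bmi) pairs; ``bins`` are non-overlapping
    half-open intervals [low, high).  Each record falls in exactly one bin
    or none.  Bins with fewer than 2 records report n and bias only.
    """
    if bins is None:
        bins = DEFAULT_BMI_BINS
    spans = sorted(bins)
    for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
        if hi1 > lo2:
            raise ValueError(f"overlapping bins: [{lo1},{hi1}) and [{lo2},{hi2})")
    for lo, hi in bins:
        if lo >= hi:
            raise ValueError(f"empty bin [{lo},{hi})")
    out = []
    diffs = np.array([d for d, _ in records], dtype=float)
    bmis = np.array([b for _, b in records], dtype=float)
    for lo, hi in bins:
        mask = (bmis >= lo) & (bmis < hi)
        d = diffs[mask]
        row = {"bin": (lo, hi), "n": int(mask.sum())}
        if d.size >= 2:
            bias = float(np.mean(d))
            sd = float(np.std(d, ddof=1))
            row.update(bias=bias, sd=sd, loa_halfwidth=LOA_FACTOR * sd)
        elif d.size == 1:
            row.update(bias=float(d[0]), sd=float("nan"), loa_halfwidth=float("nan"))
        else:
            row.update(bias=float("nan"), sd=float("nan"), loa_halfwidth=float("nan"))
        out.append(row)
    return out


def bland_altman_plot(seat: Sequence[float], gold: Sequence[float], path,
                      title: str = "", units: str = "",
                      shaded_loa: float = None) -> BlandAltmanResult:
    """Write a Bland-Altman plot to ``path``; returns the computed statistics.

    Differences are plotted against pair means with the bias and the
    ±1.96·SD limits of agreement; ``shaded_loa`` adds a compliance band
    around the bias.  Requires matplotlib (not a core dependency).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    result = bland_altman(seat, gold)
    seat = np.asarray(seat, float)
    gold = np.asarray(gold, float)
    means = (seat + gold) / 2.0
    diffs = seat - gold
    fig, ax = plt.subplots(figsize=(5, 4))
    if shaded_loa is not None:
        ax.axhspan(result.bias - shaded_loa, result.bias + shaded_loa,
                   color="0.88", zorder=0)
    ax.scatter(means, diffs, s=12, alpha=0.7)
    ax.axhline(result.bias, color="k", lw=1)
    for y in result.loa_interval:
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel(f"mean of methods {('(' + units + ')') if units else ''}")
    ax.set_ylabel(f"device − reference {('(' + units + ')') if units else ''}")
    ax.set_title(title or f"n={result.n}, bias={result.bias:.1f}, LoA=±{result.loa_halfwidth:.1f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return result


def percent_slope_variation(s1: float, s2: float) -> float:
    """Relative spread of two calibration-curve slopes, % of their mean.

    Returns ``100·|s1 − s2| / |mean(s1, s2)|``; report rounded to the
    nearest integer.  Slopes must be nonzero and of the same sign.
    """
    if s1 == 0 or s2 == 0:
        raise ValueError("slopes must be nonzero")
    if (s1 > 0) != (s2 > 0):
        raise ValueError("slopes must have the same sign")
    return 100.0 * abs(s1 - s2) / abs((s1 + s2) / 2.0)
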