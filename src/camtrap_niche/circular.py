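"""Circular (diel) statistics for activity patterns.

Clock times are mapped to angles on the 24-h circle
(theta = 2*pi*hours/24).  Per-species summaries report the mean direction,
mean resultant length R-bar, circular variance V = 1 - R-bar, the
large-sample (dispersion-based) standard error and confidence interval of the
mean direction, and Rayleigh's uniformity test Z = n*R-bar^2 with the
exponential large-sample p approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, time
from typing import Sequence

import numpy as np

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class ActivitySample:
    """Event clock times as angles in [0, 2*pi)."""

    angles: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.angles, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("angles must be a non-empty 1-D array")
        if ((arr < 0) | (arr >= TWO_PI)).any():
            raise ValueError("angles must lie in [0, 2*pi)")
        object.__setattr__(self, "angles", arr)

    @property
    def n(self) -> int:
        return int(self.angles.size)

    @classmethod
    def from_times(cls, timestamps: Sequence[datetime]) -> "ActivitySample":
        return cls(np.array([time_to_angle(t) for t in timestamps]))


@dataclass(frozen=True)
class CircularSummary:
    """One row of a circular-statistics activity table."""

    n: int
    mean_direction: float | None   # radians, None when R-bar == 0
    mean_resultant_length: float   # R-bar in [0, 1]
    circular_variance: float       # V = 1 - R-bar
    se_mean: float | None          # radians; None when undefined (n < 2)
    ci95: tuple[float, float] | None  # radians on the circle
    rayleigh_z: float
    rayleigh_p: float

    @property
    def mean_clock(self) -> str:
        """hh:mm rendering of the mean direction."""
        if self.mean_direction is None:
            return "undefined"
        return angle_to_clock(self.mean_direction)


@dataclass(frozen=True)
class HourlyProfile:
    """Percent of events in each of the 24 clock-hour bins."""

    percent: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.percent, dtype=float)
        if arr.shape != (24,):
            raise ValueError("percent must have 24 entries")
        if not np.isclose(arr.sum(), 100.0, atol=1e-9):
            raise ValueError("hourly percents must sum to 100")
        object.__setattr__(self, "percent", arr)


def time_to_angle(t: datetime | time) -> float:
    """Map a clock time to its angle on the 24-h circle, in [0, 2*pi)."""
    h = t.hour + t.minute / 60.0 + t.second / 3600.0
    return (TWO_PI * h / 24.0) % TWO_PI


def angle_to_clock(theta: float) -> str:
    """Render an angle as hh:mm (minutes rounded)."""
    hours = (theta % TWO_PI) * 24.0 / TWO_PI
    total_min = int(round(hours * 60.0)) % (24 * 60)
    return f"{total_min // 60:02d}:{total_min % 60:02d}"


def _resultant(angles: np.ndarray) -> tuple[float, float, float]:
    c = float(np.cos(angles).sum())
    s = float(np.sin(angles).sum())
    return c, s, float(np.hypot(c, s))


def circular_summary(sample: ActivitySample, alpha: float = 0.05) -> CircularSummary:
    """Mean vector, dispersion, CI of the mean direction, and Rayleigh test.

    The standard error is the large-sample circular dispersion estimate
    sigma-hat = sqrt((1 - alpha2-hat) / (2 n R-bar^2)) with
    alpha2-hat = mean(cos 2(theta - mu-hat)); the (1 - alpha) CI is
    mu-hat +/- arcsin(z * sigma-hat), undefined when z * sigma-hat > 1
    (too dispersed for the arcsine interval) or when R-bar = 0.
    """
    from scipy import stats

    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    angles = sample.angles
    n = sample.n
    c, s, r = _resultant(angles)
    rbar = r / n
    v = 1.0 - rbar

    if rbar <= 1e-12:
        mean_dir = None
        se = None
        ci = None
    else:
        mean_dir = float(np.arctan2(s, c) % TWO_PI)
        if n < 2:
            se = None
            ci = None
        else:
            alpha2 = float(np.mean(np.cos(2.0 * (angles - mean_dir))))
            disp = (1.0 - alpha2) / (2.0 * n * rbar**2)
            se = float(np.sqrt(max(disp, 0.0)))
            z = stats.norm.ppf(1.0 - alpha / 2.0)
            if z * se <= 1.0:
                half = float(np.arcsin(z * se))
                ci = ((mean_dir - half) % TWO_PI, (mean_dir + half) % TWO_PI)
            else:
                ci = None

    zstat, p = _rayleigh(n, rbar)
    return CircularSummary(
        n=n,
        mean_direction=mean_dir,
        mean_resultant_length=rbar,
        circular_variance=v,
        se_mean=se,
        ci95=ci,
        rayleigh_z=zstat,
        rayleigh_p=p,
    )


def _rayleigh(n: int, rbar: float) -> tuple[float, float]:
    z = n * rbar**2
    r = n * rbar
    # Large-sample exponential approximation with the second-order correction.
    p = float(np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - r**2)) - (1.0 + 2.0 * n)))
    return float(z), float(min(max(p, np.finfo(float).tiny), 1.0))


def rayleigh_test(sample: ActivitySample) -> tuple[float, float]:
    """Rayleigh's test of circular uniformity: returns (Z, p).

    Z = n * R-bar^2; p by the exponential large-sample approximation,
    clipped to (0, 1].
    """
    if sample.n < 2:
        raise ValueError("Rayleigh test requires n >= 2")
    _, _, r = _resultant(sample.angles)
    return _rayleigh(sample.n, r / sample.n)


def hourly_profile(timestamps: Sequence[datetime]) -> HourlyProfile:
    """Percent of events whose clock hour falls in each bin [b, b+1)."""
    if len(timestamps) == 0:
        raise ValueError("hourly profile requires at least one event")
    hours = np.array([t.hour for t in timestamps])
    counts = np.bincount(hours, minlength=24).astype(float)
    return HourlyProfile(percent=100.0 * counts / counts.sum())
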