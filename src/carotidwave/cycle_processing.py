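"""Cardiac-cycle segmentation, arrhythmia rejection and ensemble averaging.

Cycles are delimited at the start of systole ("foot" of the upstroke),
located by the intersecting-tangents construction: the horizontal tangent
through the pre-upstroke minimum intersected with the tangent at the point
of maximum upstroke slope.  Feet are detected on one reference signal
(velocity or flow) and reused to segment all phase-locked signals, which
are then resampled to a common number of samples per cycle and averaged
pointwise.  Cycles whose RR interval deviates from the median by more than
a configurable fraction (arrhythmic beats) are excluded before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = [
    "CycleEnsemble",
    "CycleDetectionError",
    "detect_systole_feet",
    "reject_arrhythmic",
    "ensemble_average",
]


class CycleDetectionError(RuntimeError):
    """Raised when too few cardiac cycles can be identified."""


@dataclass
class CycleEnsemble:
    """Resampled cardiac cycles and their pointwise average.

    ``cycles[name]`` has shape (n_cycles_used, n_samples); ``mean_cycle``
    holds the per-signal average.  All signals share the same sample grid,
    so area, velocity and flow stay sample-aligned.
    """

    n_cycles_used: int
    n_cycles_rejected: int
    period: float  #: median RR of retained cycles, s
    cycles: dict
    mean_cycle: dict

    @property
    def heart_rate(self) -> float:
        """beats/min, from the median RR interval."""
        return 60.0 / self.period

    @property
    def n_samples(self) -> int:
        return next(iter(self.mean_cycle.values())).shape[0]

    def phase_time(self) -> np.ndarray:
        """Time within the averaged cycle, s."""
        return np.arange(self.n_samples) * self.period / self.n_samples


def detect_systole_feet(
    t: np.ndarray,
    signal: np.ndarray,
    smooth_sigma_samples: float = 2.0,
    min_rr: float = 0.06,
    slope_prominence_frac: float = 0.5,
) -> np.ndarray:
    """Locate cycle-start times at the foot of each systolic upstroke.

    Upstrokes are the prominent maxima of the signal's time derivative (at
    least ``min_rr`` apart).  For each, the foot is the intersection of the
    horizontal tangent through the preceding minimum with the tangent at
    the maximum-slope point.

    Returns strictly increasing foot times; raises
    :class:`CycleDetectionError` if fewer than 3 are found.
    """
    if len(t) != len(signal):
        raise ValueError("t and signal must have equal length")
    dt = float(t[1] - t[0])
    x = gaussian_filter1d(np.asarray(signal, dtype=float), smooth_sigma_samples)
    dx = np.gradient(x, dt)

    prom = slope_prominence_frac * max(float(np.percentile(dx, 99)), 1e-300)
    if not np.isfinite(prom) or prom <= 0 or np.percentile(dx, 99) <= 0:
        raise CycleDetectionError("no systolic upstrokes found (flat signal?)")
    peaks, _ = find_peaks(dx, prominence=prom,
                          distance=max(2, int(round(min_rr / dt))))
    if len(peaks) < 3:
        raise CycleDetectionError(
            f"only {len(peaks)} upstroke(s) detected; need at least 3 cycles"
        )

    med_gap = float(np.median(np.diff(peaks)))
    feet = []
    for k, m in enumerate(peaks):
        lo = peaks[k - 1] if k > 0 else max(0, int(m - med_gap))
        if lo >= m:
            continue
        y_min = float(x[lo:m + 1].min())
        slope = float(dx[m])
        if slope <= 0:
            continue
        t_foot = t[m] - (x[m] - y_min) / slope
        feet.append(t_foot)
    feet = np.asarray(feet)
    feet = feet[np.concatenate([[True], np.diff(feet) > 0])]
    if len(feet) < 3:
        raise CycleDetectionError("fewer than 3 valid systolic feet located")
    return feet


def reject_arrhythmic(feet: np.ndarray, max_rr_deviation: float = 0.2):
    """Indices of cycles whose RR interval is within tolerance of the median.

    Cycle ``i`` spans ``feet[i]`` to ``feet[i+1]``.  A cycle is rejected
    when ``|RR_i − median(RR)| > max_rr_deviation · median(RR)``.

    Returns
    -------
    retained, rejected : ndarray of int
    """
    rr = np.diff(np.asarray(feet, dtype=float))
    if len(rr) < 1:
        raise ValueError("need at least two feet to form a cycle")
    med = float(np.median(rr))
    ok = np.abs(rr - med) <= max_rr_deviation * med
    idx = np.arange(len(rr))
    return idx[ok], idx[~ok]


def ensemble_average(
    t: np.ndarray,
    signals: dict,
    feet: np.ndarray,
    n_samples: int = 256,
    max_rr_deviation: float = 0.2,
) -> CycleEnsemble:
    """Resample retained cycles to a common grid and average pointwise.

    Each retained cycle is linearly resampled to ``n_samples`` points
    spanning foot-to-foot (the last, partial cycle after the final foot is
    always discarded).  The heart rate comes from the median RR of the
    retained cycles.
    """
    feet = np.asarray(feet, dtype=float)
    retained, rejected = reject_arrhythmic(feet, max_rr_deviation)
    if len(retained) < 3:
        raise CycleDetectionError(
            f"only {len(retained)} cycles retained after arrhythmia rejection"
        )
    frac = np.arange(n_samples) / n_samples
    cycles = {}
    for name, sig in signals.items():
        sig = np.asarray(sig, dtype=float)
        rows = np.empty((len(retained), n_samples))
        for r, i in enumerate(retained):
            grid = feet[i] + (feet[i + 1] - feet[i]) * frac
            rows[r] = np.interp(grid, t, sig)
        cycles[name] = rows
    mean_cycle = {name: rows.mean(axis=0) for name, rows in cycles.items()}
    period = float(np.median(np.diff(feet)[retained]))
    return CycleEnsemble(
        n_cycles_used=len(retained),
        n_cycles_rejected=len(rejected),
        period=period,
        cycles=cycles,
        mean_cycle=mean_cycle,
    )
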