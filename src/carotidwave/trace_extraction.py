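"""Recover wall-position and velocity-envelope time series from images.

The M-mode wall outliner assumes the generator's contract: a dark lumen
between two dominant bright wall bands.  Per column it finds the two most
prominent peaks of the smoothed depth profile, refines each band to
sub-pixel accuracy as the midpoint of its half-maximum crossings (exact
for a symmetric band profile), and reads wall thickness off the full width
at half maximum, deconvolving the depth smoothing.  The Doppler envelope
tracer picks, per column, the highest velocity bin that clears a
noise-floor threshold with a few contiguous filled bins beneath it, and
halves the envelope to get the lumen-mean velocity (parabolic-profile
rule).  Both traces get a temporal despike filter that replaces only
outliers against a running median, so clean systolic peaks are preserved.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, gaussian_filter1d, median_filter
from scipy.signal import find_peaks

from .images import DopplerSpectrogram, MModeImage

__all__ = [
    "WallTrace",
    "VelocityEnvelope",
    "ExtractionError",
    "outline_walls",
    "trace_envelope",
]


class ExtractionError(RuntimeError):
    """Raised when an image does not yield usable traces."""


@dataclass
class WallTrace:
    """Per-column wall positions and thicknesses, mm."""

    t: np.ndarray  #: s
    near_wall_depth: np.ndarray  #: mm
    far_wall_depth: np.ndarray  #: mm
    near_wall_thickness: np.ndarray  #: mm
    far_wall_thickness: np.ndarray  #: mm

    @property
    def diameter(self) -> np.ndarray:
        """Lumen diameter (band-centre separation), mm."""
        return self.far_wall_depth - self.near_wall_depth

    def validate(self) -> None:
        for arr in (self.near_wall_depth, self.far_wall_depth):
            if np.any(~np.isfinite(arr)):
                raise ValueError("wall traces contain non-finite values")
        if np.any(self.far_wall_depth <= self.near_wall_depth):
            raise ValueError("far wall must lie deeper than near wall")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.t,
            "near_wall_depth_mm": self.near_wall_depth,
            "far_wall_depth_mm": self.far_wall_depth,
            "near_wall_thickness_mm": self.near_wall_thickness,
            "far_wall_thickness_mm": self.far_wall_thickness,
            "diameter_mm": self.diameter,
        })


@dataclass
class VelocityEnvelope:
    """Traced maximum-velocity envelope; mean velocity is half of it."""

    t: np.ndarray  #: s
    v_max: np.ndarray  #: mm/s

    @property
    def v_mean(self) -> np.ndarray:
        """Lumen-mean velocity, mm/s (envelope divided by two)."""
        return self.v_max / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "v_max_mm_s": self.v_max,
                             "v_mean_mm_s": self.v_mean})


def _despike(x: np.ndarray, tol: float, width: int = 5) -> np.ndarray:
    """Replace samples deviating more than ``tol`` from a running median."""
    med = median_filter(x, size=width, mode="nearest")
    return np.where(np.abs(x - med) > tol, med, x)


def _band_center_fwhm(profile: np.ndarray, peak: int, base: float):
    """Band centre = midpoint of the half-maximum crossings (linear
    interpolation), width = their separation; both in pixels."""
    half = base + (profile[peak] - base) / 2.0
    left = peak
    while left > 0 and profile[left - 1] >= half:
        left -= 1
    if left > 0 and profile[left] != profile[left - 1]:
        x_left = left - (profile[left] - half) / (profile[left] - profile[left - 1])
    else:
        x_left = float(left)
    right = peak
    n = len(profile)
    while right < n - 1 and profile[right + 1] >= half:
        right += 1
    if right < n - 1 and profile[right] != profile[right + 1]:
        x_right = right + (profile[right] - half) / (profile[right] - profile[right + 1])
    else:
        x_right = float(right)
    return (x_left + x_right) / 2.0, x_right - x_left


def outline_walls(
    img: MModeImage,
    smooth_sigma_px: float = 1.5,
    min_gap_mm: float = 0.15,
    despike_px: float = 2.0,
    despike_width: int = 5,
    max_bad_fraction: float = 0.10,
) -> WallTrace:
    """Outline near and far vessel walls in an M-mode image.

    Per time column the two most prominent peaks of the Gaussian-smoothed
    depth profile (separated by at least ``min_gap_mm``) are taken as the
    wall bands; half-maximum crossing midpoints give sub-pixel wall depths
    and the FWHM (corrected for the smoothing kernel) gives wall thickness.
    A temporal despike filter replaces columns deviating more than
    ``despike_px`` pixels from a running median.

    Raises
    ------
    ExtractionError
        If fewer than two bands are found in more than ``max_bad_fraction``
        of columns.
    """
    pitch = img.pixel_pitch_mm
    data = gaussian_filter1d(img.image.astype(float), smooth_sigma_px, axis=0)
    n_depth, n_cols = data.shape
    min_gap_px = max(2, int(round(min_gap_mm / pitch)))

    near = np.full(n_cols, np.nan)
    far = np.full(n_cols, np.nan)
    near_th = np.full(n_cols, np.nan)
    far_th = np.full(n_cols, np.nan)
    for j in range(n_cols):
        profile = data[:, j]
        peaks, props = find_peaks(profile, distance=min_gap_px,
                                  prominence=0.05 * profile.max())
        if len(peaks) < 2:
            continue
        top2 = peaks[np.argsort(props["prominences"])[-2:]]
        top2.sort()
        base = float(np.median(profile))
        c_near, w_near = _band_center_fwhm(profile, int(top2[0]), base)
        c_far, w_far = _band_center_fwhm(profile, int(top2[1]), base)
        near[j], far[j] = (c_near + 0.5) * pitch, (c_far + 0.5) * pitch
        near_th[j], far_th[j] = w_near * pitch, w_far * pitch

    bad = ~np.isfinite(near) | ~np.isfinite(far)
    if bad.mean() > max_bad_fraction:
        raise ExtractionError(
            f"two wall bands detected in only {100 * (1 - bad.mean()):.1f}% of "
            f"columns ({int(bad.sum())}/{n_cols} failed)"
        )
    if bad.any():  # interpolate isolated failures from neighbours
        good = np.flatnonzero(~bad)
        idx = np.arange(n_cols)
        for arr in (near, far, near_th, far_th):
            arr[bad] = np.interp(idx[bad], good, arr[good])

    if despike_px > 0:
        near = _despike(near, despike_px * pitch, despike_width)
        far = _despike(far, despike_px * pitch, despike_width)
        near_th = _despike(near_th, despike_px * pitch, despike_width)
        far_th = _despike(far_th, despike_px * pitch, despike_width)

    # deconvolve the depth-smoothing kernel from the measured FWHM
    blur_fwhm = 2.0 * math.sqrt(2.0 * math.log(2.0)) * smooth_sigma_px * pitch
    for arr in (near_th, far_th):
        np.sqrt(np.maximum(arr**2 - blur_fwhm**2, (pitch) ** 2), out=arr)

    trace = WallTrace(
        t=img.time_axis(),
        near_wall_depth=near,
        far_wall_depth=far,
        near_wall_thickness=near_th,
        far_wall_thickness=far_th,
    )
    trace.validate()
    return trace


def trace_envelope(
    spec: DopplerSpectrogram,
    threshold: float | None = None,
    noise_percentile: float = 99.5,
    min_run_bins: int = 3,
    despike_bins: float = 8.0,
    despike_width: int = 5,
) -> VelocityEnvelope:
    """Trace the maximum-velocity envelope of a Doppler spectrogram.

    Per column the envelope is the upper edge of the highest velocity bin
    that exceeds the threshold as part of a contiguous run of at least
    ``min_run_bins`` bins (isolated noise pixels above the envelope are
    thereby ignored).  When ``threshold`` is None it is estimated as the
    ``noise_percentile`` of the intensities in the top decile of velocity
    bins (assumed signal-free noise floor).  Raising the threshold can only
    lower (never raise) the traced envelope.
    """
    img = spec.image.astype(float)
    n_bins, _ = img.shape
    if threshold is None:
        floor = img[int(0.9 * n_bins):, :]
        threshold = float(np.percentile(floor, noise_percentile)) + 1e-9

    above = img > threshold
    if min_run_bins > 1:
        above = binary_erosion(above, structure=np.ones((min_run_bins, 1), bool))
        offset = (min_run_bins - 1) // 2
    else:
        offset = 0
    any_above = above.any(axis=0)
    top_idx = n_bins - 1 - np.argmax(above[::-1, :], axis=0) + offset
    v = np.where(any_above, (top_idx + 1) * spec.v_bin_mm_s, 0.0)
    if not any_above.any():
        warnings.warn("spectrogram contains no signal above the noise floor")
    if despike_bins > 0:
        v = _despike(v, despike_bins * spec.v_bin_mm_s, despike_width)
    return VelocityEnvelope(t=spec.time_axis(), v_max=np.maximum(v, 0.0))
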