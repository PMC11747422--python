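"""Calibrated image containers for M-mode traces and pulsed-Doppler spectra.

An M-mode image is a depth × time intensity map from a single ultrasound
scan line; the moving vessel walls appear as bright bands.  A Doppler
spectrogram is a velocity × time map whose upper envelope follows the
instantaneous maximum blood velocity in the sample volume.

Both are stored on disk as single-channel TIFF with a JSON sidecar holding
the calibration (pixel pitch, line rate, velocity bin) so that the image
file itself stays a plain raster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


@dataclass
class MModeImage:
    """Depth × time intensity image with spatial/temporal calibration.

    Attributes
    ----------
    image : ndarray, shape (n_depth, n_time)
        Intensity map; depth increases with row index.
    pixel_pitch_mm : float
        Depth extent of one pixel, mm.
    line_rate_hz : float
        Scan lines (columns) per second.
    meta : dict
        Free-form metadata (rendering parameters, warnings).
    """

    image: np.ndarray
    pixel_pitch_mm: float
    line_rate_hz: float
    meta: dict = field(default_factory=dict)

    def depth_axis(self) -> np.ndarray:
        """Depth (mm) of each row centre."""
        return (np.arange(self.image.shape[0]) + 0.5) * self.pixel_pitch_mm

    def time_axis(self) -> np.ndarray:
        """Acquisition time (s) of each column."""
        return np.arange(self.image.shape[1]) / self.line_rate_hz

    def save(self, path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.image.astype(np.float32))
        sidecar = {
            "kind": "mmode",
            "pixel_pitch_mm": self.pixel_pitch_mm,
            "line_rate_hz": self.line_rate_hz,
            "meta": self.meta,
        }
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "MModeImage":
        path = Path(path)
        sidecar = json.loads(_sidecar_path(path).read_text())
        if sidecar.get("kind") != "mmode":
            raise ValueError(f"{path} sidecar does not describe an M-mode image")
        return cls(
            image=tifffile.imread(path),
            pixel_pitch_mm=sidecar["pixel_pitch_mm"],
            line_rate_hz=sidecar["line_rate_hz"],
            meta=sidecar.get("meta", {}),
        )


@dataclass
class DopplerSpectrogram:
    """Velocity × time intensity image (velocity increases with row index)."""

    image: np.ndarray
    v_bin_mm_s: float
    line_rate_hz: float
    meta: dict = field(default_factory=dict)

    def velocity_axis(self) -> np.ndarray:
        """Velocity (mm/s) of each bin centre."""
        return (np.arange(self.image.shape[0]) + 0.5) * self.v_bin_mm_s

    def time_axis(self) -> np.ndarray:
        return np.arange(self.image.shape[1]) / self.line_rate_hz

    def save(self, path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.image.astype(np.float32))
        sidecar = {
            "kind": "doppler",
            "v_bin_mm_s": self.v_bin_mm_s,
            "line_rate_hz": self.line_rate_hz,
            "meta": self.meta,
        }
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "DopplerSpectrogram":
        path = Path(path)
        sidecar = json.loads(_sidecar_path(path).read_text())
        if sidecar.get("kind") != "doppler":
            raise ValueError(f"{path} sidecar does not describe a Doppler spectrogram")
        return cls(
            image=tifffile.imread(path),
            v_bin_mm_s=sidecar["v_bin_mm_s"],
            line_rate_hz=sidecar["line_rate_hz"],
            meta=sidecar.get("meta", {}),
        )
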