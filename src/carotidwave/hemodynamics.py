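"""Derived carotid hemodynamic metrics from an averaged cardiac cycle.

Implements the wave-reflection ultrasound analysis chain:

* flow from area × velocity (instantaneous product);
* pulse wave velocity (PWV) from the flow–area (QA) loop — a line fit over
  the 20–80% band of the systolic upstroke, where the slope dQ/dA of the
  reflection-free forward wave equals the local wave speed;
* linear wave separation of the observed flow into forward and reflected
  components using that PWV;
* reflection coefficient as the magnitude ratio of the first (heart-rate)
  harmonics of the reflected and forward components;
* pulsatility index and Moens–Korteweg Young's modulus.

All waveform arguments are SI (m², m/s, m³/s); :class:`VesselMetrics` and
:func:`analyze_ensemble` report in conventional units (mm, mL/min, m/s,
kPa, beats/min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import units
from .cycle_processing import CycleEnsemble

__all__ = [
    "VesselMetrics",
    "QAFitError",
    "area_from_diameter",
    "flow_waveform",
    "pwv_qa_loop",
    "decompose_waves",
    "reflection_coefficient",
    "pulsatility_index",
    "youngs_modulus",
    "analyze_ensemble",
]

#: blood density used throughout, g/mL
BLOOD_DENSITY_G_ML = 1.05


class QAFitError(RuntimeError):
    """Raised when the QA-loop fit window is degenerate."""


@dataclass
class VesselMetrics:
    """One record of derived metrics for a (mouse, age, side) recording."""

    diameter_mm: float  #: end-diastolic inner diameter
    wall_thickness_mm: float
    heart_rate_bpm: float
    flow_ml_min: float  #: cycle-mean flow
    pulsatility_index: float
    pwv_m_s: float
    reflection_coefficient: float
    youngs_modulus_kpa: float
    side: str = "LCCA"
    qa_diagnostics: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.pwv_m_s <= 0 or self.youngs_modulus_kpa <= 0:
            raise ValueError("PWV and Young's modulus must be positive")
        if self.reflection_coefficient < 0 or self.pulsatility_index < 0:
            raise ValueError("reflection coefficient and PI must be non-negative")
        if not self.qa_diagnostics:
            raise ValueError("QA-fit diagnostics must be populated")

    def to_frame(self) -> pd.DataFrame:
        d = {k: v for k, v in self.__dict__.items() if k != "qa_diagnostics"}
        return pd.DataFrame([d])

    def save(self, path) -> None:
        """One CSV row (units in the column names) plus a JSON sidecar with
        the QA-fit diagnostics."""
        import json
        from pathlib import Path

        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(self.qa_diagnostics, indent=2))


def area_from_diameter(D):
    """Circular cross-section area, π·D²/4 (units follow the input squared)."""
    D = np.asarray(D, dtype=float)
    return np.pi * D**2 / 4.0


def flow_waveform(A: np.ndarray, V: np.ndarray):
    """Instantaneous flow Q(t) = A(t)·V(t) and its cycle mean, SI (m³/s)."""
    A = np.asarray(A, dtype=float)
    V = np.asarray(V, dtype=float)
    Q = A * V
    return Q, float(Q.mean())


def _foot_index(Q: np.ndarray) -> int:
    """Index of the end-diastolic (foot) sample: the minimum preceding the
    systolic peak, searched over the early part of the cycle."""
    i_peak = int(np.argmax(Q))
    hi = max(i_peak, 1)
    return int(np.argmin(Q[:hi + 1]))


def pwv_qa_loop(Q: np.ndarray, A: np.ndarray, lo: float = 0.2, hi: float = 0.8):
    """Pulse wave velocity from the QA loop of one averaged cycle.

    Restricts to the systolic upstroke (foot to peak flow), keeps samples
    where the flow lies between ``lo`` and ``hi`` of the foot-to-peak flow
    excursion, and fits Q on A by ordinary least squares.  The slope,
    with Q in m³/s and A in m², is the PWV in m/s.

    Returns
    -------
    pwv : float
    diagnostics : dict
        ``r_squared``, ``i_foot``, ``i_peak``, ``window`` (sample indices
        used), ``n_window``, ``negative_slope`` flag.
    """
    Q = np.asarray(Q, dtype=float)
    A = np.asarray(A, dtype=float)
    i_foot = _foot_index(Q)
    i_peak = int(np.argmax(Q))
    q0, q1 = Q[i_foot], Q[i_peak]
    if i_peak - i_foot < 3 or q1 <= q0:
        raise QAFitError("no systolic upstroke identifiable in the QA loop")
    rel = (Q[i_foot:i_peak + 1] - q0) / (q1 - q0)
    window = np.flatnonzero((rel >= lo) & (rel <= hi)) + i_foot
    if len(window) < 4:
        raise QAFitError(
            f"only {len(window)} samples in the {lo:.0%}–{hi:.0%} systolic band"
        )
    slope, intercept = np.polyfit(A[window], Q[window], 1)
    resid = Q[window] - (slope * A[window] + intercept)
    ss_tot = float(np.sum((Q[window] - Q[window].mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    diag = {
        "r_squared": r2,
        "i_foot": i_foot,
        "i_peak": i_peak,
        "window": (int(window[0]), int(window[-1])),
        "n_window": int(len(window)),
        "negative_slope": bool(slope < 0),
    }
    return float(slope), diag


def decompose_waves(Q: np.ndarray, A: np.ndarray, pwv: float):
    """Separate the observed flow into forward and reflected components.

    Perturbations are taken about the end-diastolic (foot) baseline:
    ``q = Q − Q_dia``, ``a = A − A_dia``; then

        Q_f = Q_dia + (q + c·a)/2,    Q_r = (q − c·a)/2

    so ``Q_f + Q_r = Q`` pointwise by construction.
    """
    Q = np.asarray(Q, dtype=float)
    A = np.asarray(A, dtype=float)
    i0 = _foot_index(Q)
    q = Q - Q[i0]
    a = A - A[i0]
    Q_f = Q[i0] + (q + pwv * a) / 2.0
    Q_r = (q - pwv * a) / 2.0
    return Q_f, Q_r


def _first_harmonic(x: np.ndarray) -> complex:
    """Complex Fourier coefficient at the fundamental of one cycle."""
    return complex(np.fft.rfft(np.asarray(x, dtype=float))[1])


def reflection_coefficient(Q_f: np.ndarray, Q_r: np.ndarray,
                           min_forward_harmonic: float = 1e-15):
    """|first harmonic of Q_r| / |first harmonic of Q_f| on one mean cycle.

    The cycle is treated as exactly one period (fundamental = heart rate),
    with no windowing; a constant baseline does not contribute.  Raises if
    the forward first harmonic is below tolerance (relative to the forward
    amplitude), where the ratio is undefined.
    """
    h_f = abs(_first_harmonic(Q_f))
    h_r = abs(_first_harmonic(Q_r))
    scale = float(np.max(np.abs(Q_f))) * len(np.asarray(Q_f)) + 1e-300
    if h_f < min_forward_harmonic * scale:
        raise ValueError("forward first harmonic below tolerance; RC undefined")
    return h_r / h_f


def pulsatility_index(V: np.ndarray, v_ed: float | None = None) -> float:
    """(peak systolic − end diastolic) / cycle-mean velocity.

    ``v_ed`` defaults to the velocity at the cycle foot (the minimum before
    the systolic peak of an averaged, foot-aligned cycle).
    """
    V = np.asarray(V, dtype=float)
    if v_ed is None:
        v_ed = float(V[_foot_index(V)])
    v_mean = float(V.mean())
    if v_mean == 0:
        raise ValueError("mean velocity is zero; PI undefined")
    return (float(V.max()) - v_ed) / v_mean


def youngs_modulus(pwv: float, D_dia: float, h: float,
                   rho: float = units.gml_to_kgm3(BLOOD_DENSITY_G_ML)) -> float:
    """Moens–Korteweg Young's modulus, Pa: E = c²·ρ·D/h.

    Uses the inner (lumen) end-diastolic diameter and the thin-wall form.
    ``pwv`` in m/s, ``D_dia`` and ``h`` in m, ``rho`` in kg/m³.
    """
    if D_dia <= 0 or h <= 0 or rho <= 0:
        raise ValueError("diameter, wall thickness and density must be positive")
    return pwv**2 * rho * D_dia / h


def analyze_ensemble(
    ens: CycleEnsemble,
    wall_thickness_mm: float,
    side: str = "LCCA",
    rho_g_ml: float = BLOOD_DENSITY_G_ML,
) -> VesselMetrics:
    """Full metric chain on an averaged cycle (needs ``A`` [m²], ``V`` [m/s])."""
    A = ens.mean_cycle["A"]
    V = ens.mean_cycle["V"]
    Q, mean_q = flow_waveform(A, V)
    pwv, diag = pwv_qa_loop(Q, A)
    Q_f, Q_r = decompose_waves(Q, A, pwv)
    rc = reflection_coefficient(Q_f, Q_r)
    pi = pulsatility_index(V)

    i0 = _foot_index(Q)
    D_dia_m = math.sqrt(4.0 * float(A[i0]) / math.pi)
    rho = units.gml_to_kgm3(rho_g_ml)
    E = youngs_modulus(pwv, D_dia_m, units.mm_to_m(wall_thickness_mm), rho)

    metrics = VesselMetrics(
        diameter_mm=units.m_to_mm(D_dia_m),
        wall_thickness_mm=wall_thickness_mm,
        heart_rate_bpm=ens.heart_rate,
        flow_ml_min=units.m3s_to_mlmin(mean_q),
        pulsatility_index=pi,
        pwv_m_s=pwv,
        reflection_coefficient=rc,
        youngs_modulus_kpa=units.pa_to_kpa(E),
        side=side,
        qa_diagnostics=diag,
    )
    metrics.validate()
    return metrics
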