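"""Synthetic carotid hemodynamics with known ground truth.

This module generates everything the analysis pipeline consumes, from first
principles it controls:

* single-cycle forward flow pulses (raised-cosine upstroke, exponential
  decay) on a diastolic baseline;
* multi-cycle flow/area/velocity waveforms obeying linear wave mechanics —
  a forward wave, a delayed and scaled reflected wave, and an area
  perturbation coupled to them through the pulse wave velocity, so the
  early-systolic flow–area (QA) slope equals the planted wave speed by
  construction;
* rendered M-mode images (two bright wall bands tracking the diameter
  waveform) and pulsed-Doppler spectrograms (filled envelope at twice the
  mean velocity, the parabolic-profile convention);
* longitudinal cohorts of control and *dcr* (decrepit, Mrpl3-mutant)
  mice with planted genotype × sex × age effects, between-mouse
  heterogeneity and residual measurement noise.

All randomness is seeded; identical seeds give identical arrays.

Wave conventions
----------------
The diastolic baseline flow is treated as purely forward.  The reflected
wave is a delayed, scaled copy of the *pulsatile* forward perturbation
with flow sign inverted (a reflection opposes forward flow) while its area
contribution adds — a reflected wave raises area per unit net flow:

    Q_f(t) = Q_dia + p(t)
    Q_r(t) = -gamma * p(t - tau)
    A(t)   = A_dia + (p(t) + gamma * p(t - tau)) / c

with ``p`` the pulsatile forward flow (m³/s), ``gamma`` the reflection
magnitude, ``tau`` the reflection delay and ``c`` the pulse wave velocity.
With ``gamma = 0`` this gives ``Q - Q_dia = c * (A - A_dia)`` exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import units
from .images import DopplerSpectrogram, MModeImage

__all__ = [
    "HemoTruth",
    "WaveformPair",
    "CohortSpec",
    "make_forward_pulse",
    "synthesize_waveforms",
    "render_mmode",
    "render_doppler",
    "simulate_cohort",
    "hemotruth_for_row",
    "write_waveforms",
    "read_waveforms",
]


# --------------------------------------------------------------------------
# ground-truth parameter containers
# --------------------------------------------------------------------------


@dataclass
class HemoTruth:
    """Ground-truth hemodynamic parameters for one synthetic recording.

    Parameters are given in conventional reporting units; synthesis
    converts to SI internally.
    """

    c_true: float = 3.0  #: pulse wave velocity, m/s
    gamma_true: float = 0.3  #: reflection coefficient magnitude, in [0, 1)
    tau: float = 0.02  #: reflection delay, s
    D_dia: float = 0.5  #: end-diastolic inner diameter, mm
    h_true: float = 0.05  #: wall thickness, mm
    HR_true: float = 450.0  #: heart rate, beats/min
    q_baseline: float = 0.35  #: diastolic forward flow, mL/min
    q_amplitude: float = 1.8  #: systolic forward pulse amplitude, mL/min
    t_rise: float = 0.015  #: systolic upstroke duration, s
    t_decay: float = 0.025  #: post-peak exponential decay constant, s
    rho: float = 1.05  #: blood density, g/mL
    noise_sd: float = 0.0  #: additive noise, fraction of pulsatile amplitude
    seed: int = 0  #: RNG seed

    @property
    def A_dia(self) -> float:
        """End-diastolic lumen area, mm² (circular cross-section)."""
        return math.pi * self.D_dia**2 / 4.0

    @property
    def period(self) -> float:
        """Cardiac period, s."""
        return 60.0 / self.HR_true

    def validate(self) -> None:
        if not self.c_true > 0:
            raise ValueError("pulse wave velocity must be positive")
        if not (0.0 <= self.gamma_true < 1.0):
            raise ValueError("reflection coefficient must lie in [0, 1)")
        if not self.tau > 0:
            raise ValueError("reflection delay must be positive")
        if not self.HR_true > 0:
            raise ValueError("heart rate must be positive")
        if self.D_dia <= 0 or self.h_true <= 0:
            raise ValueError("diameter and wall thickness must be positive")
        T = self.period
        if self.t_rise + self.t_decay >= T:
            raise ValueError(
                f"rise ({self.t_rise} s) + decay ({self.t_decay} s) exceed "
                f"the cardiac period ({T:.4f} s)"
            )
        if self.t_rise > 0.4 * T:
            raise ValueError("systolic peak would fall beyond 40% of the cycle")


@dataclass
class WaveformPair:
    """Time-aligned flow/area/velocity waveforms, SI units throughout.

    ``Q = Q_f + Q_r`` holds pointwise before noise injection; with noise the
    measured channels are ``A`` and ``V`` and ``Q = A·V`` while ``Q_f``/``Q_r``
    stay the noiseless ground truth.
    """

    t: np.ndarray  #: time, s (uniform step)
    Q: np.ndarray  #: net flow, m³/s
    A: np.ndarray  #: lumen area, m²
    V: np.ndarray  #: lumen-mean velocity, m/s
    Q_f: np.ndarray  #: forward flow component, m³/s
    Q_r: np.ndarray  #: reflected flow component, m³/s

    @property
    def fs(self) -> float:
        """Sampling rate, Hz."""
        return 1.0 / (self.t[1] - self.t[0])

    def validate(self) -> None:
        n = len(self.t)
        for name in ("Q", "A", "V", "Q_f", "Q_r"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array length mismatch for {name}")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.A < 0):
            raise ValueError("lumen area must be non-negative")


# --------------------------------------------------------------------------
# waveform synthesis
# --------------------------------------------------------------------------


def _pulse_kernel(u: np.ndarray, amp: float, t_rise: float, t_decay: float) -> np.ndarray:
    """Single systolic pulse: raised-cosine upstroke then exponential decay.

    Zero for ``u < 0``; peaks at ``u = t_rise`` with value ``amp``.
    """
    out = np.zeros_like(u, dtype=float)
    rising = (u >= 0) & (u < t_rise)
    out[rising] = amp * 0.5 * (1.0 - np.cos(np.pi * u[rising] / t_rise))
    decaying = u >= t_rise
    out[decaying] = amp * np.exp(-(u[decaying] - t_rise) / t_decay)
    return out


def make_forward_pulse(truth: HemoTruth, fs: float = 2000.0):
    """One cycle of the forward flow waveform (baseline + systolic pulse).

    Returns
    -------
    t : ndarray
        Time within the cycle, s, ``[0, period)``.
    q : ndarray
        Forward flow, m³/s.
    """
    truth.validate()
    T = truth.period
    t = np.arange(0.0, T, 1.0 / fs)
    q = units.mlmin_to_m3s(truth.q_baseline) + _pulse_kernel(
        t, units.mlmin_to_m3s(truth.q_amplitude), truth.t_rise, truth.t_decay
    )
    return t, q


def _cycle_starts(truth: HemoTruth, n_cycles: int, rr_jitter: float, rng) -> np.ndarray:
    """Cycle onset times; RR jitter (if any) is heavy-tailed (Student-t, df=3)."""
    T = truth.period
    if rr_jitter > 0:
        jit = rng.standard_t(df=3, size=n_cycles) * rr_jitter
        rr = np.clip(T * (1.0 + jit), 0.5 * T, 2.0 * T)
    else:
        rr = np.full(n_cycles, T)
    starts = np.concatenate([[0.0], np.cumsum(rr)])
    return starts  # length n_cycles + 1; last entry is the record end


def _superpose_pulses(t, starts, amp, t_rise, t_decay, delay=0.0):
    """Sum of pulse kernels placed at each cycle onset (plus ``delay``)."""
    out = np.zeros_like(t)
    cap = t_rise + 12.0 * t_decay
    for s in starts:
        u = t - s - delay
        m = (u >= 0) & (u < cap)
        if m.any():
            out[m] += _pulse_kernel(u[m], amp, t_rise, t_decay)
    return out


def synthesize_waveforms(
    truth: HemoTruth,
    n_cycles: int = 10,
    fs: float = 2000.0,
    rr_jitter: float = 0.0,
) -> WaveformPair:
    """Synthesize a multi-cycle flow/area/velocity recording.

    Parameters
    ----------
    truth : HemoTruth
        Planted parameters (converted to SI internally).
    n_cycles : int
        Number of cardiac cycles, at least 3.
    fs : float
        Sampling rate, Hz.
    rr_jitter : float
        Scale of heavy-tailed per-cycle RR jitter as a fraction of the
        period (0 disables; ~0.15 produces occasional arrhythmic cycles).
    """
    truth.validate()
    if n_cycles < 3:
        raise ValueError("need at least 3 cardiac cycles")
    rng = np.random.default_rng(truth.seed)

    T = truth.period
    starts = _cycle_starts(truth, n_cycles, rr_jitter, rng)
    t = np.arange(0.0, starts[-1], 1.0 / fs)
    # two virtual preceding cycles put the record start in steady state
    all_starts = np.concatenate([[-2.0 * T, -T], starts[:-1]])

    amp = units.mlmin_to_m3s(truth.q_amplitude)
    q_base = units.mlmin_to_m3s(truth.q_baseline)
    p_fwd = _superpose_pulses(t, all_starts, amp, truth.t_rise, truth.t_decay)
    p_del = _superpose_pulses(t, all_starts, amp, truth.t_rise, truth.t_decay, delay=truth.tau)

    Q_f = q_base + p_fwd
    Q_r = -truth.gamma_true * p_del
    Q = Q_f + Q_r
    a = (p_fwd + truth.gamma_true * p_del) / truth.c_true  # m²
    A = units.mm2_to_m2(truth.A_dia) + a
    V = Q / A

    if truth.noise_sd > 0:
        sd_A = truth.noise_sd * float(a.max() - a.min())
        sd_V = truth.noise_sd * float(V.max() - V.min())
        A = A + rng.normal(0.0, sd_A, size=A.shape)
        V = V + rng.normal(0.0, sd_V, size=V.shape)
        A = np.maximum(A, 0.05 * units.mm2_to_m2(truth.A_dia))
        Q = A * V

    wf = WaveformPair(t=t, Q=Q, A=A, V=V, Q_f=Q_f, Q_r=Q_r)
    wf.validate()
    return wf


# --------------------------------------------------------------------------
# image rendering
# --------------------------------------------------------------------------


def render_mmode(
    truth: HemoTruth,
    waveforms: WaveformPair,
    pixel_pitch_mm: float = 0.01,
    line_rate_hz: float | None = None,
    center_depth_mm: float = 2.0,
    depth_mm: float | None = None,
    wall_amp: float = 1.0,
    background: float = 0.05,
    speckle_weight: float = 0.5,
    seed: int | None = None,
) -> MModeImage:
    """Render an M-mode image with two bright wall bands.

    Band centres sit on the lumen boundary (near wall at
    ``center − D/2``, far wall at ``center + D/2``) so the centre-to-centre
    separation equals the inner diameter ``D(t) = sqrt(4·A(t)/π)``.  Each
    band has a Gaussian depth profile of FWHM equal to the wall thickness.
    Speckle is multiplicative Rayleigh noise blended with weight
    ``speckle_weight`` (0 = noiseless).
    """
    rng = np.random.default_rng(truth.seed + 101 if seed is None else seed)
    D_mm = units.m_to_mm(np.sqrt(4.0 * waveforms.A / np.pi))

    if line_rate_hz is None or np.isclose(line_rate_hz, waveforms.fs):
        line_rate_hz = waveforms.fs
        t_cols, D_cols = waveforms.t, D_mm
    else:
        t_cols = np.arange(0.0, waveforms.t[-1], 1.0 / line_rate_hz)
        D_cols = np.interp(t_cols, waveforms.t, D_mm)

    near = center_depth_mm - D_cols / 2.0
    far = center_depth_mm + D_cols / 2.0
    if depth_mm is None:
        depth_mm = center_depth_mm + D_cols.max()  # symmetric margin below far wall
    z = (np.arange(int(round(depth_mm / pixel_pitch_mm))) + 0.5) * pixel_pitch_mm

    sigma = truth.h_true / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    img = background + wall_amp * (
        np.exp(-0.5 * ((z[:, None] - near[None, :]) / sigma) ** 2)
        + np.exp(-0.5 * ((z[:, None] - far[None, :]) / sigma) ** 2)
    )
    meta: dict = {
        "center_depth_mm": center_depth_mm,
        "wall_thickness_mm": truth.h_true,
        "warnings": [],
    }
    if truth.h_true < 2.0 * pixel_pitch_mm:
        meta["warnings"].append(
            f"pixel pitch {pixel_pitch_mm} mm too coarse to resolve "
            f"wall thickness {truth.h_true} mm"
        )
    if speckle_weight > 0:
        ray = rng.rayleigh(scale=math.sqrt(2.0 / math.pi), size=img.shape)  # mean 1
        img = img * ((1.0 - speckle_weight) + speckle_weight * ray)
    return MModeImage(
        image=img.astype(np.float32),
        pixel_pitch_mm=pixel_pitch_mm,
        line_rate_hz=float(line_rate_hz),
        meta=meta,
    )


def render_doppler(
    waveforms: WaveformPair,
    v_bin_mm_s: float = 2.0,
    line_rate_hz: float | None = None,
    v_range_mm_s: float | None = None,
    noise_floor: float = 0.0,
    speckle_weight: float = 0.0,
    seed: int = 0,
) -> DopplerSpectrogram:
    """Render a pulsed-Doppler spectrogram.

    Each column is filled from zero velocity up to the instantaneous maximum
    velocity ``V_max(t) = 2·V(t)`` — the parabolic flow-profile convention
    whose inverse is the envelope-halving rule used in analysis.  A bin is
    filled when its centre lies at or below ``V_max``.
    """
    rng = np.random.default_rng(seed)
    v_max = 2.0 * units.ms_to_mms(waveforms.V)

    if line_rate_hz is None or np.isclose(line_rate_hz, waveforms.fs):
        line_rate_hz = waveforms.fs
        v_cols = v_max
    else:
        t_cols = np.arange(0.0, waveforms.t[-1], 1.0 / line_rate_hz)
        v_cols = np.interp(t_cols, waveforms.t, v_max)

    if v_range_mm_s is None:
        v_range_mm_s = 1.3 * float(v_cols.max()) + 5.0 * v_bin_mm_s
    n_bins = int(math.ceil(v_range_mm_s / v_bin_mm_s))
    centers = (np.arange(n_bins) + 0.5) * v_bin_mm_s

    img = (centers[:, None] <= v_cols[None, :]).astype(float)
    if speckle_weight > 0:
        ray = rng.rayleigh(scale=math.sqrt(2.0 / math.pi), size=img.shape)
        img = img * ((1.0 - speckle_weight) + speckle_weight * ray)
    if noise_floor > 0:
        img = img + np.abs(rng.normal(0.0, noise_floor, size=img.shape))
    return DopplerSpectrogram(
        image=img.astype(np.float32),
        v_bin_mm_s=v_bin_mm_s,
        line_rate_hz=float(line_rate_hz),
        meta={},
    )


# --------------------------------------------------------------------------
# waveform CSV I/O (SI units; sidecar JSON records them)
# --------------------------------------------------------------------------

_WF_COLUMNS = ("t", "Q", "A", "V", "Q_f", "Q_r")
_WF_UNITS = {"t": "s", "Q": "m3/s", "A": "m2", "V": "m/s", "Q_f": "m3/s", "Q_r": "m3/s"}


def write_waveforms(wf: WaveformPair, path) -> None:
    """Write a WaveformPair as CSV plus a JSON sidecar noting SI units."""
    path = Path(path)
    df = pd.DataFrame({c: getattr(wf, c) for c in _WF_COLUMNS})
    df.to_csv(path, index=False)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"units": _WF_UNITS}, indent=2)
    )


def read_waveforms(path) -> WaveformPair:
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(_WF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"waveform CSV {path} missing columns {sorted(missing)}")
    wf = WaveformPair(**{c: df[c].to_numpy() for c in _WF_COLUMNS})
    wf.validate()
    return wf


# --------------------------------------------------------------------------
# longitudinal cohort simulation
# --------------------------------------------------------------------------

#: metrics the cohort simulator draws directly (Young's modulus is derived)
COHORT_METRICS = (
    "diameter_mm",
    "wall_thickness_mm",
    "heart_rate_bpm",
    "flow_ml_min",
    "pulsatility_index",
    "pwv_m_s",
    "reflection_coefficient",
)

#: control-female-LCCA values at the first imaging age
DEFAULT_BASELINES = {
    "diameter_mm": 0.39,
    "wall_thickness_mm": 0.045,
    "heart_rate_bpm": 450.0,
    "flow_ml_min": 0.55,
    "pulsatility_index": 1.8,
    "pwv_m_s": 3.0,
    "reflection_coefficient": 0.35,
}

#: common growth/maturation slope, fractional change per day past day 50
DEFAULT_AGE_SLOPES = {
    "diameter_mm": 0.0008,
    "wall_thickness_mm": 0.0004,
    "heart_rate_bpm": 0.0,
    "flow_ml_min": 0.002,
    "pulsatility_index": 0.0,
    "pwv_m_s": 0.0011,
    "reflection_coefficient": 0.0,
}

#: RCCA / LCCA multiplicative asymmetry (right side larger)
DEFAULT_SIDE_RATIO = {
    "diameter_mm": 1.04,
    "wall_thickness_mm": 1.0,
    "heart_rate_bpm": 1.0,
    "flow_ml_min": 1.12,
    "pulsatility_index": 1.0,
    "pwv_m_s": 1.0,
    "reflection_coefficient": 1.0,
}

#: fractional dcr effect by metric → sex → {age_days: effect}; linearly
#: interpolated in age between anchors.  Directions and magnitudes follow the
#: reported sex-specific disease course (e.g. early flow deficit in females,
#: early dilation and PWV drop in males, late female PWV/reflection rise).
DEFAULT_DCR_EFFECTS = {
    "diameter_mm": {
        "M": {50: 0.12, 75: 0.06, 125: 0.0},
        "F": {50: 0.0, 75: 0.07, 125: 0.15},
    },
    "flow_ml_min": {
        "F": {50: -0.25, 75: 0.0, 125: 0.10},
        "M": {50: 0.0, 75: -0.05, 125: -0.10},
    },
    "heart_rate_bpm": {
        "F": {50: -0.29, 75: -0.15, 125: 0.0},
        "M": {50: 0.0, 75: -0.08, 125: -0.15},
    },
    "pwv_m_s": {
        "M": {50: -0.22, 75: -0.26, 125: -0.30},
        "F": {50: 0.0, 75: 0.10, 125: 0.21},
    },
    "pulsatility_index": {
        "F": {50: 0.20, 75: 0.20, 125: 0.20},
        "M": {50: 0.0, 75: 0.15, 125: 0.15},
    },
    "reflection_coefficient": {
        "F": {50: 0.0, 75: 0.05, 125: 0.15},
        "M": {50: 0.0, 75: 0.0, 125: 0.0},
    },
    "wall_thickness_mm": {
        "F": {50: 0.08, 75: 0.08, 125: 0.08},
        "M": {50: 0.08, 75: 0.08, 125: 0.08},
    },
}

#: lognormal sigma of the per-mouse random intercept, by metric
DEFAULT_BETWEEN_SD = {
    "diameter_mm": 0.04,
    "wall_thickness_mm": 0.06,
    "heart_rate_bpm": 0.05,
    "flow_ml_min": 0.10,
    "pulsatility_index": 0.10,
    "pwv_m_s": 0.08,
    "reflection_coefficient": 0.10,
}

#: lognormal sigma of the residual per (age, side) observation, by metric
DEFAULT_RESID_SD = {
    "diameter_mm": 0.03,
    "wall_thickness_mm": 0.05,
    "heart_rate_bpm": 0.04,
    "flow_ml_min": 0.08,
    "pulsatility_index": 0.08,
    "pwv_m_s": 0.07,
    "reflection_coefficient": 0.10,
}


@dataclass
class CohortSpec:
    """Design of a simulated longitudinal imaging cohort.

    ``effects`` plants multiplicative dcr-vs-control offsets per metric, sex
    and age; ``between_sd``/``resid_sd`` are lognormal sigmas for mouse-level
    and observation-level variation.  ``dropout`` removes two male dcr mice
    at the final age (pre-endpoint death); ``arrhythmia_fraction`` flags a
    fraction of mice whose recordings get heavy-tailed RR jitter when the
    cohort is rendered at waveform level.
    """

    n_per_group: int = 6
    ages: tuple = (50, 75, 125)
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    age_slopes: dict = field(default_factory=lambda: dict(DEFAULT_AGE_SLOPES))
    side_ratio: dict = field(default_factory=lambda: dict(DEFAULT_SIDE_RATIO))
    effects: dict = field(default_factory=lambda: {
        m: {s: dict(v) for s, v in d.items()} for m, d in DEFAULT_DCR_EFFECTS.items()
    })
    between_sd: dict = field(default_factory=lambda: dict(DEFAULT_BETWEEN_SD))
    resid_sd: dict = field(default_factory=lambda: dict(DEFAULT_RESID_SD))
    dropout: bool = False
    arrhythmia_fraction: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 mice per genotype × sex cell")
        if list(self.ages) != sorted(set(self.ages)):
            raise ValueError("ages must be strictly increasing")
        for d in (self.between_sd, self.resid_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("standard deviations must be non-negative")


def _effect_at(spec: CohortSpec, metric: str, sex: str, age: float) -> float:
    anchors = spec.effects.get(metric, {}).get(sex)
    if not anchors:
        return 0.0
    xs = np.array(sorted(anchors))
    ys = np.array([anchors[x] for x in xs])
    return float(np.interp(age, xs, ys))


def simulate_cohort(spec: CohortSpec):
    """Simulate a longitudinal cohort at the metric level.

    Each metric value is a product of: baseline, common age trajectory,
    side asymmetry (RCCA larger), planted dcr effect (by sex and age),
    a lognormal per-mouse intercept, and lognormal residual noise.

    Returns
    -------
    table : DataFrame
        Long format; columns ``mouse_id, genotype, sex, age_days, side,
        arrhythmic`` plus the metric columns (units in the names) and the
        derived ``youngs_modulus_kpa``.
    truth_log : DataFrame
        One row per mouse: the planted lognormal intercepts per metric and
        the arrhythmia / dropout flags.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rho_si = units.gml_to_kgm3(1.05)

    mice = []
    for genotype in ("control", "dcr"):
        for sex in ("F", "M"):
            for i in range(spec.n_per_group):
                mice.append({
                    "mouse_id": f"{genotype[:3]}_{sex}{i:02d}",
                    "genotype": genotype,
                    "sex": sex,
                })
    for m in mice:
        m["arrhythmic"] = bool(rng.random() < spec.arrhythmia_fraction)
        for metric in COHORT_METRICS:
            m[f"b_{metric}"] = float(rng.normal(0.0, spec.between_sd.get(metric, 0.0)))
        m["dropout"] = False
    if spec.dropout:
        male_dcr = [m for m in mice if m["genotype"] == "dcr" and m["sex"] == "M"]
        for m in male_dcr[: min(2, len(male_dcr))]:
            m["dropout"] = True

    rows = []
    last_age = spec.ages[-1]
    for m in mice:
        for age in spec.ages:
            if m["dropout"] and age == last_age:
                continue
            for side in ("LCCA", "RCCA"):
                row = {
                    "mouse_id": m["mouse_id"],
                    "genotype": m["genotype"],
                    "sex": m["sex"],
                    "age_days": age,
                    "side": side,
                    "arrhythmic": m["arrhythmic"],
                }
                for metric in COHORT_METRICS:
                    value = spec.baselines[metric]
                    value *= 1.0 + spec.age_slopes.get(metric, 0.0) * (age - spec.ages[0])
                    if side == "RCCA":
                        value *= spec.side_ratio.get(metric, 1.0)
                    if m["genotype"] == "dcr":
                        value *= 1.0 + _effect_at(spec, metric, m["sex"], age)
                    value *= math.exp(m[f"b_{metric}"])
                    resid = spec.resid_sd.get(metric, 0.0)
                    if resid > 0:
                        value *= math.exp(rng.normal(0.0, resid))
                    row[metric] = value
                # Moens–Korteweg: E = c²·ρ·D/h, reported in kPa
                row["youngs_modulus_kpa"] = units.pa_to_kpa(
                    row["pwv_m_s"] ** 2
                    * rho_si
                    * units.mm_to_m(row["diameter_mm"])
                    / units.mm_to_m(row["wall_thickness_mm"])
                )
                rows.append(row)

    table = pd.DataFrame(rows)
    truth_log = pd.DataFrame(mice)
    return table, truth_log


def hemotruth_for_row(
    row,
    base: HemoTruth | None = None,
    seed: int = 0,
) -> HemoTruth:
    """Map one cohort-table row to waveform-level ground truth.

    Pulse wave velocity, diameter, wall thickness, heart rate and reflection
    coefficient transfer directly; the forward-pulse amplitude and baseline
    are rescaled together so the analytic cycle-mean flow of the synthesized
    waveform equals the row's ``flow_ml_min``.  The pulsatility index is
    emergent rather than planted.
    """
    if base is None:
        base = HemoTruth()
    truth = replace(
        base,
        c_true=float(row["pwv_m_s"]),
        gamma_true=min(float(row["reflection_coefficient"]), 0.95),
        D_dia=float(row["diameter_mm"]),
        h_true=float(row["wall_thickness_mm"]),
        HR_true=float(row["heart_rate_bpm"]),
        seed=seed,
    )
    # analytic mean of one forward-pulse cycle at unit scaling
    T = truth.period
    pulse_int = truth.q_amplitude * (
        0.5 * truth.t_rise
        + truth.t_decay * (1.0 - math.exp(-(T - truth.t_rise) / truth.t_decay))
    )
    mean_unit = truth.q_baseline + (1.0 - truth.gamma_true) * pulse_int / T
    scale = float(row["flow_ml_min"]) / mean_unit
    return replace(
        truth,
        q_baseline=truth.q_baseline * scale,
        q_amplitude=truth.q_amplitude * scale,
    )
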