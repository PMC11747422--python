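"""Reproducible orchestration: simulate → extract → analyze → stats → figures.

A run is driven by a :class:`RunConfig` (YAML-serialisable).  Every
stochastic stage derives its seed deterministically from the global seed
and the stage (or recording) name, so identical config + seed reproduces
byte-identical metric CSVs.  Each run writes a JSON manifest recording the
config, its hash, the package version, the stages executed and every
artifact produced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, units
from .cohort_stats import day50_biomarker_screen, fit_lmm
from .cycle_processing import (CycleDetectionError, detect_systole_feet,
                               ensemble_average)
from .hemodynamics import QAFitError, analyze_ensemble, area_from_diameter
from .synthwave import (CohortSpec, HemoTruth, hemotruth_for_row,
                        read_waveforms, render_doppler, render_mmode,
                        simulate_cohort, synthesize_waveforms, write_waveforms)
from .trace_extraction import (ExtractionError, outline_walls, trace_envelope)

__all__ = [
    "RunConfig",
    "ConfigError",
    "StageError",
    "run_pipeline",
    "analyze_waveform_dir",
    "stage_seed",
    "read_metrics",
]

log = logging.getLogger("carotidwave")

STAGE_ORDER = ("simulate", "extract", "analyze", "stats", "figures")

#: metric columns that are legitimately dimensionless
DIMENSIONLESS_METRICS = {"pulsatility_index", "reflection_coefficient",
                         "qa_r_squared", "n_cycles_used", "n_cycles_rejected"}
UNIT_SUFFIXES = ("_mm", "_ml_min", "_m_s", "_kpa", "_bpm", "_mm2", "_mm_s", "_s")
ID_COLUMNS = {"mouse_id", "genotype", "sex", "age_days", "side", "arrhythmic"}


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


def stage_seed(global_seed: int, name: str) -> int:
    """Deterministic per-stage / per-recording seed below 2³¹."""
    return (int(global_seed) * 1000003 + zlib.crc32(name.encode())) % (2**31)


@dataclass
class RunConfig:
    """Full configuration of a pipeline run (one block per stage)."""

    seed: int = 0
    outdir: str = "runs/demo"
    log_level: str = "INFO"
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "extract": True, "analyze": True,
        "stats": True, "figures": True,
    })
    cohort: dict = field(default_factory=dict)  #: CohortSpec kwargs
    waveform: dict = field(default_factory=lambda: {
        "n_cycles": 10, "fs": 1000.0, "noise_sd": 0.02,
        "arrhythmia_jitter": 0.15, "save_waveforms": False,
    })
    render: dict = field(default_factory=lambda: {
        "pixel_pitch_mm": 0.01, "v_bin_mm_s": 2.0, "speckle_weight": 0.5,
        "noise_floor": 0.05, "save_images": False,
    })
    extraction: dict = field(default_factory=dict)  #: outline/trace kwargs
    cycles: dict = field(default_factory=lambda: {
        "n_samples": 256, "max_rr_deviation": 0.2,
    })
    stats: dict = field(default_factory=lambda: {
        "alpha": 0.05, "stratified": False,
    })

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        base = cls()
        merged = {}
        for f in dataclasses.fields(cls):
            default = getattr(base, f.name)
            if f.name in d:
                value = d[f.name]
                if isinstance(default, dict):
                    if not isinstance(value, dict):
                        raise ConfigError(f"config block {f.name!r} must be a mapping")
                    merged[f.name] = {**default, **value}
                else:
                    merged[f.name] = value
            else:
                merged[f.name] = default
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse YAML config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a YAML mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def sha256(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


def read_metrics(path) -> pd.DataFrame:
    """Read a vessel-metrics CSV, refusing unitless metric columns."""
    df = pd.read_csv(path)
    for col in df.columns:
        if col in ID_COLUMNS or col in DIMENSIONLESS_METRICS:
            continue
        if not col.endswith(UNIT_SUFFIXES):
            raise ConfigError(
                f"metric column {col!r} in {path} carries no unit suffix; "
                f"expected one of {UNIT_SUFFIXES} or a known dimensionless name"
            )
    return df


# --------------------------------------------------------------------------
# per-recording processing
# --------------------------------------------------------------------------


def _recording_id(row) -> str:
    return f"{row['mouse_id']}_d{int(row['age_days'])}_{row['side']}"


def _extract_recording(truth: HemoTruth, wf, cfg: RunConfig, rec_id: str,
                       outdir: Path | None):
    """Render M-mode + Doppler and recover (t, A[m²], V[m/s], thickness)."""
    r = cfg.render
    mmode = render_mmode(
        truth, wf,
        pixel_pitch_mm=r["pixel_pitch_mm"],
        speckle_weight=r["speckle_weight"],
        seed=stage_seed(cfg.seed, rec_id + ":mmode"),
    )
    doppler = render_doppler(
        wf,
        v_bin_mm_s=r["v_bin_mm_s"],
        noise_floor=r["noise_floor"],
        speckle_weight=r["speckle_weight"],
        seed=stage_seed(cfg.seed, rec_id + ":doppler"),
    )
    if r.get("save_images") and outdir is not None:
        imgdir = outdir / "images"
        imgdir.mkdir(exist_ok=True)
        mmode.save(imgdir / f"{rec_id}_mmode.tif")
        doppler.save(imgdir / f"{rec_id}_doppler.tif")

    walls = outline_walls(mmode, **cfg.extraction.get("walls", {}))
    env = trace_envelope(doppler, **cfg.extraction.get("envelope", {}))
    A = units.mm2_to_m2(area_from_diameter(walls.diameter))
    V = units.mms_to_ms(env.v_mean)
    thickness = float(np.median((walls.near_wall_thickness
                                 + walls.far_wall_thickness) / 2.0))
    return walls.t, A, V, thickness


def _analyze_recording(t, A, V, thickness_mm, side, cycles_cfg):
    feet = detect_systole_feet(t, V)
    ens = ensemble_average(
        t, {"A": A, "V": V}, feet,
        n_samples=cycles_cfg.get("n_samples", 256),
        max_rr_deviation=cycles_cfg.get("max_rr_deviation", 0.2),
    )
    metrics = analyze_ensemble(ens, wall_thickness_mm=thickness_mm, side=side)
    return metrics, ens


def _metrics_row(row, metrics, ens) -> dict:
    return {
        "mouse_id": row["mouse_id"],
        "genotype": row["genotype"],
        "sex": row["sex"],
        "age_days": row["age_days"],
        "side": row["side"],
        "arrhythmic": row.get("arrhythmic", False),
        "diameter_mm": metrics.diameter_mm,
        "wall_thickness_mm": metrics.wall_thickness_mm,
        "heart_rate_bpm": metrics.heart_rate_bpm,
        "flow_ml_min": metrics.flow_ml_min,
        "pulsatility_index": metrics.pulsatility_index,
        "pwv_m_s": metrics.pwv_m_s,
        "reflection_coefficient": metrics.reflection_coefficient,
        "youngs_modulus_kpa": metrics.youngs_modulus_kpa,
        "qa_r_squared": metrics.qa_diagnostics["r_squared"],
        "n_cycles_used": ens.n_cycles_used,
        "n_cycles_rejected": ens.n_cycles_rejected,
    }


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest.

    A stage failure raises :class:`StageError` naming the stage; artifacts
    written before the failure are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: dict = {
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "version": __version__,
        "stages_run": [],
        "outputs": {},
        "failed_recordings": [],
    }

    state: dict = {}
    enabled = [s for s in STAGE_ORDER if config.stages.get(s, False)]

    for stage in enabled:
        log.info("running stage %s", stage)
        try:
            _STAGES[stage](config, outdir, state, manifest)
        except StageError:
            _write_manifest(outdir, manifest)
            raise
        except Exception as exc:  # halt with the failing stage named
            _write_manifest(outdir, manifest)
            raise StageError(stage, str(exc)) from exc
        manifest["stages_run"].append(stage)

    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         default=str))


def _stage_simulate(config: RunConfig, outdir: Path, state, manifest) -> None:
    spec = CohortSpec(seed=stage_seed(config.seed, "simulate"), **config.cohort)
    table, truth_log = simulate_cohort(spec)
    table.to_csv(outdir / "cohort_truth.csv", index=False)
    truth_log.to_csv(outdir / "truth_log.csv", index=False)
    manifest["outputs"]["cohort_truth"] = "cohort_truth.csv"
    manifest["outputs"]["truth_log"] = "truth_log.csv"

    wf_cfg = config.waveform
    recordings = []
    index_rows = []
    wf_dir = outdir / "waveforms"
    if wf_cfg.get("save_waveforms"):
        wf_dir.mkdir(exist_ok=True)
    for _, row in table.iterrows():
        rec_id = _recording_id(row)
        truth = hemotruth_for_row(row, seed=stage_seed(config.seed, rec_id))
        truth = dataclasses.replace(truth, noise_sd=wf_cfg.get("noise_sd", 0.0))
        jitter = wf_cfg.get("arrhythmia_jitter", 0.0) if row["arrhythmic"] else 0.0
        wf = synthesize_waveforms(truth, n_cycles=wf_cfg.get("n_cycles", 10),
                                  fs=wf_cfg.get("fs", 1000.0), rr_jitter=jitter)
        recordings.append({"row": row, "rec_id": rec_id, "truth": truth, "wf": wf})
        if wf_cfg.get("save_waveforms"):
            write_waveforms(wf, wf_dir / f"{rec_id}.csv")
            index_rows.append({
                "rec_id": rec_id, "mouse_id": row["mouse_id"],
                "genotype": row["genotype"], "sex": row["sex"],
                "age_days": row["age_days"], "side": row["side"],
                "arrhythmic": row["arrhythmic"],
                "wall_thickness_mm": row["wall_thickness_mm"],
                "waveform_file": f"waveforms/{rec_id}.csv",
            })
    if index_rows:
        pd.DataFrame(index_rows).to_csv(outdir / "recordings.csv", index=False)
        manifest["outputs"]["recordings"] = "recordings.csv"
    state["recordings"] = recordings
    log.info("simulated %d recordings", len(recordings))


def _stage_extract(config: RunConfig, outdir: Path, state, manifest) -> None:
    if "recordings" not in state:
        raise StageError("extract", "no simulated recordings in memory; "
                                    "enable the simulate stage")
    n_fail = 0
    for rec in state["recordings"]:
        try:
            t, A, V, thickness = _extract_recording(
                rec["truth"], rec["wf"], config, rec["rec_id"], outdir)
            rec["extracted"] = (t, A, V, thickness)
        except ExtractionError as exc:
            n_fail += 1
            manifest["failed_recordings"].append(
                {"rec_id": rec["rec_id"], "stage": "extract", "error": str(exc)})
    if n_fail > 0.2 * len(state["recordings"]):
        raise StageError("extract", f"{n_fail} recordings failed extraction")
    manifest["outputs"]["extracted"] = f"{len(state['recordings']) - n_fail} traces"


def _stage_analyze(config: RunConfig, outdir: Path, state, manifest) -> None:
    if "recordings" not in state:
        raise StageError("analyze", "no recordings to analyze; enable simulate")
    rows = []
    n_fail = 0
    for rec in state["recordings"]:
        row = rec["row"]
        try:
            if "extracted" in rec:
                t, A, V, thickness = rec["extracted"]
            elif config.stages.get("extract", False):
                continue  # failed extraction already logged
            else:
                wf = rec["wf"]
                t, A, V, thickness = wf.t, wf.A, wf.V, rec["truth"].h_true
            metrics, ens = _analyze_recording(t, A, V, thickness, row["side"],
                                              config.cycles)
            rows.append(_metrics_row(row, metrics, ens))
        except (CycleDetectionError, QAFitError, ValueError) as exc:
            n_fail += 1
            manifest["failed_recordings"].append(
                {"rec_id": rec["rec_id"], "stage": "analyze", "error": str(exc)})
    if not rows or n_fail > 0.2 * len(state["recordings"]):
        raise StageError("analyze", f"{n_fail} recordings failed analysis")
    metrics_df = pd.DataFrame(rows)
    metrics_df.to_csv(outdir / "vessel_metrics.csv", index=False)
    state["metrics"] = metrics_df
    manifest["outputs"]["vessel_metrics"] = "vessel_metrics.csv"
    log.info("analyzed %d recordings (%d failed)", len(rows), n_fail)


def _stage_stats(config: RunConfig, outdir: Path, state, manifest) -> None:
    if "metrics" in state:
        metrics_df = state["metrics"]
    else:
        path = outdir / "vessel_metrics.csv"
        if not path.exists():
            raise StageError("stats", f"missing metrics table {path}")
        metrics_df = read_metrics(path)

    alpha = config.stats.get("alpha", 0.05)
    metric_cols = [c for c in metrics_df.columns
                   if c not in ID_COLUMNS
                   and c not in ("qa_r_squared", "n_cycles_used", "n_cycles_rejected")]
    lmm_lines = []
    for metric in metric_cols:
        try:
            fit = fit_lmm(metrics_df, metric,
                          fixed_spec=config.stats.get("fixed_spec",
                                                      "genotype * sex * age + side"))
            geno = [n for n in fit.coefficients.index
                    if n.startswith("C(genotype") and ":" not in n][0]
            p = fit.coefficients.loc[geno, "p"]
            lmm_lines.append(
                f"{metric}: genotype effect at reference levels "
                f"estimate={fit.coefficients.loc[geno, 'estimate']:+.4g}, "
                f"p={p:.4g}, converged={fit.converged}")
        except Exception as exc:
            lmm_lines.append(f"{metric}: model failed ({exc})")

    screen = day50_biomarker_screen(
        metrics_df, metrics=metric_cols, alpha=alpha,
        stratified=config.stats.get("stratified", False))
    screen.to_csv(outdir / "screening_report.csv", index=False)

    summary = ["Linear mixed-effects models (per-mouse random intercept):"]
    summary += ["  " + line for line in lmm_lines]
    summary.append("")
    summary.append(f"Pre-symptomatic (earliest-age) biomarker screen, alpha={alpha}:")
    for _, r in screen[screen["significant"]].iterrows():
        summary.append(
            f"  {r['sex']}: {r['metric']} {r['direction']} in dcr "
            f"(p={r['p_value']:.3g}, AUC={r['auc']:.2f}, "
            f"cut-off={r['youden_cutoff']:.3g}, orientation={r['orientation']})")
    if not screen["significant"].any():
        summary.append("  no metric passed the screen")
    (outdir / "summary.txt").write_text("\n".join(summary) + "\n")
    state["screen"] = screen
    manifest["outputs"]["screening_report"] = "screening_report.csv"
    manifest["outputs"]["summary"] = "summary.txt"


def _stage_figures(config: RunConfig, outdir: Path, state, manifest) -> None:
    from . import plots  # deferred: pulls in matplotlib

    path = outdir / "vessel_metrics.csv"
    if "metrics" in state:
        metrics_df = state["metrics"]
    elif path.exists():
        metrics_df = read_metrics(path)
    else:
        raise StageError("figures", f"missing metrics table {path}")
    if metrics_df.empty:
        raise StageError("figures", "metrics table is empty; nothing to plot")

    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    files = plots.longitudinal_panels(metrics_df, figdir)
    rec = state.get("recordings", [None])[0]
    if rec is not None:
        wf = rec["wf"]
        files.append(plots.decomposition_figure(wf, figdir / "decomposition.png",
                                                title=rec["rec_id"]))
    manifest["outputs"]["figures"] = [str(f.name) for f in files]


_STAGES = {
    "simulate": _stage_simulate,
    "extract": _stage_extract,
    "analyze": _stage_analyze,
    "stats": _stage_stats,
    "figures": _stage_figures,
}


def analyze_waveform_dir(indir, outdir, cycles_cfg=None) -> pd.DataFrame:
    """Compute vessel metrics from waveform CSVs listed in recordings.csv.

    This is the extraction-free entry point: it consumes flow/area/velocity
    waveform files directly (e.g. written by a previous run with
    ``waveform.save_waveforms: true``) instead of rendered images.
    """
    indir, outdir = Path(indir), Path(outdir)
    index_path = indir / "recordings.csv"
    if not index_path.exists():
        raise ConfigError(f"missing recording index {index_path}")
    index = pd.read_csv(index_path)
    cycles_cfg = cycles_cfg or {}
    rows = []
    for _, row in index.iterrows():
        wf = read_waveforms(indir / row["waveform_file"])
        metrics, ens = _analyze_recording(
            wf.t, wf.A, wf.V, row["wall_thickness_mm"], row["side"], cycles_cfg)
        rows.append(_metrics_row(row, metrics, ens))
    metrics_df = pd.DataFrame(rows)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics_df.to_csv(outdir / "vessel_metrics.csv", index=False)
    return metrics_df
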