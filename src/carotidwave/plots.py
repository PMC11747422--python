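"""Figures: longitudinal metric panels and wave-decomposition overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import units
from .hemodynamics import decompose_waves, flow_waveform, pwv_qa_loop

GROUP_STYLE = {
    ("control", "F"): dict(color="black", label="control F"),
    ("dcr", "F"): dict(color="tab:green", label="dcr F"),
    ("control", "M"): dict(color="gray", label="control M"),
    ("dcr", "M"): dict(color="tab:blue", label="dcr M"),
}

METRIC_LABELS = {
    "diameter_mm": "Diameter (mm)",
    "wall_thickness_mm": "Wall thickness (mm)",
    "heart_rate_bpm": "Heart rate (bpm)",
    "flow_ml_min": "Blood flow (mL/min)",
    "pulsatility_index": "Pulsatility index",
    "pwv_m_s": "PWV (m/s)",
    "reflection_coefficient": "Reflection coefficient",
    "youngs_modulus_kpa": "Young's modulus (kPa)",
}


def longitudinal_panels(metrics_df, figdir) -> list:
    """One PNG per metric: mean ± SEM vs age by genotype × sex, split by side."""
    figdir = Path(figdir)
    sides = sorted(metrics_df["side"].unique())
    files = []
    for metric, label in METRIC_LABELS.items():
        if metric not in metrics_df.columns:
            continue
        fig, axes = plt.subplots(1, len(sides), figsize=(4.2 * len(sides), 3.4),
                                 sharey=True, squeeze=False)
        for ax, side in zip(axes[0], sides):
            sub = metrics_df[metrics_df["side"] == side]
            for (genotype, sex), style in GROUP_STYLE.items():
                g = sub[(sub["genotype"] == genotype) & (sub["sex"] == sex)]
                if g.empty:
                    continue
                stats = g.groupby("age_days")[metric].agg(["mean", "sem"])
                ax.errorbar(stats.index, stats["mean"], yerr=stats["sem"],
                            marker="o", capsize=3, **style)
            ax.set_title(side)
            ax.set_xlabel("Age (days)")
        axes[0][0].set_ylabel(label)
        axes[0][-1].legend(fontsize=8)
        fig.tight_layout()
        path = figdir / f"{metric}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        files.append(path)
    return files


def decomposition_figure(wf, path, title="") -> Path:
    """Observed flow with its forward/reflected components on one cycle.

    The residual max|Q − (Q_f + Q_r)| of the re-summed decomposition is
    annotated on the plot.
    """
    Q, _ = flow_waveform(wf.A, wf.V)
    pwv, _ = pwv_qa_loop(Q, wf.A)
    Q_f, Q_r = decompose_waves(Q, wf.A, pwv)
    residual = float(np.max(np.abs(Q - (Q_f + Q_r))))

    fig, ax = plt.subplots(figsize=(6, 3.4))
    ax.plot(wf.t, units.m3s_to_mlmin(Q), "k-", label="Q (observed)")
    ax.plot(wf.t, units.m3s_to_mlmin(Q_f), "r-", label="$Q_f$ (forward)")
    ax.plot(wf.t, units.m3s_to_mlmin(Q_r), "b-", label="$Q_r$ (reflected)")
    ax.set_xlabel("Time (s)")
    ax.set_ylabel("Flow (mL/min)")
    ax.set_title(title)
    ax.annotate(f"max |Q − (Q_f + Q_r)| = {residual:.2e} m³/s",
                xy=(0.02, 0.02), xycoords="axes fraction", fontsize=8)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
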