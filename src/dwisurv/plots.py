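"""Plotting helpers (Kaplan-Meier and risk-group calibration)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .selection import CalibrationResult
from .survival import KMResult


def plot_km(km_result: KMResult, path: str | Path, label: str = "KM") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    sf = km_result.survival
    if sf.knots.size:
        t_max = sf.knots[-1] * 1.05
        ax.step([0, *sf.knots, t_max], [1.0, *sf.values, sf.values[-1]],
                where="post", label=label)
        ax.step([0, *km_result.lower.knots, t_max],
                [1.0, *km_result.lower.values, km_result.lower.values[-1]],
                where="post", ls="--", color="grey", lw=0.8)
        ax.step([0, *km_result.upper.knots, t_max],
                [1.0, *km_result.upper.values, km_result.upper.values[-1]],
                where="post", ls="--", color="grey", lw=0.8)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_calibration(calib: CalibrationResult, path: str | Path) -> None:
    """Per-risk-group comparison of the KM curve and the mean model curve."""
    colors = {"low": "tab:green", "medium": "tab:orange", "high": "tab:red"}
    fig, ax = plt.subplots(figsize=(5.5, 4))
    for g, km_res in calib.group_km.items():
        sf = km_res.survival
        if sf.knots.size:
            ax.step([0, *sf.knots], [1.0, *sf.values], where="post",
                    color=colors[g], label=f"{g} (KM)")
        mc = calib.group_model_curve[g]
        ax.plot([0, *mc.knots], [1.0, *mc.values], color=colors[g], ls=":",
                label=f"{g} (model)")
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
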