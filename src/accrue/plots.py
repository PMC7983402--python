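"""Learning-curve figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .study import StudySummary

__all__ = ["plot_learning_curve", "plot_corrected_vs_holdout"]


def plot_learning_curve(curve: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Three panels vs sample size: corrected AUC, AUC optimism, corrected slope."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))
    panels = [
        ("auc_corrected", "bootstrap-corrected AUC", None),
        ("auc_optimism", "AUC optimism", 0.0),
        ("slope_corrected", "corrected calibration slope", 1.0),
    ]
    for ax, (col, label, ref) in zip(axes, panels):
        ax.plot(curve["n"], curve[col], lw=1.5)
        if ref is not None:
            ax.axhline(ref, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("development sample size n")
        ax.set_ylabel(label)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_corrected_vs_holdout(summary: StudySummary, path: str | Path) -> None:
    """Overlay mean corrected and mean holdout AUC / slope by sample size."""
    m = summary.curve.merge(summary.holdout_curve, on="n")
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6))
    for ax, (c, h, lab) in zip(
        axes,
        [("auc_corrected", "holdout_auc", "AUC"),
         ("slope_corrected", "holdout_slope", "calibration slope")],
    ):
        ax.plot(m["n"], m[c], label="bootstrap-corrected")
        ax.plot(m["n"], m[h], label="holdout", ls="--")
        ax.set_xlabel("development sample size n")
        ax.set_ylabel(lab)
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
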