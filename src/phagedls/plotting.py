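"""Optional static plots (spectrum overlays, calibration scatter, ROC).

Never required for any computation; the CLI writes these only when asked.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .calibration import LinearCalibration, PairedObservation, ThresholdClassifier
from .spectra import DLSSpectrum

__all__ = ["plot_spectra", "plot_calibration", "plot_roc"]


def plot_spectra(spectra: Sequence[DLSSpectrum], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for spec in spectra:
        ax.plot(spec.grid.centers, spec.intensity, label=spec.label or None)
    ax.set_xscale("log")
    ax.set_xlabel("hydrodynamic diameter (nm)")
    ax.set_ylabel("relative intensity (%)")
    if any(s.label for s in spectra):
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_calibration(
    model: LinearCalibration, pairs: Sequence[PairedObservation], path: str | Path
) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    xs = [p.auc_delta for p in pairs]
    ys = [p.titer_loss_log10 for p in pairs]
    ax.scatter(xs, ys, s=18, alpha=0.7)
    grid_x = [min(xs), max(xs)]
    ax.plot(grid_x, [model.predict_point(x) for x in grid_x], "k-")
    ax.set_xlabel("AUCΔ")
    ax.set_ylabel("titer loss (log10 PFU/mL)")
    ax.set_title(f"r² = {model.r_squared:.2f}, p = {model.p_value:.2g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(
    classifier: ThresholdClassifier, points: Sequence[tuple[float, float]], path: str | Path
) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    fpr = [p[0] for p in points]
    tpr = [p[1] for p in points]
    ax.plot(fpr, tpr, "-", drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(
        f"loss > {classifier.threshold_log10:g} log10, AUC = {classifier.roc_auc:.2f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
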