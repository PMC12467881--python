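"""Figure output: confusion matrices, protocol comparisons, k-distance curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classify import ClassificationReport
from .postprocess import KDistanceCurve

__all__ = ["plot_confusion", "plot_comparison", "plot_kdistance"]


def plot_confusion(report: ClassificationReport, path: str | Path) -> None:
    """Render a row-normalized confusion matrix with counts annotated."""
    conf = report.confusion
    with np.errstate(invalid="ignore"):
        frac = conf / np.maximum(conf.sum(axis=1, keepdims=True), 1)
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    im = ax.imshow(frac, cmap="Blues", vmin=0, vmax=1)
    ax.set_xticks(range(len(report.classes)), report.classes, rotation=30, ha="right")
    ax.set_yticks(range(len(report.classes)), report.classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(f"accuracy {100 * report.accuracy:.2f}%")
    for i in range(conf.shape[0]):
        for j in range(conf.shape[1]):
            ax.text(
                j, i, str(conf[i, j]), ha="center", va="center",
                color="white" if frac[i, j] > 0.5 else "black", fontsize=9,
            )
    fig.colorbar(im, ax=ax, fraction=0.046)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_comparison(table: pd.DataFrame, path: str | Path) -> None:
    """Bar chart of accuracy per protocol (the summary-figure analogue)."""
    fig, ax = plt.subplots(figsize=(5.0, 3.2))
    ax.bar(table["protocol"], 100.0 * table["accuracy"], color="#4878a8")
    ax.set_ylabel("accuracy (%)")
    ax.set_ylim(0, 100)
    for x, acc in zip(table["protocol"], table["accuracy"]):
        ax.text(x, 100 * acc + 1, f"{100 * acc:.1f}", ha="center", fontsize=8)
    ax.tick_params(axis="x", rotation=20)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_kdistance(curves: list[KDistanceCurve], path: str | Path) -> None:
    """Sorted k-th-nearest-neighbor distance curves with elbow markers."""
    fig, ax = plt.subplots(figsize=(5.0, 3.2))
    for curve in curves:
        ax.plot(curve.distances, label=f"k={curve.k}")
        ax.axhline(curve.suggested_eps, ls="--", lw=0.8, color="gray")
    ax.set_xlabel("sample index (sorted)")
    ax.set_ylabel("k-NN distance")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
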