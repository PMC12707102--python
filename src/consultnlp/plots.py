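"""Optional matplotlib figures: per-concept ROC panels and confusion heatmaps."""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .concepts import Concept
from .evaluation import RocCurve
from .grading import AgreementReport

__all__ = ["roc_panel", "confusion_heatmap"]


def roc_panel(curves: Mapping[Concept, RocCurve], path: str) -> None:
    """3x3 grid of ROC curves, one per concept, AUC in each title."""
    fig, axes = plt.subplots(3, 3, figsize=(9, 9), sharex=True, sharey=True)
    for ax, (concept, curve) in zip(axes.ravel(), curves.items()):
        ax.plot(curve.fpr, curve.tpr, lw=1.5)
        ax.plot([0, 1], [0, 1], ls="--", lw=0.8, color="grey")
        ax.set_title(f"{concept.value} (AUC {curve.auc:.2f})", fontsize=9)
    fig.supxlabel("1 - specificity")
    fig.supylabel("Sensitivity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def confusion_heatmap(reports: Mapping[Concept, AgreementReport], path: str) -> None:
    """3x3 grid of 6x6 actual-vs-predicted consult-score matrices."""
    fig, axes = plt.subplots(3, 3, figsize=(10, 10))
    for ax, (concept, rep) in zip(axes.ravel(), reports.items()):
        ax.imshow(rep.confusion, cmap="Blues")
        for i in range(rep.n_levels):
            for j in range(rep.n_levels):
                if rep.confusion[i, j]:
                    ax.text(j, i, str(rep.confusion[i, j]), ha="center", va="center", fontsize=8)
        ax.set_title(f"{concept.value} (acc {rep.accuracy:.2f})", fontsize=9)
        ax.set_xlabel("predicted")
        ax.set_ylabel("actual")
        ax.set_xticks(range(rep.n_levels))
        ax.set_yticks(range(rep.n_levels))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
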