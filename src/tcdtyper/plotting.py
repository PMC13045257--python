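"""Minimal plots: Kaplan-Meier step curves and ROC curves.

These helpers render the two figures users ask for most; they are not
part of the pipeline's written artifacts (which stay plain text).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .classify import ClassifierEval
from .survival import KMCurve

__all__ = ["plot_km", "plot_roc"]


def plot_km(curves: Mapping[str, KMCurve], path: str | Path, title: str = "") -> None:
    """Step plot of one survival curve per named group."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in curves.items():
        times = [0.0, *curve.event_times.tolist()]
        surv = [1.0, *curve.survival.tolist()]
        ax.step(times, surv, where="post", label=name)
    ax.set_xlabel("time")
    ax.set_ylabel("S(t)")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(evals: Mapping[str, ClassifierEval], path: str | Path, title: str = "") -> None:
    """ROC curves with AUC in the legend."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, ev in evals.items():
        ax.plot(ev.fpr, ev.tpr, label=f"{name} (AUC = {ev.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(frameon=False, loc="lower right")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
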