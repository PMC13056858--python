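"""Diagnostic plots: preprocessing QC, ROC overlays and decision curves.

All functions take an optional matplotlib Axes and return it, so figures
compose in the usual way.
"""

from __future__ import annotations

import numpy as np

from .evaluate import NetBenefitCurve
from .spectra import Spectrum


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_spectrum_qc(raw: Spectrum, processed: Spectrum, baseline=None, ax=None):
    """Before/after preprocessing overlay for visual QC of one sample."""
    ax = _axes(ax)
    ax.plot(raw.mz, raw.intensity, lw=0.4, alpha=0.6, label="raw")
    ax.plot(processed.mz, processed.intensity, lw=0.4, label=processed.stage)
    if baseline is not None:
        ax.plot(raw.mz, baseline, lw=0.8, ls="--", label="baseline")
    ax.set_xlabel("m/z (Da)")
    ax.set_ylabel("intensity")
    ax.set_title(raw.sample_id)
    ax.legend(frameon=False)
    return ax


def plot_roc(curves: dict[str, tuple[np.ndarray, np.ndarray, float]], ax=None):
    """ROC overlay; ``curves`` maps label -> (fpr, tpr, auc)."""
    ax = _axes(ax)
    for label, (fpr, tpr, auc) in curves.items():
        ax.plot(fpr, tpr, label=f"{label} (AUC {auc:.2f})")
    ax.plot([0, 1], [0, 1], ls=":", c="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_decision_curves(curves: dict[str, NetBenefitCurve], ax=None):
    """Net-benefit curves with treat-all / treat-none references."""
    ax = _axes(ax)
    ref = next(iter(curves.values()))
    ax.plot(ref.thresholds, ref.nb_all, c="grey", ls="--", lw=0.8, label="treat all")
    ax.axhline(0.0, c="grey", ls=":", lw=0.8, label="treat none")
    for label, c in curves.items():
        ax.plot(c.thresholds, c.nb, label=f"{label} (area {c.area:.3f})")
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.set_ylim(bottom=max(-0.1, ax.get_ylim()[0]))
    ax.legend(frameon=False, fontsize=8)
    return ax
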