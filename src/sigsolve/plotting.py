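"""Graphical outputs: signature profiles, exposure bars, cost curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .denovo import CVResult
from .fitting import CostCurve, ExposureMatrix
from .panel import SignaturePanel

__all__ = ["plot_signature_profile", "plot_contributions", "plot_cost_curve"]

_CLASS_COLOURS = {
    "C>A": "#03bcee",
    "C>G": "#010101",
    "C>T": "#e32926",
    "T>A": "#999999",
    "T>C": "#a1cf64",
    "T>G": "#ecc6c5",
}


def plot_signature_profile(panel: SignaturePanel, out: str | Path) -> None:
    """One bar-profile row per signature, coloured by substitution class.

    SBS-96 catalogs use the conventional 6-class grouped layout; other
    channel sets fall back to a generic bar chart.
    """
    n = panel.n_signatures
    is_sbs96 = panel.catalog.name == "SBS96"
    fig, axes = plt.subplots(n, 1, figsize=(12, 2.2 * n), squeeze=False)
    for ax, name, probs in zip(axes[:, 0], panel.names, panel.probs):
        if is_sbs96:
            colours = [_CLASS_COLOURS[lab[2:5]] for lab in panel.catalog.labels]
        else:
            colours = "tab:blue"
        ax.bar(range(len(probs)), probs, color=colours, width=0.8)
        ax.set_ylabel("probability")
        ax.set_title(name, fontsize=9, loc="left")
        ax.set_xticks(range(len(probs)))
        ax.set_xticklabels(panel.catalog.labels, rotation=90, fontsize=3)
        ax.margins(x=0.005)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def clustered_order(W: ExposureMatrix) -> list[int]:
    """Sample order from average-linkage clustering of exposure fractions.

    Fractions (row-normalised exposures) are compared by Euclidean distance;
    the returned order is the dendrogram leaf order.
    """
    if len(W.samples) < 3:
        return list(range(len(W.samples)))
    frac = W.values / np.maximum(W.values.sum(axis=1, keepdims=True), 1e-300)
    link = hierarchy.linkage(pdist(frac), method="average")
    return list(hierarchy.leaves_list(link))


def plot_contributions(
    W: ExposureMatrix, out: str | Path, clustered: bool = False
) -> None:
    """Stacked per-sample bars of attributed mutations, one block per signature."""
    order = clustered_order(W) if clustered else list(range(len(W.samples)))
    values = W.values[order]
    samples = [W.samples[i] for i in order]
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(samples)), 4))
    bottom = np.zeros(len(samples))
    for j, sig in enumerate(W.signatures):
        ax.bar(samples, values[:, j], bottom=bottom, label=sig, width=0.8)
        bottom += values[:, j]
    ax.set_ylabel("mutations attributed")
    ax.legend(fontsize=7, ncol=2)
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    if clustered:
        fig.text(
            0.01, 0.01,
            "sample order: average-linkage clustering, Euclidean distance on "
            "exposure fractions",
            fontsize=6,
        )
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def plot_cost_curve(curve: CostCurve | CVResult, out: str | Path) -> None:
    """Cost versus model size, with signature labels (or train/test series).

    Backward curves are rendered in importance order so the cost appears
    decreasing, matching the forward display.
    """
    fig, ax = plt.subplots(figsize=(7, 4.5))
    if isinstance(curve, CostCurve):
        costs = curve.costs
        labels = [s.signature for s in curve.steps]
        if curve.direction == "backward":
            costs, labels = costs[::-1], labels[::-1]
        x = np.arange(1, len(costs) + 1)
        ax.plot(x, costs, "o-", color="tab:blue")
        for xi, yi, lab in zip(x, costs, labels):
            ax.annotate(lab, (xi, yi), fontsize=6, rotation=45,
                        textcoords="offset points", xytext=(4, 4))
        ax.set_xlabel("number of signatures in model")
        ax.set_title(f"{curve.direction} selection cost curve")
    else:
        ax.plot(curve.candidates, curve.mean_train_cost, "s--",
                color="tab:grey", label="training")
        ax.plot(curve.candidates, curve.mean_test_cost, "o-",
                color="tab:red", label="test (held out)")
        ax.set_xlabel("number of de novo signatures")
        ax.legend()
        ax.set_title(f"leave-{curve.k}-out cross-validation")
    ax.set_ylabel("cost C")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
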