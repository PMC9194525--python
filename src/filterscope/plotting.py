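"""Publication-style figures for the explainability artifacts."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless-safe; figures are saved, never shown
import matplotlib.pyplot as plt
import numpy as np

from .lrp import ClusterRelevance
from .model import FilterBank
from .perturbation import CANONICAL_BANDS, ImportanceMap, PerturbationResult
from .spectra import ClusterAssignment, SpectraMatrix

__all__ = [
    "plot_filters_by_cluster",
    "plot_cluster_spectra",
    "plot_cluster_relevance",
    "plot_ablation_importance",
    "plot_band_perturbation",
    "plot_temporal_importance",
    "save_all",
]

_CLUSTER_CMAP = plt.get_cmap("tab10")


def plot_filters_by_cluster(bank: FilterBank, assignment: ClusterAssignment):
    """Time-domain traces of every filter, stacked and grouped by cluster."""
    order = np.argsort(assignment.labels, kind="stable")
    t = np.arange(bank.filter_len) / bank.fs
    fig, ax = plt.subplots(figsize=(7, 0.45 * bank.n_filters + 1))
    span = max(np.abs(bank.weights).max(), 1e-12)
    for row, f in enumerate(order):
        c = assignment.labels[f]
        ax.plot(t, bank.weights[f] / (2.2 * span) + row,
                color=_CLUSTER_CMAP(c), lw=0.8)
        ax.text(t[-1], row, f" f{f} (c{c})", va="center", fontsize=7)
    ax.set_xlabel("time (s)")
    ax.set_yticks([])
    ax.set_title("first-layer filters by cluster")
    fig.tight_layout()
    return fig


def plot_cluster_spectra(spectra: SpectraMatrix, assignment: ClusterAssignment):
    """Per-cluster filter spectra with the cluster center overlaid."""
    k = assignment.k
    fig, axes = plt.subplots(1, k, figsize=(4 * k, 3), sharey=True, squeeze=False)
    for c, ax in enumerate(axes[0]):
        for f in assignment.members(c):
            ax.plot(spectra.freqs, spectra.power[f],
                    color=_CLUSTER_CMAP(c), alpha=0.4, lw=0.8)
        ax.plot(spectra.freqs, assignment.centers[c], color="red", lw=1.5,
                label="center")
        for band in CANONICAL_BANDS[:-1]:
            ax.axvline(band.hi, color="gray", ls="--", lw=0.6)
        ax.set_title(f"cluster {c} (n={assignment.sizes[c]})")
        ax.set_xlabel("frequency (Hz)")
    axes[0][0].set_ylabel("power")
    fig.tight_layout()
    return fig


def plot_cluster_relevance(cluster_rel: ClusterRelevance,
                           class_names: tuple[str, ...] = ()):
    """Grouped bars: normalized relevance per class and cluster."""
    nr = cluster_rel.nr
    n_classes, k = nr.shape
    names = list(class_names) or [str(i) for i in range(n_classes)]
    x = np.arange(n_classes)
    width = 0.8 / k
    fig, ax = plt.subplots(figsize=(1.2 * n_classes + 2, 3))
    for c in range(k):
        ax.bar(x + c * width, nr[:, c], width, color=_CLUSTER_CMAP(c),
               label=f"cluster {c}")
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(names)
    ax.set_ylabel("normalized relevance")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_ablation_importance(ablations: list[PerturbationResult],
                             class_names: tuple[str, ...] = ()):
    """Grouped bars: F1 percent change after ablating each cluster."""
    k = len(ablations)
    n_classes = ablations[0].baseline.n_classes
    names = (list(class_names) or
             [str(i) for i in range(n_classes)]) + ["weighted"]
    x = np.arange(n_classes + 1)
    width = 0.8 / k
    fig, ax = plt.subplots(figsize=(1.2 * n_classes + 2, 3))
    for c, res in enumerate(ablations):
        vals = np.append(res.per_class_change, res.weighted_change)
        ax.bar(x + c * width, vals, width, color=_CLUSTER_CMAP(c),
               label=f"cluster {res.descriptor['cluster']}")
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(names, rotation=30)
    ax.set_ylabel("F1 % change")
    ax.axhline(0, color="k", lw=0.5)
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_band_perturbation(band_results: list[PerturbationResult],
                           class_names: tuple[str, ...] = ()):
    """One heatmap per cluster: band x class F1 percent change."""
    clusters = sorted({r.descriptor["cluster"] for r in band_results})
    n_classes = band_results[0].baseline.n_classes
    names = list(class_names) or [str(i) for i in range(n_classes)]
    band_names = [b.name for b in CANONICAL_BANDS]
    fig, axes = plt.subplots(1, len(clusters), figsize=(3.2 * len(clusters), 3),
                             squeeze=False)
    vmax = max(1e-9, max(np.nanmax(np.abs(r.per_class_change))
                         for r in band_results))
    for ax, c in zip(axes[0], clusters):
        grid = np.full((len(band_names), n_classes), np.nan)
        for r in band_results:
            if r.descriptor["cluster"] == c:
                grid[band_names.index(r.descriptor["band"])] = r.per_class_change
        im = ax.imshow(grid, cmap="RdBu", vmin=-vmax, vmax=vmax, aspect="auto")
        ax.set_xticks(range(n_classes))
        ax.set_xticklabels(names, rotation=45, fontsize=7)
        ax.set_yticks(range(len(band_names)))
        ax.set_yticklabels(band_names, fontsize=7)
        ax.set_title(f"cluster {c}", fontsize=9)
    fig.colorbar(im, ax=axes[0], label="F1 % change", shrink=0.8)
    return fig


def plot_temporal_importance(importance: ImportanceMap,
                             assignment: ClusterAssignment | None = None):
    """Heatmaps of per-weight importance: one panel per class + weighted."""
    n_panels = importance.importance.shape[2]
    n_classes = n_panels - 1
    names = (list(importance.class_names) or
             [str(i) for i in range(n_classes)]) + ["weighted"]
    order = (np.argsort(assignment.labels, kind="stable")
             if assignment is not None else np.arange(importance.n_filters))
    fig, axes = plt.subplots(n_panels, 1,
                             figsize=(7, 1.6 * n_panels), squeeze=False)
    vmax = max(1e-9, np.nanmax(np.abs(importance.importance)))
    for p, ax in enumerate(axes[:, 0]):
        im = ax.imshow(importance.importance[order, :, p], cmap="RdBu",
                       vmin=-vmax, vmax=vmax, aspect="auto")
        ax.set_ylabel(names[p], fontsize=8)
        ax.set_yticks([])
    axes[-1, 0].set_xlabel("filter weight position")
    fig.colorbar(im, ax=axes[:, 0], label="F1 % change", shrink=0.6)
    return fig


def save_all(outdir: str | Path, *, bank, spectra, assignment, cluster_rel,
             ablations, band_results, importance, class_names=()) -> list[Path]:
    """Render and save every figure; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    figs = {
        "filters_by_cluster.png": plot_filters_by_cluster(bank, assignment),
        "cluster_spectra.png": plot_cluster_spectra(spectra, assignment),
        "cluster_relevance.png": plot_cluster_relevance(cluster_rel, class_names),
        "cluster_ablation.png": plot_ablation_importance(ablations, class_names),
        "band_perturbation.png": plot_band_perturbation(band_results, class_names),
        "temporal_importance.png": plot_temporal_importance(importance, assignment),
    }
    paths = []
    for name, fig in figs.items():
        path = outdir / name
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
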