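"""Minimal plotting helpers (PC projections, scatter + fit, Q-Q, heatmap)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_embedding(emb, path: str | Path, pcs=(1, 2)) -> None:
    """Scatter of two PCs with cancers and normals in different colors."""
    i, j = pcs
    fig, ax = plt.subplots(figsize=(6, 5))
    for cls, color in (("cancer", "tab:blue"), ("normal", "tab:red")):
        mask = emb.classes == cls
        xs = emb.coordinates.loc[mask, f"PC{i}"]
        ys = emb.coordinates.loc[mask, f"PC{j}"]
        ax.scatter(xs, ys, c=color, label=cls, s=25)
        for name, x, y in zip(xs.index, xs, ys):
            ax.annotate(name, (x, y), fontsize=6)
    ax.set_xlabel(f"PC{i}")
    ax.set_ylabel(f"PC{j}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_scree(emb, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(np.arange(1, len(emb.variances) + 1), emb.variances)
    ax.set_xlabel("component")
    ax.set_ylabel("variance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_scatter_fit(x, y, fit, path: str | Path, xlabel="", ylabel="") -> None:
    """Gene scatter with the least-squares line and rho annotation."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=3, alpha=0.3, color="black")
    xs = np.linspace(np.min(x), np.max(x), 50)
    ax.plot(xs, fit.slope * xs + fit.intercept, color="red")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(f"Spearman rho = {fit.rho:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_qq(report, path: str | Path, label_all="all genes", label_filtered="filtered") -> None:
    """Q-Q plot of filtered vs unfiltered p-values with the identity line."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(report.quantiles_all, report.quantiles_filtered, color="black")
    lim = [0, 1]
    ax.plot(lim, lim, color="red", lw=1)
    ax.set_xlabel(f"p-value quantiles ({label_all})")
    ax.set_ylabel(f"p-value quantiles ({label_filtered})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_fc_heatmap(fc, path: str | Path) -> None:
    """Pairwise fold-change correlation heatmap: unfiltered below the
    diagonal, filtered above."""
    cancers = list(fc.unfiltered.index)
    k = len(cancers)
    M = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            if i > j:
                M[i, j] = fc.unfiltered.iloc[i, j]
            elif i < j:
                M[i, j] = fc.filtered.iloc[i, j]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(M, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(k), cancers, rotation=90, fontsize=7)
    ax.set_yticks(range(k), cancers, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
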