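"""Plot helpers: PCA/bgPCA scatter with trajectories, regression scatter,
and a simple wireframe of a mean shape (visualisation only, unvalidated)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .shape_metrics import OrdinationResult

__all__ = ["plot_ordination", "plot_trajectories", "plot_regression", "plot_wireframe"]

# default connection order for the 12-landmark fish outline
FISH_WIREFRAME = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6),
                  (6, 7), (7, 8), (8, 9), (9, 10), (10, 11), (11, 0)]


def plot_ordination(result: OrdinationResult, groups, path, axes=(0, 1)):
    i, j = axes
    fig, ax = plt.subplots(figsize=(6, 5))
    groups = np.asarray(groups)
    for g in dict.fromkeys(groups):
        mask = groups == g
        ax.scatter(result.scores[mask, i], result.scores[mask, j], s=12, label=str(g))
    ve = result.variance_explained
    ax.set_xlabel(f"axis {i + 1} ({100 * ve[i]:.1f}%)")
    ax.set_ylabel(f"axis {j + 1} ({100 * ve[j]:.1f}%)")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trajectories(result: OrdinationResult, pairs: dict, path):
    """Connect each derived group's mean score to its source's on bgPC1/2."""
    gms = result.group_mean_scores
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(gms.iloc[:, 0], gms.iloc[:, 1], c="k", s=20)
    for name, row in gms.iterrows():
        ax.annotate(str(name), (row.iloc[0], row.iloc[1]), fontsize=6)
    for crater, source in pairs.values():
        if crater in gms.index and source in gms.index:
            ax.annotate(
                "",
                xy=gms.loc[crater].iloc[:2],
                xytext=gms.loc[source].iloc[:2],
                arrowprops=dict(arrowstyle="->", color="tab:blue"),
            )
    ve = result.variance_explained
    ax.set_xlabel(f"bgPC1 ({100 * ve[0]:.1f}%)")
    ax.set_ylabel(f"bgPC2 ({100 * ve[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_regression(x, y, fit, path, xlabel="", ylabel=""):
    fig, ax = plt.subplots(figsize=(5, 4))
    x = np.asarray(x, dtype=float)
    if fit.transform == "log10_x":
        x = np.log10(x)
        xlabel = f"log10({xlabel or fit.predictor})"
    ax.scatter(x, y, c="k")
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, "r-")
    ax.set_xlabel(xlabel or fit.predictor)
    ax.set_ylabel(ylabel or fit.response)
    ax.set_title(f"adj R$^2$ = {fit.adj_r2:.3f}, p = {fit.p:.3g}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_wireframe(mean_shape, path, connections=FISH_WIREFRAME, other=None):
    shape = np.asarray(mean_shape).reshape(-1, 2)
    fig, ax = plt.subplots(figsize=(5, 4))
    for a, b in connections:
        ax.plot(*zip(shape[a], shape[b]), "k-")
    if other is not None:
        o = np.asarray(other).reshape(-1, 2)
        for a, b in connections:
            ax.plot(*zip(o[a], o[b]), "r--", alpha=0.7)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
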