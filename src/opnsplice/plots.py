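"""Plot plumbing: per-group scatter vs total and a z-score heat map."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .deconvolution import ExpressionMatrix, GroupEstimate, TotalProxy

__all__ = ["plot_group_scatter", "plot_expression_heatmap"]


def plot_group_scatter(
    estimate: GroupEstimate, proxy: TotalProxy, path: str | Path, log_scale: bool = True
) -> Path:
    """Scatter of one group's abundance against the total proxy."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    x = proxy.total.to_numpy(dtype=float)
    y = estimate.abundances.to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=12, alpha=0.6, edgecolors="none")
    if log_scale:
        ax.set_xscale("log", base=2)
        ax.set_yscale("log", base=2)
    ax.set_xlabel("total OPN expression (linear)")
    ax.set_ylabel(f"{estimate.group_label} (linear)")
    ax.set_title(f"{estimate.group_label} vs total")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def plot_expression_heatmap(X: ExpressionMatrix, path: str | Path) -> Path:
    """Row-z-scored probe-set heat map (samples x probe sets)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vals = X.values.to_numpy(dtype=float)
    mu = vals.mean(axis=0, keepdims=True)
    sd = vals.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - mu) / sd
    fig, ax = plt.subplots(figsize=(max(4, 0.25 * z.shape[1]), 4))
    im = ax.imshow(z.T, aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3)
    ax.set_yticks(np.arange(z.shape[1]), labels=X.probesets, fontsize=6)
    ax.set_xlabel("samples")
    fig.colorbar(im, ax=ax, label="z-score (log2 signal)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
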