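"""Basic plots: signature profiles and the TMB outlier view."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .channels import SUBSTITUTIONS

_SUB_COLORS = {
    "C>A": "#03bcee",
    "C>G": "#010101",
    "C>T": "#e32926",
    "T>A": "#cac9c9",
    "T>C": "#a1cf63",
    "T>G": "#ecc6c5",
}


def plot_signatures(W: pd.DataFrame, path: str | Path) -> None:
    """Bar plot of each signature over the 96 channels, one row per signature."""
    k = W.shape[1]
    fig, axes = plt.subplots(k, 1, figsize=(12, 1.8 * k), sharex=True, squeeze=False)
    x = np.arange(96)
    colors = [_SUB_COLORS[s] for s in SUBSTITUTIONS for _ in range(16)]
    for ax, name in zip(axes.ravel(), W.columns):
        ax.bar(x, W[name].to_numpy(), color=colors, width=0.8)
        ax.set_ylabel(name, fontsize=7)
        ax.set_xlim(-1, 96)
    axes.ravel()[-1].set_xticks(x[::16])
    axes.ravel()[-1].set_xticklabels([s for s in SUBSTITUTIONS], fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_tmb(values: pd.Series, threshold: float, path: str | Path) -> None:
    """Strip plot of per-sample POLE-signature TMB with the outlier fence."""
    fig, ax = plt.subplots(figsize=(5, 4))
    rng = np.random.default_rng(0)
    x = rng.uniform(-0.15, 0.15, size=len(values))
    ax.scatter(x, values, s=12, alpha=0.7)
    ax.axhline(threshold, color="red", linestyle="--", label=f"fence {threshold:.2f}")
    ax.set_ylabel("POLE-signature TMB (mut/Mb)")
    ax.set_xticks([])
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
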