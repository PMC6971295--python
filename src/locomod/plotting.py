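"""Module summary figures: bars for spatial modules, lines for temporal
modules, dots for task-dependent modulations — one row per component."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .datatypes import CPModel, TaskDescriptor

__all__ = ["plot_model", "plot_vaf_curve"]


def plot_model(model: CPModel, descriptors: Optional[Sequence[TaskDescriptor]] = None,
               channel_labels: Optional[Sequence[str]] = None, path=None):
    """One row per component: spatial bars, temporal line, task-modulation dots."""
    R = model.R
    fig, axes = plt.subplots(R, 3, figsize=(10, 1.9 * R), squeeze=False)
    S = model.spatial.shape[0]
    xlabels = channel_labels if channel_labels is not None else range(S)
    speeds = ([d.speed for d in descriptors] if descriptors is not None
              else np.arange(model.task.shape[0]))
    for r in range(R):
        ax = axes[r][0]
        ax.bar(range(S), model.spatial[:, r], color="tab:blue")
        ax.set_xticks(range(S))
        ax.set_xticklabels(xlabels, rotation=90, fontsize=6)
        ax.set_ylabel(f"#{r + 1}  λ={model.weights[r]:.1f}", fontsize=8)
        axes[r][1].plot(model.temporal[:, r], color="tab:green")
        axes[r][1].set_xlabel("frame")
        axes[r][2].plot(speeds, model.task[:, r], ".", ms=3, color="tab:red")
        axes[r][2].set_xlabel("speed (m/s)")
    axes[0][0].set_title("spatial module")
    axes[0][1].set_title("temporal module")
    axes[0][2].set_title("task modulation")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_vaf_curve(vaf: np.ndarray, fitting_error: np.ndarray,
                   threshold: float = 0.7, path=None):
    ranks = np.arange(1, len(vaf) + 1)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3))
    ax1.plot(ranks, vaf, "o-")
    ax1.axhline(threshold, ls="--", c="gray")
    ax1.set_xlabel("number of components R")
    ax1.set_ylabel("variance accounted for")
    ax2.plot(ranks, fitting_error, "o-")
    ax2.set_xlabel("number of components R")
    ax2.set_ylabel("fitting error")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
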