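"""Figures: model-space evidence bars, BMA parameter bars, trajectory bands."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .peb import BMAResult, ModelSpace, Trajectories

__all__ = ["plot_model_space", "plot_bma", "plot_trajectories"]


def plot_model_space(space: ModelSpace, title: str = "", path: str | None = None):
    """Relative pooled log evidence per reduced second-level model."""
    fig, (ax0, ax1) = plt.subplots(1, 2, figsize=(9, 3.2), width_ratios=[1, 2])
    ax0.imshow(space.inclusion.T, aspect="auto", cmap="Greys", interpolation="nearest")
    ax0.set_yticks(range(len(space.regressor_labels)), space.regressor_labels)
    ax0.set_xlabel("model")
    ax0.set_title("model space")
    rel = space.pooled_logev - space.pooled_logev.max()
    ax1.bar(np.arange(1, space.n_models + 1), rel)
    ax1.axvline(space.winner() + 1, color="r", ls=":", lw=1)
    ax1.set_xlabel("model")
    ax1.set_ylabel("log evidence (rel. best)")
    ax1.set_title(title or "pooled evidence")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_bma(bma: BMAResult, title: str = "", path: str | None = None, pp_threshold: float = 0.95):
    """Averaged second-level coefficients; * marks Pp above threshold."""
    fig, ax = plt.subplots(figsize=(max(6, 0.35 * bma.mean.size), 3.2))
    x = np.arange(bma.mean.size)
    sd = np.sqrt(np.clip(np.diag(bma.cov), 0, None))
    ax.bar(x, bma.mean, yerr=1.645 * sd, capsize=2)
    for j in np.flatnonzero(bma.Pp > pp_threshold):
        ax.annotate("*", (x[j], bma.mean[j]), ha="center", fontsize=14, color="r")
    ax.set_xticks(x, bma.param_labels or x, rotation=90, fontsize=6)
    ax.set_ylabel("BMA mean (log gain units)")
    ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_trajectories(traj: Trajectories, title: str = "", path: str | None = None):
    """Group-level log-gain trajectories with credible bands."""
    fig, ax = plt.subplots(figsize=(6, 3.2))
    w = np.arange(traj.values.shape[0])
    for b in range(traj.values.shape[1]):
        lab = traj.connection_labels[b] if traj.connection_labels else f"conn {b}"
        (line,) = ax.plot(w, traj.values[:, b], label=lab)
        ax.fill_between(w, traj.lower[:, b], traj.upper[:, b], alpha=0.2, color=line.get_color())
    ax.set_xlabel("window")
    ax.set_ylabel("log gain")
    ax.set_title(title or f"trajectories ({traj.level:.0%} credible band)")
    ax.legend(fontsize=6)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
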