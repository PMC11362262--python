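"""Basic diagnostic plots: scree, distortion elbow, dendrogram."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

from .clustering import Dendrogram, DistortionProfile
from .embedding import ElbowResult, StressProfile


def save_scree_plot(profile: StressProfile, elbow: ElbowResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(
        profile.dims, profile.mean_stress, yerr=profile.table["sd_stress"],
        marker="o", capsize=3,
    )
    if elbow.found:
        ax.axvline(elbow.x_at_elbow, linestyle="--", color="gray")
    ax.set_xlabel("dimensions")
    ax.set_ylabel("mean raw stress")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_distortion_plot(
    profile: DistortionProfile, elbow: ElbowResult, path: str | Path
) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(profile.table["k"], profile.table["distortion"], marker="o")
    if elbow.found:
        ax.axvline(elbow.x_at_elbow, linestyle="--", color="gray")
    ax.set_xlabel("clusters (k)")
    ax.set_ylabel("squared-error distortion")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_dendrogram_plot(dend: Dendrogram, path: str | Path, cut: int | None = None) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    scipy_dendrogram(
        dend.merges, labels=[str(i) for i in dend.object_ids], ax=ax,
        color_threshold=None,
    )
    if cut is not None and 1 < cut <= dend.n_leaves:
        # height separating the last `cut-1` merges
        heights = dend.heights()
        threshold = (heights[-cut] + heights[-cut + 1]) / 2 if cut > 1 else heights[-1]
        ax.axhline(threshold, linestyle="--", color="gray")
    ax.set_ylabel("Ward linkage height")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
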