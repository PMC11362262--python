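"""Bootstrap stability of the clustering solutions.

The resampling unit is the participant: each bootstrap replicate draws
participants with replacement, averages their dissimilarity matrices,
re-embeds the average with metric SMACOF at a fixed dimensionality, and
re-clusters at a fixed cluster count (k-means on the embedded coordinates,
Ward on the embedded distances).  Agreement between partitions is
summarized with the Adjusted Rand Index: within a method over all
replicate pairs, and across methods over replicate-matched pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .arrangement import DissimilarityMatrix, group_matrix
from .clustering import Partition, cut_tree, kmeans_partition, ward_tree
from .designgen import TrialDesign
from .embedding import smacof_embed

__all__ = [
    "BootstrapSpec",
    "StabilityReport",
    "adjusted_rand_index",
    "bootstrap_partitions",
    "stability_summary",
]


@dataclass(frozen=True)
class BootstrapSpec:
    """Bootstrap protocol parameters.

    ``sample_size`` defaults to the number of available participants so
    each replicate mirrors the original sample; ``fixed_k`` is the cluster
    count applied to every replicate and both methods.
    """

    n_replicates: int = 1000
    sample_size: int | None = None
    fixed_k: int = 7
    embed_dim: int = 3
    embed_starts: int = 4
    kmeans_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.fixed_k < 1 or self.embed_dim < 1:
            raise ValueError("bootstrap parameters must be positive")
        if self.sample_size is not None and self.sample_size < 1:
            raise ValueError("sample_size must be positive")


@dataclass(frozen=True)
class StabilityReport:
    mean_ari_kmeans: float | None
    mean_ari_ward: float | None
    mean_ari_cross: float | None
    n_replicates: int


def adjusted_rand_index(p1: Partition, p2: Partition) -> float:
    """Chance-corrected agreement between two partitions of the same objects."""
    if p1.object_ids != p2.object_ids:
        raise ValueError("partitions cover different object sets")
    ids = p1.object_ids
    return float(adjusted_rand_score(p1.label_array(ids), p2.label_array(ids)))


def bootstrap_partitions(
    matrices: list[DissimilarityMatrix],
    spec: BootstrapSpec,
    method: str,
) -> list[Partition]:
    """Re-cluster bootstrap resamples of the participant pool.

    For each replicate: draw ``sample_size`` participants with
    replacement, average their matrices, embed at ``embed_dim``, then
    cluster at ``fixed_k`` with ``method`` (``"kmeans"`` on coordinates or
    ``"ward"`` on embedded distances).  Replicate ``b`` derives all of its
    randomness from ``(spec.seed, b)``, so the same seed re-runs the same
    resamples for either method.
    """
    if len(matrices) < 2:
        raise ValueError("bootstrap needs at least 2 participants")
    if method not in ("kmeans", "ward"):
        raise ValueError("method must be 'kmeans' or 'ward'")
    size = spec.sample_size or len(matrices)
    parts: list[Partition] = []
    for b in range(spec.n_replicates):
        ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(b,))
        rng = np.random.default_rng(ss)
        idx = rng.integers(len(matrices), size=size)
        avg = group_matrix([matrices[i] for i in idx])
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        fit = smacof_embed(
            avg, dim=spec.embed_dim, n_starts=spec.embed_starts, seed=sub_seed
        )
        if method == "kmeans":
            part, _ = kmeans_partition(
                fit.coordinates,
                spec.fixed_k,
                n_restarts=spec.kmeans_restarts,
                seed=sub_seed,
                object_ids=fit.object_ids,
            )
        else:
            part = cut_tree(ward_tree(fit.distances(), fit.object_ids), spec.fixed_k)
        parts.append(part)
    return parts


def _mean_pairwise_ari(parts: list[Partition]) -> float | None:
    if len(parts) < 2:
        return None
    vals = [adjusted_rand_index(a, b) for a, b in combinations(parts, 2)]
    return float(np.mean(vals))


def stability_summary(
    kmeans_parts: list[Partition], ward_parts: list[Partition]
) -> StabilityReport:
    """Mean ARIs within each method (all replicate pairs) and across methods.

    The cross-method mean pairs replicate ``b`` of one method with
    replicate ``b`` of the other, so both clusterings see the same
    bootstrap sample.  With fewer than two replicates the within-method
    means are undefined and reported as ``None``.
    """
    if len(kmeans_parts) != len(ward_parts):
        raise ValueError("partition lists must have equal length")
    cross = (
        float(
            np.mean(
                [adjusted_rand_index(a, b) for a, b in zip(kmeans_parts, ward_parts)]
            )
        )
        if kmeans_parts
        else None
    )
    return StabilityReport(
        mean_ari_kmeans=_mean_pairwise_ari(kmeans_parts),
        mean_ari_ward=_mean_pairwise_ari(ward_parts),
        mean_ari_cross=cross,
        n_replicates=len(kmeans_parts),
    )
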