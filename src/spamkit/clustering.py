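"""Global categories from the embedded configuration.

Two complementary clusterings of the MDS solution:

* k-means on the raw embedded coordinates (non-overlapping categories),
  with the cluster count chosen by the elbow of the squared-error
  distortion curve (mean squared distance of objects to their centroid);
* Ward agglomerative clustering on the embedded distance matrix, cut to a
  requested number of flat categories.  Because the embedded distances are
  Euclidean by construction, Ward's variance interpretation is exact.

Ranked pair tables are additionally binned into similarity quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .embedding import ElbowResult, kneedle_elbow

__all__ = [
    "Partition",
    "DistortionProfile",
    "Dendrogram",
    "kmeans_partition",
    "distortion_elbow",
    "ward_tree",
    "cut_tree",
    "quartile_bins",
]


@dataclass(frozen=True)
class Partition:
    """Assignment of every object to exactly one of ``k`` clusters."""

    labels: dict[int, int]  # object_id -> cluster index (1..k)
    k: int
    method: str

    def __post_init__(self) -> None:
        used = set(self.labels.values())
        if used != set(range(1, self.k + 1)):
            raise ValueError(f"labels must use every cluster 1..{self.k} at least once")

    def label_array(self, object_ids: Sequence[int] | None = None) -> np.ndarray:
        ids = sorted(self.labels) if object_ids is None else list(object_ids)
        return np.array([self.labels[i] for i in ids])

    @property
    def object_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.labels))


@dataclass(frozen=True)
class DistortionProfile:
    table: pd.DataFrame  # columns: k, distortion


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree in scipy linkage form.

    ``merges`` is the (n-1, 4) linkage matrix: each row merges the two
    listed clusters at the given height; new clusters are numbered from n
    upward in merge order.
    """

    merges: np.ndarray
    object_ids: tuple[int, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.object_ids)

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def merges_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.merges[:, :3], columns=["cluster_a", "cluster_b", "height"]
        )
        frame.insert(0, "step", np.arange(1, len(frame) + 1))
        return frame


def _relabel_canonical(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance (stable ids)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def kmeans_partition(
    X: np.ndarray,
    k: int,
    n_restarts: int = 50,
    seed: int = 0,
    object_ids: Sequence[int] | None = None,
) -> tuple[Partition, float]:
    """Best-of-restarts Lloyd k-means on embedded coordinates.

    Returns the partition and the squared-error distortion: the mean
    squared Euclidean distance from each object to its assigned centroid.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    ids = list(range(1, n + 1)) if object_ids is None else list(object_ids)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed % (2**32))
    raw = km.fit_predict(X)
    labels = _relabel_canonical(raw)
    distortion = float(km.inertia_ / n)
    part = Partition(labels=dict(zip(ids, labels.tolist())), k=k, method="kmeans")
    return part, distortion


def distortion_elbow(
    X: np.ndarray,
    k_range: Sequence[int],
    n_restarts: int = 50,
    seed: int = 0,
    sensitivity: float = 1.0,
) -> tuple[DistortionProfile, ElbowResult]:
    """Distortion curve over ``k_range`` plus its kneedle elbow."""
    ks = sorted(set(int(k) for k in k_range))
    rows = []
    for k in ks:
        _, distortion = kmeans_partition(X, k, n_restarts=n_restarts, seed=seed)
        rows.append({"k": k, "distortion": distortion})
    profile = DistortionProfile(table=pd.DataFrame(rows))
    elbow = kneedle_elbow(
        profile.table["k"], profile.table["distortion"], sensitivity=sensitivity
    )
    return profile, elbow


def ward_tree(
    D: np.ndarray, object_ids: Sequence[int] | None = None
) -> Dendrogram:
    """Ward agglomerative clustering of a distance matrix.

    Merges are chosen to minimize the increase in total within-cluster
    variance (Lance–Williams recurrence on the supplied distances); the
    resulting heights are monotone non-decreasing.
    """
    from .arrangement import DissimilarityMatrix
    from scipy.spatial.distance import squareform

    if isinstance(D, DissimilarityMatrix):
        object_ids = object_ids or D.object_ids
        D = D.values
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be a square distance matrix")
    n = D.shape[0]
    ids = tuple(range(1, n + 1)) if object_ids is None else tuple(object_ids)
    Z = linkage(squareform(D, checks=False), method="ward")
    return Dendrogram(merges=Z, object_ids=ids)


def cut_tree(dend: Dendrogram, c: int) -> Partition:
    """Flat partition into ``c`` clusters by undoing the last ``c-1`` merges."""
    n = dend.n_leaves
    if not 1 <= c <= n:
        raise ValueError(f"cluster count must be in [1, {n}]")
    raw = fcluster(dend.merges, t=c, criterion="maxclust")
    labels = _relabel_canonical(raw)
    return Partition(
        labels=dict(zip(dend.object_ids, labels.tolist())), k=int(labels.max()),
        method="ward",
    )


def quartile_bins(ranked_pairs: pd.DataFrame) -> pd.DataFrame:
    """Label rank-sorted pairs Q1 (most similar) .. Q4 (least similar).

    The split is by rank at the 25/50/75 percentiles; when the pair count
    is not divisible by four the earlier quartiles take the extra pair, so
    sizes differ by at most one.  Cutoff distances (the largest distance
    inside each quartile) are attached as an attribute ``cutoffs``.
    """
    n = len(ranked_pairs)
    if n < 4:
        raise ValueError("need at least 4 pairs to form quartiles")
    if not ranked_pairs["distance"].is_monotonic_increasing:
        raise ValueError("ranked_pairs must be sorted ascending by distance")
    base, extra = divmod(n, 4)
    sizes = [base + (1 if q < extra else 0) for q in range(4)]
    labels = np.repeat([f"Q{q + 1}" for q in range(4)], sizes)
    out = ranked_pairs.copy()
    out["quartile"] = labels
    cutoffs = out.groupby("quartile")["distance"].max().to_dict()
    out.attrs["cutoffs"] = cutoffs
    return out
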