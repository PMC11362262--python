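"""Metric multidimensional scaling by majorization (SMACOF).

The group dissimilarity matrix is embedded in a low-dimensional Euclidean
space by minimizing raw stress,

    sigma(X) = sum_{i<j} (d_ij - dhat_ij(X))**2 ,

where ``d_ij`` is the observed (averaged) dissimilarity and ``dhat_ij`` the
Euclidean distance of the embedded coordinates.  Stress is kept
un-normalized: the configuration is fit to the dissimilarities at ratio
level, with no monotone re-estimation (metric MDS).  Each majorization step
applies the Guttman transform, which guarantees a non-increasing stress
sequence within a start; ruggedness across random starts is handled by
keeping the best of several initializations.

Dimensionality is chosen from a scree of mean stress over many random
starts per candidate dimension, with the elbow located by the discrete
kneedle algorithm (maximum of the normalized difference curve).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .arrangement import DissimilarityMatrix

__all__ = [
    "MDSResult",
    "StressProfile",
    "ElbowResult",
    "raw_stress",
    "smacof_embed",
    "stress_profile",
    "kneedle_elbow",
    "ranked_pair_table",
]


@dataclass(frozen=True)
class MDSResult:
    """An embedded configuration with its raw stress."""

    coordinates: np.ndarray  # (n_objects, dim)
    stress: float
    dim: int
    n_starts: int
    seed: int
    object_ids: tuple[int, ...]

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distance matrix of the configuration."""
        return squareform(pdist(self.coordinates))

    def coordinates_frame(self) -> pd.DataFrame:
        cols = [f"dim{k + 1}" for k in range(self.dim)]
        frame = pd.DataFrame(self.coordinates, columns=cols)
        frame.insert(0, "object_id", self.object_ids)
        return frame


@dataclass(frozen=True)
class StressProfile:
    """Mean/sd of stress over random-start replicates, per dimensionality."""

    table: pd.DataFrame  # columns: dim, mean_stress, sd_stress, n_replicates

    @property
    def dims(self) -> np.ndarray:
        return self.table["dim"].to_numpy()

    @property
    def mean_stress(self) -> np.ndarray:
        return self.table["mean_stress"].to_numpy()


@dataclass(frozen=True)
class ElbowResult:
    x_at_elbow: float | None
    found: bool
    sensitivity: float


def _check_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if np.any(~np.isfinite(D)):
        raise ValueError("D has missing or non-finite entries; metric MDS needs a complete matrix")
    if not np.allclose(D, D.T):
        raise ValueError("D must be symmetric")
    if np.any(D < 0):
        raise ValueError("D must be non-negative")
    return D


def raw_stress(D: np.ndarray | DissimilarityMatrix, X: np.ndarray) -> float:
    """Un-normalized raw stress sum_{i<j} (d_ij - dhat_ij(X))^2."""
    if isinstance(D, DissimilarityMatrix):
        D = D.values
    D = _check_dissimilarity(D)
    X = np.asarray(X, dtype=float)
    if X.shape[0] != D.shape[0]:
        raise ValueError("X and D disagree on the number of objects")
    d = squareform(D, checks=False)
    dhat = pdist(X)
    return float(np.sum((d - dhat) ** 2))


def _guttman_iterate(
    D: np.ndarray, X: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, list[float]]:
    """Majorize raw stress from one start; returns (X, stress, trace)."""
    n = D.shape[0]
    d = squareform(D, checks=False)
    stress = float(np.sum((d - pdist(X)) ** 2))
    trace = [stress]
    for _ in range(max_iter):
        dist = squareform(pdist(X))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, D / np.where(dist > 0, dist, 1.0), 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = B @ X / n
        new_stress = float(np.sum((d - pdist(X)) ** 2))
        trace.append(new_stress)
        if stress - new_stress < tol * max(stress, np.finfo(float).tiny):
            stress = new_stress
            break
        stress = new_stress
    return X, stress, trace


def smacof_embed(
    D: np.ndarray | DissimilarityMatrix,
    dim: int,
    n_starts: int = 8,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
    return_traces: bool = False,
):
    """Best-of-``n_starts`` metric SMACOF embedding of ``D`` in ``dim`` dims.

    Starts are drawn uniformly in a hypercube scaled to ``mean(D)``; start
    ``s`` uses an RNG seeded from ``(seed, s)``.  Within each start the
    Guttman transform is iterated until the relative stress decrease drops
    below ``tol`` or ``max_iter`` is reached.

    With ``return_traces`` the per-iteration stress sequences of every
    start are returned alongside the result (used to verify monotone
    convergence).
    """
    ids: tuple[int, ...]
    if isinstance(D, DissimilarityMatrix):
        ids = D.object_ids
        D = D.values
    else:
        D = np.asarray(D, dtype=float)
        ids = tuple(range(1, D.shape[0] + 1))
    D = _check_dissimilarity(D)
    if dim < 1:
        raise ValueError("dim must be >= 1")
    n = D.shape[0]
    scale = float(D.mean()) or 1.0
    best: tuple[np.ndarray, float] | None = None
    traces: list[list[float]] = []
    for s in range(n_starts):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(s,)))
        X0 = rng.uniform(-scale, scale, size=(n, dim))
        X, stress, trace = _guttman_iterate(D, X0, max_iter, tol)
        traces.append(trace)
        if best is None or stress < best[1]:
            best = (X, stress)
    assert best is not None
    result = MDSResult(
        coordinates=best[0],
        stress=best[1],
        dim=dim,
        n_starts=n_starts,
        seed=seed,
        object_ids=ids,
    )
    if return_traces:
        return result, traces
    return result


def stress_profile(
    D: np.ndarray | DissimilarityMatrix,
    dims: Sequence[int],
    replicates: int = 1000,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> StressProfile:
    """Mean and sd of stress over independently initialized fits per dim.

    Each replicate is a single random start, so the profile reflects the
    stress landscape a one-shot fit would sample — the averaging is what
    stabilizes the scree curve against initialization noise.
    """
    dims = sorted(set(int(d) for d in dims))
    if not dims:
        raise ValueError("dims must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for d in dims:
        stresses = np.empty(replicates)
        for r in range(replicates):
            fit = smacof_embed(
                D, d, n_starts=1, max_iter=max_iter, tol=tol,
                seed=int(np.random.SeedSequence(entropy=seed, spawn_key=(d, r)).generate_state(1)[0] % (2**31)),
            )
            stresses[r] = fit.stress
        rows.append(
            {
                "dim": d,
                "mean_stress": float(stresses.mean()),
                "sd_stress": float(stresses.std(ddof=1)) if replicates > 1 else 0.0,
                "n_replicates": replicates,
            }
        )
    return StressProfile(table=pd.DataFrame(rows))


def kneedle_elbow(
    xs: Sequence[float], ys: Sequence[float], sensitivity: float = 1.0
) -> ElbowResult:
    """Discrete kneedle elbow detector for decreasing convex curves.

    Both axes are min-max normalized; for a decreasing convex curve (a
    scree or distortion plot) the difference curve is
    ``d_i = 1 - x_i - y_i``, whose local maxima are elbow candidates.  A
    candidate is confirmed when the difference curve falls below its value
    minus ``sensitivity`` times the mean normalized x-spacing before the
    next local maximum (or the end of the curve).  On (near-)linear input
    the difference curve stays below threshold and no elbow is reported.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.ndim != 1 or xs.shape != ys.shape or len(xs) < 3:
        raise ValueError("xs and ys must be equal-length 1-d arrays with >= 3 points")
    if np.any(np.diff(xs) <= 0):
        raise ValueError("xs must be strictly increasing")
    if ys.max() == ys.min():
        return ElbowResult(None, False, sensitivity)
    x_n = (xs - xs[0]) / (xs[-1] - xs[0])
    y_n = (ys - ys.min()) / (ys.max() - ys.min())
    if ys[0] >= ys[-1]:  # decreasing scree: elbow of the convex curve
        diff = 1.0 - x_n - y_n
    else:  # increasing curve: knee of the mirrored problem
        diff = y_n - x_n
    mean_dx = float(np.mean(np.diff(x_n)))
    threshold_drop = sensitivity * mean_dx

    # local maxima of the difference curve (strictly above both neighbours,
    # plateaus resolved to their first point)
    candidates = []
    for i in range(1, len(diff) - 1):
        if diff[i] >= diff[i - 1] and diff[i] > diff[i + 1]:
            candidates.append(i)
    for i in candidates:
        threshold = diff[i] - threshold_drop
        j = i + 1
        while j < len(diff):
            if diff[j] >= diff[i] and j in candidates:
                break  # a higher local max takes over
            if diff[j] < threshold:
                return ElbowResult(float(xs[i]), True, sensitivity)
            j += 1
    return ElbowResult(None, False, sensitivity)


def ranked_pair_table(result: MDSResult) -> pd.DataFrame:
    """All object pairs sorted by embedded distance, most similar first.

    Ties keep lexical ``(object_i, object_j)`` order; ``rank`` is 1-based.
    """
    dist = result.distances()
    ids = result.object_ids
    rows = [
        (ids[i], ids[j], dist[i, j])
        for i, j in combinations(range(len(ids)), 2)
    ]
    frame = pd.DataFrame(rows, columns=["object_i", "object_j", "distance"])
    frame = frame.sort_values(
        ["distance", "object_i", "object_j"], kind="stable"
    ).reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame
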