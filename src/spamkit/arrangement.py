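"""From canvas arrangements to dissimilarity matrices.

Participants drag objects on a fixed-size canvas so that similar objects
end up close together.  The only quantity carried forward is the Euclidean
distance in pixels between the final centers of each pair of objects shown
in the same trial.  Pairs seen in several trials are averaged within a
participant; the group matrix is the element-wise mean over participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .designgen import TrialDesign

__all__ = [
    "CANVAS_WIDTH",
    "CANVAS_HEIGHT",
    "DissimilarityMatrix",
    "trial_pair_distances",
    "participant_matrix",
    "group_matrix",
    "read_arrangements",
    "write_arrangements",
]

#: Default canvas size in pixels (origin top-left, y increases downward).
CANVAS_WIDTH = 1000
CANVAS_HEIGHT = 600

ARRANGEMENT_COLUMNS = ["participant_id", "trial_index", "object_id", "x_px", "y_px"]


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric zero-diagonal matrix of pairwise dissimilarities.

    ``values[i, j]`` is the (averaged) canvas distance between objects
    ``object_ids[i]`` and ``object_ids[j]``; ``provenance`` names the
    participant it came from, or ``"group"`` for the across-participant
    average.
    """

    values: np.ndarray
    object_ids: tuple[int, ...]
    provenance: str = "group"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if v.shape[0] != len(self.object_ids):
            raise ValueError("object_ids length must match matrix size")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("dissimilarities must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def n_objects(self) -> int:
        return len(self.object_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed (pdist) order."""
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.object_ids, columns=self.object_ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="object_id")

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "group") -> "DissimilarityMatrix":
        frame = pd.read_csv(path, index_col=0)
        ids = tuple(int(i) for i in frame.index)
        return cls(values=frame.to_numpy(dtype=float), object_ids=ids, provenance=provenance)


def trial_pair_distances(trial_records: pd.DataFrame) -> pd.DataFrame:
    """Pairwise center distances within a single participant-trial.

    Parameters
    ----------
    trial_records:
        Rows of one participant-trial with columns ``object_id``, ``x_px``,
        ``y_px``.

    Returns
    -------
    A frame with columns ``object_i``, ``object_j`` (``i < j``) and
    ``distance`` in pixels, one row per within-trial unordered pair.
    """
    if len(trial_records) < 2:
        raise ValueError("a trial needs at least 2 objects")
    ids = trial_records["object_id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValueError("duplicate object in trial")
    order = np.argsort(ids)
    ids = ids[order]
    xy = trial_records[["x_px", "y_px"]].to_numpy(dtype=float)[order]
    d = pdist(xy)
    pairs = list(combinations(ids.tolist(), 2))
    return pd.DataFrame(
        {
            "object_i": [p[0] for p in pairs],
            "object_j": [p[1] for p in pairs],
            "distance": d,
        }
    )


def participant_matrix(
    records: pd.DataFrame,
    design: TrialDesign,
    *,
    normalize_coords: bool = False,
    canvas: tuple[int, int] = (CANVAS_WIDTH, CANVAS_HEIGHT),
) -> DissimilarityMatrix:
    """Average within-trial pair distances into one participant's matrix.

    A pair measured in several trials contributes the arithmetic mean of
    its per-trial distances.  Under a covering design every off-diagonal
    entry is populated; a pair never co-displayed raises an error naming
    the offenders.

    With ``normalize_coords`` the distances are divided by the canvas
    diagonal before averaging, yielding unit-free entries in [0, 1]·√2
    range; default is raw pixels.
    """
    n = design.n_objects
    pids = records["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError("participant_matrix expects records of a single participant")
    scale = float(np.hypot(*canvas)) if normalize_coords else 1.0
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for _, trial in records.groupby("trial_index", sort=True):
        pairs = trial_pair_distances(trial)
        i = pairs["object_i"].to_numpy() - 1
        j = pairs["object_j"].to_numpy() - 1
        sums[i, j] += pairs["distance"].to_numpy() / scale
        counts[i, j] += 1
    missing = [
        (a + 1, b + 1)
        for a in range(n)
        for b in range(a + 1, n)
        if counts[a, b] == 0
    ]
    if missing:
        raise ValueError(f"pairs never co-displayed: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    upper = np.triu(sums, 1) / np.where(counts == 0, 1, counts)
    values = upper + upper.T
    return DissimilarityMatrix(
        values=values,
        object_ids=tuple(range(1, n + 1)),
        provenance=str(pids[0]),
    )


def group_matrix(matrices: list[DissimilarityMatrix]) -> DissimilarityMatrix:
    """Element-wise mean of per-participant matrices."""
    if not matrices:
        raise ValueError("need at least one participant matrix")
    ids = matrices[0].object_ids
    for m in matrices:
        if m.object_ids != ids:
            raise ValueError("participant matrices disagree on object sets")
    stacked = np.stack([m.values for m in matrices])
    return DissimilarityMatrix(
        values=stacked.mean(axis=0), object_ids=ids, provenance="group"
    )


def read_arrangements(path: str | Path) -> pd.DataFrame:
    """Load an arrangements CSV (participant_id, trial_index, object_id, x_px, y_px)."""
    frame = pd.read_csv(path)
    missing = set(ARRANGEMENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"arrangements file missing columns: {sorted(missing)}")
    return frame[ARRANGEMENT_COLUMNS]


def write_arrangements(records: pd.DataFrame, path: str | Path) -> None:
    records[ARRANGEMENT_COLUMNS].to_csv(path, index=False)
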