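"""Pair-covering trial designs for spatial arrangement experiments.

A spatial arrangement study shows ``block_size`` objects per trial; the
inter-object distances a participant produces only inform the object pairs
that appear together on screen.  To estimate a complete dissimilarity matrix
every unordered pair of the ``n_objects`` stimuli must co-occur in at least
one trial.  This module builds such covering designs with a randomized
greedy heuristic, audits their coverage, and sweeps the block size to find
the trial count each choice requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignParams",
    "TrialDesign",
    "CoverageReport",
    "count_pairs",
    "generate_blocks",
    "minimal_blocks",
    "sweep_block_size",
    "verify_coverage",
    "design_to_frame",
    "design_from_frame",
]


@dataclass(frozen=True)
class DesignParams:
    """Parameters of a randomized covering-design search.

    Parameters
    ----------
    n_objects:
        Total number of stimulus objects (ids are 1-based).
    block_size:
        Number of objects shown per trial.
    restarts:
        Independent randomized restarts used by :func:`minimal_blocks`.
    seed:
        Base seed; restart ``r`` uses ``seed + r``.
    """

    n_objects: int
    block_size: int
    restarts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_objects < 2:
            raise ValueError("n_objects must be at least 2")
        if not 2 <= self.block_size <= self.n_objects:
            raise ValueError("block_size must satisfy 2 <= block_size <= n_objects")
        if self.restarts < 1:
            raise ValueError("restarts must be at least 1")


@dataclass(frozen=True)
class TrialDesign:
    """An ordered list of trial blocks over objects ``1..n_objects``."""

    blocks: tuple[frozenset[int], ...]
    n_objects: int

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_lists(self) -> list[list[int]]:
        """Blocks as sorted id lists, in trial order."""
        return [sorted(b) for b in self.blocks]


@dataclass(frozen=True)
class CoverageReport:
    """Audit of which unordered pairs a design covers, and how often."""

    n_pairs_total: int
    n_pairs_covered: int
    multiplicity: dict[tuple[int, int], int]
    uncovered: tuple[tuple[int, int], ...]

    @property
    def valid(self) -> bool:
        return not self.uncovered


def count_pairs(n: int) -> int:
    """Number of unordered pairs among ``n`` objects, ``n*(n-1)/2``."""
    if n < 2:
        raise ValueError("need at least 2 objects to form a pair")
    return n * (n - 1) // 2


def _greedy_cover(n: int, k: int, rng: np.random.Generator) -> list[list[int]]:
    # covered[i, j] for i<j marks pairs already placed in some block
    covered = np.zeros((n, n), dtype=bool)
    iu = np.triu_indices(n, k=1)
    blocks: list[list[int]] = []
    while not covered[iu].all():
        # seed the block with a uniformly chosen uncovered pair
        open_i, open_j = np.nonzero(np.triu(~covered, k=1))
        pick = rng.integers(len(open_i))
        in_block = np.zeros(n, dtype=bool)
        in_block[open_i[pick]] = True
        in_block[open_j[pick]] = True
        while in_block.sum() < k:
            members = np.nonzero(in_block)[0]
            cand = np.nonzero(~in_block)[0]
            # gain = number of not-yet-covered pairs a candidate would add
            gain = (~covered[np.ix_(members, cand)]).sum(axis=0)
            best = np.nonzero(gain == gain.max())[0]
            chosen = cand[best[rng.integers(len(best))]]
            in_block[chosen] = True
        members = np.nonzero(in_block)[0]
        covered[np.ix_(members, members)] = True
        blocks.append((members + 1).tolist())  # 1-based ids
    return blocks


def generate_blocks(params: DesignParams) -> TrialDesign:
    """Build one randomized covering design.

    Blocks are grown greedily: each block is seeded with a currently
    uncovered pair and extended with the object adding the most uncovered
    pairs (ties broken uniformly at random), until all pairs are covered.
    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    if params.block_size == params.n_objects:
        return TrialDesign(
            blocks=(frozenset(range(1, params.n_objects + 1)),),
            n_objects=params.n_objects,
        )
    raw = _greedy_cover(params.n_objects, params.block_size, rng)
    return TrialDesign(
        blocks=tuple(frozenset(b) for b in raw), n_objects=params.n_objects
    )


def minimal_blocks(params: DesignParams) -> tuple[int, TrialDesign]:
    """Best design over ``params.restarts`` independent greedy restarts.

    Returns the smallest block count achieved and the first design
    attaining it (restart ``r`` is seeded with ``params.seed + r``).
    """
    best: TrialDesign | None = None
    for r in range(params.restarts):
        d = generate_blocks(
            DesignParams(params.n_objects, params.block_size, 1, params.seed + r)
        )
        if best is None or d.n_blocks < best.n_blocks:
            best = d
    assert best is not None
    return best.n_blocks, best


def sweep_block_size(
    n: int, k_range: Iterable[int], restarts: int, seed: int
) -> pd.DataFrame:
    """Minimal achieved block count per block size ``k``.

    Returns a frame with columns ``k`` and ``n_blocks`` (best over
    ``restarts`` restarts for each k; each k uses the same base seed so
    rows are independent searches).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range must be non-empty")
    rows = []
    for k in ks:
        if not 2 <= k <= n:
            raise ValueError(f"block size {k} outside [2, {n}]")
        count, _ = minimal_blocks(DesignParams(n, k, restarts, seed))
        rows.append({"k": k, "n_blocks": count})
    return pd.DataFrame(rows)


def verify_coverage(design: TrialDesign) -> CoverageReport:
    """Exact per-pair co-occurrence audit of a design."""
    n = design.n_objects
    mult: dict[tuple[int, int], int] = {p: 0 for p in combinations(range(1, n + 1), 2)}
    for block in design.blocks:
        for obj in block:
            if not 1 <= obj <= n:
                raise ValueError(f"object id {obj} outside 1..{n}")
        for pair in combinations(sorted(block), 2):
            mult[pair] += 1
    uncovered = tuple(p for p, c in mult.items() if c == 0)
    return CoverageReport(
        n_pairs_total=count_pairs(n),
        n_pairs_covered=sum(1 for c in mult.values() if c > 0),
        multiplicity=mult,
        uncovered=uncovered,
    )


def design_to_frame(design: TrialDesign) -> pd.DataFrame:
    """Long-format table: trial_index (1-based), slot (1..K), object_id."""
    rows = []
    for t, block in enumerate(design.block_lists(), start=1):
        for s, obj in enumerate(block, start=1):
            rows.append({"trial_index": t, "slot": s, "object_id": obj})
    return pd.DataFrame(rows)


def design_from_frame(frame: pd.DataFrame, n_objects: int | None = None) -> TrialDesign:
    """Rebuild a :class:`TrialDesign` from its long-format table."""
    if n_objects is None:
        n_objects = int(frame["object_id"].max())
    blocks = [
        frozenset(int(o) for o in grp["object_id"])
        for _, grp in frame.sort_values("trial_index").groupby("trial_index", sort=True)
    ]
    return TrialDesign(blocks=tuple(blocks), n_objects=n_objects)
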