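"""Shared fixtures: designs, synthetic worlds and derived matrices.

Session-scoped fixtures cache the expensive simulation products (a full
96-participant world and its group matrix) so the suite stays fast while
every stage is exercised on realistic inputs.
"""

from __future__ import annotations

import numpy as np
import pytest

from spamkit import arrangement as ar
from spamkit import designgen as dg
from spamkit import embedding as em
from spamkit import synthetic as sy


@pytest.fixture(scope="session")
def paper_design() -> dg.TrialDesign:
    """A 30-object, 16-per-trial covering design (6 blocks)."""
    _, design = dg.minimal_blocks(dg.DesignParams(30, 16, restarts=100, seed=11))
    return design


@pytest.fixture(scope="session")
def default_world() -> sy.LatentWorld:
    return sy.make_world(seed=0)


@pytest.fixture(scope="session")
def default_arrangements(default_world, paper_design):
    return sy.simulate_arrangements(default_world, paper_design, seed=0)


@pytest.fixture(scope="session")
def participant_matrices(default_arrangements, paper_design):
    return [
        ar.participant_matrix(grp, paper_design)
        for _, grp in default_arrangements.groupby("participant_id", sort=True)
    ]


@pytest.fixture(scope="session")
def group_dissimilarity(participant_matrices):
    return ar.group_matrix(participant_matrices)


@pytest.fixture(scope="session")
def embedded_3d(group_dissimilarity):
    return em.smacof_embed(group_dissimilarity, dim=3, n_starts=8, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
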