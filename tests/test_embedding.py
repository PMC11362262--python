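"""SMACOF embedding, stress, scree simulation and kneedle elbow."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from spamkit import embedding as em
from spamkit import synthetic as sy


def euclidean_matrix(points: np.ndarray) -> np.ndarray:
    return squareform(pdist(points))


# ---------------------------------------------------------------- raw stress

def test_raw_stress_zero_for_perfect_fit(rng):
    X = rng.normal(size=(10, 3))
    assert em.raw_stress(euclidean_matrix(X), X) == pytest.approx(0.0, abs=1e-20)


def test_raw_stress_matches_hand_sum():
    D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    X = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 3.0]])
    expected = 0.0
    for i in range(3):  # brute-force double loop over i < j
        for j in range(i + 1, 3):
            dhat = np.linalg.norm(X[i] - X[j])
            expected += (D[i, j] - dhat) ** 2
    assert em.raw_stress(D, X) == pytest.approx(expected)


def test_raw_stress_invariant_under_rigid_motion(rng):
    X = rng.normal(size=(8, 2))
    D = euclidean_matrix(rng.normal(size=(8, 2)))
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = X @ R.T + np.array([5.0, -3.0])
    assert em.raw_stress(D, moved) == pytest.approx(em.raw_stress(D, X))


def test_raw_stress_rejects_asymmetric_input():
    with pytest.raises(ValueError):
        em.raw_stress(np.array([[0.0, 1.0], [2.0, 0.0]]), np.zeros((2, 1)))


# -------------------------------------------------------------------- SMACOF

def test_smacof_recovers_exact_three_dim_distances(rng):
    pts = rng.normal(size=(30, 3))
    D = euclidean_matrix(pts)
    fit = em.smacof_embed(D, dim=3, n_starts=8, seed=0)
    assert fit.stress < 1e-6 * np.sum(squareform(D) ** 2)
    rel = np.abs(squareform(fit.distances()) - squareform(D)) / squareform(D)
    assert rel.max() < 1e-4


def test_equilateral_triangle_fits_plane_not_line():
    D = np.ones((3, 3)) - np.eye(3)
    flat = em.smacof_embed(D, dim=2, n_starts=8, seed=0)
    line = em.smacof_embed(D, dim=1, n_starts=8, seed=0)
    assert flat.stress == pytest.approx(0.0, abs=1e-10)
    assert line.stress > 1e-2


def test_more_starts_never_worse(group_dissimilarity):
    one = em.smacof_embed(group_dissimilarity, dim=2, n_starts=1, seed=5)
    many = em.smacof_embed(group_dissimilarity, dim=2, n_starts=20, seed=5)
    assert many.stress <= one.stress + 1e-12


def test_stress_non_increasing_within_each_start(rng):
    D = euclidean_matrix(rng.normal(size=(12, 4)))
    _, traces = em.smacof_embed(D, dim=2, n_starts=5, seed=2, return_traces=True)
    for trace in traces:
        diffs = np.diff(trace)
        assert np.all(diffs <= 1e-9 * max(trace))


def test_ratio_scale_handling(rng):
    """Doubling the input dissimilarities doubles the recovered distances."""
    D = euclidean_matrix(rng.normal(size=(15, 3)))
    a = em.smacof_embed(D, dim=3, n_starts=4, seed=9)
    b = em.smacof_embed(2.0 * D, dim=3, n_starts=4, seed=9)
    ratio = squareform(b.distances()) / squareform(a.distances())
    assert np.allclose(ratio, 2.0, rtol=1e-3)


def test_incomplete_matrix_rejected():
    D = np.array([[0.0, np.nan], [np.nan, 0.0]])
    with pytest.raises(ValueError, match="complete"):
        em.smacof_embed(D, dim=1)


# ------------------------------------------------------------- stress profile

def test_stress_profile_flags_latent_dimension(rng):
    pts = rng.normal(size=(25, 3))
    profile = em.stress_profile(euclidean_matrix(pts), range(1, 6), replicates=20, seed=0)
    mean = profile.mean_stress
    assert mean[2] < 1e-3 * mean[0]  # dims >= 3 fit essentially perfectly
    assert mean[3] < 1e-3 * mean[0]
    assert mean[1] > 50 * mean[2]  # dims 1-2 strictly worse


def test_stress_profile_non_increasing_in_dim(group_dissimilarity):
    profile = em.stress_profile(group_dissimilarity, range(1, 7), replicates=20, seed=3)
    mean = profile.mean_stress
    assert np.all(np.diff(mean) <= 0.05 * mean[0])


def test_stress_profile_single_replicate(group_dissimilarity):
    profile = em.stress_profile(group_dissimilarity, [2, 3], replicates=1, seed=4)
    assert list(profile.table["n_replicates"]) == [1, 1]
    assert list(profile.table["sd_stress"]) == [0.0, 0.0]


# ------------------------------------------------------------------- kneedle

def kneedle_oracle(xs, ys):
    """Direct enumeration of the normalized difference curve maximum."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    x_n = (xs - xs[0]) / (xs[-1] - xs[0])
    y_n = (ys - ys.min()) / (ys.max() - ys.min())
    diff = 1.0 - x_n - y_n
    return xs[int(np.argmax(diff))]


def test_kneedle_on_documented_curve():
    result = em.kneedle_elbow(np.arange(1, 7), [10, 5, 2, 1.9, 1.85, 1.8])
    assert result.found and result.x_at_elbow == 3


def test_kneedle_linear_curve_has_no_elbow():
    xs = np.arange(1, 8)
    assert not em.kneedle_elbow(xs, 10.0 - xs).found
    assert not em.kneedle_elbow(xs, np.full(7, 3.0)).found


def test_kneedle_matches_difference_curve_argmax():
    xs = np.arange(1, 11, dtype=float)
    ys = 1.0 / xs
    result = em.kneedle_elbow(xs, ys)
    assert result.found
    assert result.x_at_elbow == kneedle_oracle(xs, ys)


def test_kneedle_rejects_bad_grids():
    with pytest.raises(ValueError):
        em.kneedle_elbow([1, 1, 2], [3, 2, 1])
    with pytest.raises(ValueError):
        em.kneedle_elbow([1, 2], [3, 2])


@pytest.mark.parametrize("latent_dim", [2, 3])
def test_elbow_recovers_latent_dimensionality(latent_dim, rng):
    """Noiseless distances from a d*-dimensional configuration produce a
    scree whose kneedle elbow sits at d*."""
    world = sy.make_world(sy.WorldParams(latent_dim=latent_dim), seed=21)
    D = world.latent_distances()
    profile = em.stress_profile(D, range(1, 11), replicates=50, seed=21)
    result = em.kneedle_elbow(profile.dims, profile.mean_stress)
    assert result.found
    assert result.x_at_elbow == latent_dim


# ------------------------------------------------------------- ranked pairs

def test_ranked_pair_table_sorted_and_complete(embedded_3d):
    table = em.ranked_pair_table(embedded_3d)
    assert len(table) == 435
    assert table["distance"].is_monotonic_increasing
    dist = embedded_3d.distances()
    iu = np.triu_indices(30, k=1)
    assert table["distance"].iloc[0] == pytest.approx(dist[iu].min())
    # agrees with a brute-force sort of all pair distances
    assert np.allclose(np.sort(dist[iu]), table["distance"].to_numpy())
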