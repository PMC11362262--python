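"""Novelty rates, synonym coding, identity agreement and consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spamkit import novelty as nv
from spamkit import synthetic as sy


def naming_frame(rows):
    return pd.DataFrame(
        rows, columns=["participant_id", "object_id", "seen_before", "concepts"]
    )


# -------------------------------------------------------------------- coding

def test_synonyms_collapse_to_single_concept():
    records = naming_frame([("p1", 1, "yes", "half circle")])
    coded = nv.code_responses(records, {"half circle": "semicircle"})
    assert coded["coded_concepts"].iloc[0] == ["semicircle"]
    assert bool(coded["single_concept"].iloc[0])
    assert coded["top_coded"].iloc[0] == "semicircle"


def test_hybrid_and_empty_responses_are_not_single_concept():
    records = naming_frame(
        [("p1", 1, "no", "rainbow;prism"), ("p2", 1, "no", "")]
    )
    coded = nv.code_responses(records, {})
    assert list(coded["single_concept"]) == [False, False]
    assert coded["coded_concepts"].iloc[0] == ["rainbow", "prism"]


def test_unmapped_tokens_pass_through():
    coded = nv.code_responses(naming_frame([("p1", 1, "yes", "doodad")]), {"x": "y"})
    assert coded["coded_concepts"].iloc[0] == ["doodad"]


def test_repeated_synonyms_still_single_concept():
    coded = nv.code_responses(
        naming_frame([("p1", 1, "yes", "half circle;semicircle")]),
        {"half circle": "semicircle"},
    )
    assert bool(coded["single_concept"].iloc[0])


# -------------------------------------------------------------- novelty rate

def test_novelty_rate_counts_no_answers():
    records = naming_frame(
        [("p%d" % i, 1, "no" if i < 4 else "yes", "") for i in range(8)]
    )
    assert nv.novelty_rate(records) == pytest.approx(50.0)
    all_yes = naming_frame([("p1", 1, "yes", ""), ("p2", 1, "yes", "")])
    assert nv.novelty_rate(all_yes) == 0.0
    with pytest.raises(ValueError):
        nv.novelty_rate(naming_frame([]))
    with pytest.raises(ValueError):
        nv.novelty_rate(naming_frame([("p1", 1, "maybe", "")]))


def test_planted_familiarity_recovered_within_binomial_bounds():
    world = sy.make_world(seed=5)
    naming, _ = sy.simulate_naming(world, seed=5)
    n = 96
    for obj in (1, 10, 30):
        rate = nv.novelty_rate(naming[naming["object_id"] == obj])
        p_no = 1.0 - world.familiarity[obj - 1]
        lo, hi = stats.binom.interval(0.999, n, p_no)
        assert lo / n * 100 <= rate <= hi / n * 100


# --------------------------------------------------------- identity agreement

def coded(rows, mapping=None):
    return nv.code_responses(naming_frame(rows), mapping or {})


def test_agreement_is_share_of_modal_concept():
    rows = [("p%d" % i, 1, "yes", "a") for i in range(3)] + [("p4", 1, "yes", "b")]
    top, agreement, tied = nv.identity_agreement(coded(rows))
    assert (top, tied) == ("a", False)
    assert agreement == pytest.approx(75.0)


def test_agreement_all_distinct_names():
    rows = [("p%d" % i, 1, "no", f"c{i}") for i in range(10)]
    _, agreement, _ = nv.identity_agreement(coded(rows))
    assert agreement == pytest.approx(10.0)


def test_agreement_undefined_without_single_concepts():
    rows = [("p1", 1, "no", "a;b"), ("p2", 1, "no", "")]
    top, agreement, tied = nv.identity_agreement(coded(rows))
    assert top is None and agreement is None and not tied


def test_agreement_tie_broken_lexically_and_flagged():
    rows = [("p1", 1, "yes", "zed"), ("p2", 1, "yes", "ant")]
    top, agreement, tied = nv.identity_agreement(coded(rows))
    assert top == "ant" and tied and agreement == pytest.approx(50.0)


def test_agreement_increases_with_name_concentration():
    """Median identity agreement rises with the concentration parameter."""
    medians = []
    for kappa in (0.02, 0.3):
        vals = []
        for seed in range(10):
            world = sy.make_world(
                sy.WorldParams(name_concentration=kappa), seed=seed
            )
            naming, smap = sy.simulate_naming(
                world, sy.BehaviorParams(n_participants=40), seed=seed
            )
            scores = nv.object_scores(nv.code_responses(naming, smap))
            vals.append(scores["identity_agreement"].dropna().mean())
        medians.append(np.median(vals))
    assert medians[0] < medians[1]


# ------------------------------------------------------------- summary stats

def test_summary_stats_basic_and_outlier(rng):
    out = nv.summary_stats(pd.Series([10.0, 20.0, 30.0]))
    assert out["mean"] == pytest.approx(20.0)
    assert (out["min"], out["max"]) == (10.0, 30.0)
    spiked = np.concatenate([np.full(29, 10.0) + rng.normal(0, 0.5, 29), [40.0]])
    flagged = nv.summary_stats(spiked)
    assert flagged["outlier_indices"] == [29]


def test_summary_sd_matches_two_pass_oracle(rng):
    v = rng.uniform(0, 100, size=37)
    mean = sum(v) / len(v)
    two_pass = (sum((x - mean) ** 2 for x in v) / (len(v) - 1)) ** 0.5
    assert nv.summary_stats(v)["sd"] == pytest.approx(two_pass)


# ------------------------------------------------------------------ spearman

def test_spearman_monotone_extremes():
    x = np.arange(10.0)
    assert nv.spearman(x, np.exp(x))[0] == pytest.approx(1.0)
    assert nv.spearman(x, -x**3)[0] == pytest.approx(-1.0)


def test_spearman_ties_match_average_rank_oracle(rng):
    from oracles import average_ranks

    x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0])
    y = rng.uniform(size=8)
    rho, df, _ = nv.spearman(x, y)
    rx, ry = average_ranks(x), average_ranks(y)
    expected = np.corrcoef(rx, ry)[0, 1]
    assert rho == pytest.approx(expected)
    assert df == 6


def test_spearman_rejects_degenerate_input():
    with pytest.raises(ValueError):
        nv.spearman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])  # too short
    with pytest.raises(ValueError):
        nv.spearman(np.ones(6), np.arange(6.0))


def test_novelty_and_agreement_negatively_related():
    """Familiarity drives both "yes" answers and name convergence, so
    novelty rate and identity agreement anti-correlate in the synthetic
    world (the sign, not the magnitude, is the claim)."""
    world = sy.make_world(seed=2)
    naming, smap = sy.simulate_naming(world, seed=2)
    scores = nv.object_scores(nv.code_responses(naming, smap))
    valid = scores.dropna(subset=["identity_agreement"])
    rho, _, p = nv.spearman(valid["novelty_rate"], valid["identity_agreement"])
    assert rho < 0
    assert p < 0.05


def test_object_scores_benchmark_flag():
    rows = [("p%d" % i, 1, "yes", "house") for i in range(9)] + [
        ("p9", 1, "yes", "barn")
    ]
    scores = nv.object_scores(coded(rows))
    assert not bool(scores["below_known_benchmark"].iloc[0])  # 90% > 85%
    rows2 = [("p%d" % i, 2, "no", f"c{i}") for i in range(10)]
    scores2 = nv.object_scores(coded(rows2))
    assert bool(scores2["below_known_benchmark"].iloc[0])
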