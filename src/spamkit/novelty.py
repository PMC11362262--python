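"""Novelty and naming-agreement scoring.

Each participant answers, per object, a yes/no "seen this category of
object before?" question and gives a free-form name or description.  The
descriptions arrive pre-coded as concept tokens; this module collapses
synonyms through a supplied map, computes per-object novelty rates
(percentage of "no" answers) and identity agreement (share of
single-concept responses using the most popular concept), flags outliers
and objects exceeding a known-object benchmark, and reports Spearman
consistency correlations between the measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KNOWN_BENCHMARK",
    "code_responses",
    "novelty_rate",
    "identity_agreement",
    "object_scores",
    "summary_stats",
    "spearman",
    "read_naming",
    "read_concept_map",
]

#: Identity-agreement level above which an object counts as "known"
#: rather than novel (percent).
KNOWN_BENCHMARK = 85.0

NAMING_COLUMNS = ["participant_id", "object_id", "seen_before", "concepts"]


def read_naming(path: str | Path) -> pd.DataFrame:
    """Load naming records; ``concepts`` is a semicolon-separated token list."""
    frame = pd.read_csv(path, keep_default_na=False)
    missing = set(NAMING_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"naming file missing columns: {sorted(missing)}")
    return frame[NAMING_COLUMNS]


def read_concept_map(path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(path)
    return dict(zip(frame["variant"], frame["canonical"]))


def _split_concepts(cell) -> list[str]:
    if isinstance(cell, list):
        return [str(c).strip() for c in cell if str(c).strip()]
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    return [tok.strip() for tok in str(cell).split(";") if tok.strip()]


def code_responses(
    records: pd.DataFrame, synonym_map: dict[str, str]
) -> pd.DataFrame:
    """Canonicalize concept tokens and mark single-concept responses.

    Every listed concept is replaced by its canonical form (unmapped
    tokens pass through unchanged); a response is single-concept when its
    canonical concepts reduce to exactly one distinct token.  Adds columns
    ``coded_concepts`` (list), ``single_concept`` (bool) and
    ``top_coded`` (the concept, for single-concept rows).
    """
    out = records.copy()
    coded = [
        [synonym_map.get(tok, tok) for tok in _split_concepts(cell)]
        for cell in out["concepts"]
    ]
    out["coded_concepts"] = coded
    uniques = [sorted(set(c)) for c in coded]
    out["single_concept"] = [len(u) == 1 for u in uniques]
    out["top_coded"] = [u[0] if len(u) == 1 else None for u in uniques]
    return out


def novelty_rate(object_records: pd.DataFrame) -> float:
    """Percentage of "no" answers to the seen-before question, 0..100."""
    if len(object_records) == 0:
        raise ValueError("no records for object")
    answers = object_records["seen_before"].str.lower()
    bad = ~answers.isin(["yes", "no"])
    if bad.any():
        raise ValueError(f"non yes/no answers: {answers[bad].unique().tolist()}")
    return float((answers == "no").mean() * 100)


def identity_agreement(
    coded_object_records: pd.DataFrame,
) -> tuple[str | None, float | None, bool]:
    """Most popular single-concept name and its share of single-concept responses.

    Returns ``(top_concept, agreement_percent, tied)``.  Agreement is the
    count of the modal canonical concept divided by the number of
    single-concept responses, in percent; ties are broken lexically and
    flagged.  With no single-concept responses the agreement is undefined
    and ``(None, None, False)`` is returned.
    """
    singles = coded_object_records.loc[
        coded_object_records["single_concept"], "top_coded"
    ]
    if len(singles) == 0:
        return None, None, False
    counts = singles.value_counts()
    top_count = counts.iloc[0]
    tied_tops = sorted(counts[counts == top_count].index)
    return (
        tied_tops[0],
        float(top_count / len(singles) * 100),
        len(tied_tops) > 1,
    )


def object_scores(
    coded_records: pd.DataFrame, benchmark: float = KNOWN_BENCHMARK
) -> pd.DataFrame:
    """Per-object novelty rate, identity agreement and benchmark flag."""
    rows = []
    for obj, grp in coded_records.groupby("object_id", sort=True):
        top, agreement, tied = identity_agreement(grp)
        rows.append(
            {
                "object_id": obj,
                "n_responses": len(grp),
                "novelty_rate": novelty_rate(grp),
                "n_single_concept": int(grp["single_concept"].sum()),
                "top_concept": top,
                "identity_agreement": agreement,
                "agreement_tied": tied,
                "below_known_benchmark": (
                    agreement < benchmark if agreement is not None else True
                ),
            }
        )
    return pd.DataFrame(rows)


def summary_stats(values: pd.Series | np.ndarray) -> dict:
    """Mean, sample SD (n-1), range and >2-SD outlier flags for a measure."""
    v = pd.Series(values).dropna().to_numpy(dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    outliers = np.nonzero(v > mean + 2 * sd)[0]
    return {
        "mean": mean,
        "sd": sd,
        "min": float(v.min()),
        "max": float(v.max()),
        "outlier_indices": outliers.tolist(),
    }


def spearman(x, y) -> tuple[float, int, float]:
    """Two-tailed Spearman rank correlation with average ranks for ties.

    Returns ``(rho, df, p)`` with ``df = n - 2`` and the p-value from the
    t transform of the rank correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise ValueError("x and y must be equal-length vectors with n >= 4")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero rank variance: correlation undefined")
    rho, _ = stats.pearsonr(rx, ry)
    n = len(x)
    df = n - 2
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return float(rho), df, p
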