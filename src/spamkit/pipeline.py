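"""End-to-end orchestration of the norming analysis.

Runs the stages in order — design audit, per-participant and group
dissimilarity matrices, stress scree with elbow-based dimensionality
selection, final embedding, dual clustering with distortion-elbow k
selection, bootstrap stability, optional color-confound check and novelty
scoring — writing each intermediate to disk so any stage can be re-run
standalone, and collecting the headline numbers in a machine-readable
report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arrangement as ar
from . import clustering as cl
from . import colorsim as cs
from . import designgen as dg
from . import embedding as em
from . import novelty as nv
from . import plots
from . import stability as st

log = logging.getLogger("spamkit")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and settings for a full pipeline run.

    ``design``, ``arrangements`` are required inputs; ``naming`` +
    ``concept_map`` enable the novelty stage and ``images_dir`` the color
    stage.  All randomness flows from ``seed``.
    """

    design: str
    arrangements: str
    out_dir: str
    naming: str | None = None
    concept_map: str | None = None
    images_dir: str | None = None
    seed: int = 0
    normalize_coords: bool = False
    dims: tuple[int, ...] = tuple(range(1, 11))
    stress_replicates: int = 100
    final_starts: int = 8
    k_range: tuple[int, ...] = tuple(range(1, 21))
    kmeans_restarts: int = 50
    bootstrap_replicates: int = 100
    fixed_k: int | None = None  # default: the distortion-elbow k

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("dims", "k_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(int(v) for v in raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for label, path in [("design", self.design), ("arrangements", self.arrangements),
                            ("naming", self.naming), ("concept_map", self.concept_map),
                            ("images_dir", self.images_dir)]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config path for {label} does not exist: {path}")
        if self.naming is not None and self.concept_map is None:
            raise ValueError("novelty stage needs both naming and concept_map")


def _timed(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _Timer()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the run report (also written
    as ``report.json`` in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    with _timed("design"):
        design_frame = pd.read_csv(config.design)
        design = dg.design_from_frame(design_frame)
        audit = dg.verify_coverage(design)
        report["design"] = {
            "n_blocks": design.n_blocks,
            "n_pairs_total": audit.n_pairs_total,
            "n_pairs_covered": audit.n_pairs_covered,
            "valid": audit.valid,
        }
        with open(out / "coverage.json", "w") as fh:
            json.dump(report["design"], fh, indent=2)
        if not audit.valid:
            raise ValueError(f"design does not cover all pairs: {audit.uncovered[:5]}...")

    with _timed("matrices"):
        records = ar.read_arrangements(config.arrangements)
        mats = [
            ar.participant_matrix(grp, design, normalize_coords=config.normalize_coords)
            for _, grp in records.groupby("participant_id", sort=True)
        ]
        group = ar.group_matrix(mats)
        group.to_csv(out / "group_matrix.csv")
        report["n_participants"] = len(mats)

    with _timed("embedding"):
        profile = em.stress_profile(
            group, config.dims, replicates=config.stress_replicates, seed=config.seed
        )
        profile.table.to_csv(out / "stress_profile.csv", index=False)
        elbow = em.kneedle_elbow(profile.dims, profile.mean_stress)
        selected_dim = int(elbow.x_at_elbow) if elbow.found else int(config.dims[-1])
        fit = em.smacof_embed(
            group, selected_dim, n_starts=config.final_starts, seed=config.seed
        )
        fit.coordinates_frame().to_csv(out / "coordinates.csv", index=False)
        pairs = em.ranked_pair_table(fit)
        plots.save_scree_plot(profile, elbow, out / "scree.png")
        report["embedding"] = {
            "selected_dim": selected_dim,
            "elbow_found": elbow.found,
            "stress": fit.stress,
        }

    with _timed("clustering"):
        profile_k, elbow_k = cl.distortion_elbow(
            fit.coordinates, config.k_range,
            n_restarts=config.kmeans_restarts, seed=config.seed,
        )
        profile_k.table.to_csv(out / "distortion_profile.csv", index=False)
        selected_k = int(elbow_k.x_at_elbow) if elbow_k.found else int(config.k_range[-1])
        km_part, distortion = cl.kmeans_partition(
            fit.coordinates, selected_k,
            n_restarts=config.kmeans_restarts, seed=config.seed,
            object_ids=fit.object_ids,
        )
        dend = cl.ward_tree(fit.distances(), fit.object_ids)
        dend.merges_frame().to_csv(out / "dendrogram.csv", index=False)
        plots.save_distortion_plot(profile_k, elbow_k, out / "distortion.png")
        plots.save_dendrogram_plot(dend, out / "dendrogram.png", cut=selected_k)
        ward_part = cl.cut_tree(dend, selected_k)
        pd.DataFrame(
            {
                "object_id": fit.object_ids,
                "kmeans_label": km_part.label_array(fit.object_ids),
                "ward_label": ward_part.label_array(fit.object_ids),
            }
        ).to_csv(out / "partitions.csv", index=False)
        binned = cl.quartile_bins(pairs)
        binned.to_csv(out / "pairs_ranked.csv", index=False)
        report["clustering"] = {
            "selected_k": selected_k,
            "elbow_found": elbow_k.found,
            "distortion": distortion,
            "ari_kmeans_vs_ward": st.adjusted_rand_index(km_part, ward_part),
            "quartile_cutoffs": {k: float(v) for k, v in binned.attrs["cutoffs"].items()},
        }

    with _timed("stability"):
        spec = st.BootstrapSpec(
            n_replicates=config.bootstrap_replicates,
            fixed_k=config.fixed_k or selected_k,
            embed_dim=selected_dim,
            seed=config.seed,
        )
        km_parts = st.bootstrap_partitions(mats, spec, "kmeans")
        ward_parts = st.bootstrap_partitions(mats, spec, "ward")
        summary = st.stability_summary(km_parts, ward_parts)
        report["stability"] = {
            "n_replicates": summary.n_replicates,
            "fixed_k": spec.fixed_k,
            "mean_ari_kmeans": summary.mean_ari_kmeans,
            "mean_ari_ward": summary.mean_ari_ward,
            "mean_ari_cross": summary.mean_ari_cross,
        }

    if config.images_dir is not None:
        with _timed("colorcheck"):
            pixel_sets = []
            for obj in fit.object_ids:
                path = Path(config.images_dir) / f"object_{obj}.png"
                pixel_sets.append(cs.downsample_and_mask(path, object_id=obj))
            color = cs.color_score_matrix(pixel_sets)
            idx = {o: i for i, o in enumerate(fit.object_ids)}
            color_vec = np.array(
                [color[idx[i], idx[j]] for i, j in zip(pairs["object_i"], pairs["object_j"])]
            )
            r, dfree, p = cs.color_shape_correlation(
                color_vec, pairs["distance"].to_numpy()
            )
            report["color"] = {"r": r, "df": dfree, "p": p}

    if config.naming is not None:
        with _timed("novelty"):
            naming = nv.read_naming(config.naming)
            concept_map = nv.read_concept_map(config.concept_map)
            coded = nv.code_responses(naming, concept_map)
            scores = nv.object_scores(coded)
            scores.to_csv(out / "novelty_report.csv", index=False)
            nov = nv.summary_stats(scores["novelty_rate"])
            agree = nv.summary_stats(scores["identity_agreement"])
            valid = scores.dropna(subset=["identity_agreement"])
            rho, dfree, p = nv.spearman(
                valid["novelty_rate"], valid["identity_agreement"]
            )
            report["novelty"] = {
                "novelty_rate_mean": nov["mean"],
                "novelty_rate_sd": nov["sd"],
                "identity_agreement_mean": agree["mean"],
                "identity_agreement_sd": agree["sd"],
                "spearman_rho": rho,
                "spearman_df": dfree,
                "spearman_p": p,
            }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
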