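"""Synthetic worlds and participant behavior.

The generator emulates the statistical structure the analysis pipeline
assumes so that every stage can be exercised without human data:

* a latent world of objects positioned in a low-dimensional space with
  planted cluster structure (cluster centers spread through a unit
  hypercube by farthest-point selection, members jittered around them);
* arrangement behavior: for each trial a participant lays the shown
  objects out on the canvas as a 2-d metric MDS solution of their
  attention-weighted latent dissimilarities (people arrange on a flat
  canvas no matter how many latent dimensions drive their similarity
  percept, and different people weight shape features differently on
  different trials — the individual-differences-scaling view), rescaled
  into the canvas with a margin, then perturbed with isotropic Gaussian
  placement noise and clipped to the canvas.  The varying attention
  weights are what let cross-trial and cross-participant averaging
  recover latent structure beyond two dimensions; with equal weights a
  converged 2-d layout systematically crushes the third latent axis;
* naming behavior: a yes/no familiarity answer drawn per object from a
  planted familiarity probability, and concept naming drawn from a
  per-object Chinese-restaurant process whose concentration controls name
  agreement (kappa -> infinity: everyone produces the same concept;
  kappa = 0: all concepts distinct);
* a color palette per object assigned independently of the latent
  geometry, so color similarity is null with respect to shape similarity
  by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .arrangement import CANVAS_HEIGHT, CANVAS_WIDTH
from .designgen import TrialDesign
from .embedding import smacof_embed

__all__ = [
    "WorldParams",
    "BehaviorParams",
    "LatentWorld",
    "make_world",
    "simulate_arrangements",
    "simulate_naming",
    "render_object_images",
]


@dataclass(frozen=True)
class WorldParams:
    """Structural parameters of a synthetic object world.

    Defaults mirror the study scale this pipeline targets: 30 objects in
    a 3-dimensional latent shape space with 7 planted categories of 2-6
    members.  ``cluster_spread`` is the within-cluster latent SD relative
    to a unit hypercube of centers; with ``whiten`` the finished object
    cloud is rescaled to equal RMS spread along every principal axis, so
    all latent dimensions are equally salient.  ``name_concentration``
    (kappa) tunes naming agreement via a Chinese-restaurant process with
    rate 1/kappa.
    """

    n_objects: int = 30
    latent_dim: int = 3
    n_clusters: int = 7
    min_cluster_size: int = 2
    max_cluster_size: int = 6
    cluster_spread: float = 0.05
    whiten: bool = True
    familiarity_range: tuple[float, float] = (0.31, 0.81)
    name_concentration: float = 0.05

    def __post_init__(self) -> None:
        if self.n_clusters > self.n_objects:
            raise ValueError("cannot plant more clusters than objects")
        if self.n_clusters * self.min_cluster_size > self.n_objects:
            raise ValueError("min_cluster_size infeasible")
        if self.n_clusters * self.max_cluster_size < self.n_objects:
            raise ValueError("max_cluster_size infeasible")
        if self.cluster_spread < 0 or self.name_concentration < 0:
            raise ValueError("spread and concentration must be non-negative")


@dataclass(frozen=True)
class BehaviorParams:
    """Participant behavior parameters.

    ``placement_noise`` is the isotropic per-object jitter SD in canvas
    pixels added after layout; 30 px is roughly a tenth of a typical
    inter-object distance on a 1000x600 canvas and plays the role of a
    careful participant.  ``attention_concentration`` is the Dirichlet
    concentration of the per-trial attention weights over latent
    dimensions (smaller = more idiosyncratic feature weighting; ``None``
    = equal weights on every trial).  Naming responses are single-concept with
    probability ``p_single``, hybrid (two concepts) with ``p_hybrid``,
    otherwise uncodable descriptions carrying no recognizable concept.
    """

    n_participants: int = 96
    placement_noise: float = 30.0
    canvas: tuple[int, int] = (CANVAS_WIDTH, CANVAS_HEIGHT)
    canvas_margin: float = 60.0
    attention_concentration: float | None = 0.5
    p_single: float = 0.56
    p_hybrid: float = 0.22

    def __post_init__(self) -> None:
        if self.placement_noise < 0:
            raise ValueError("placement noise must be non-negative")
        if self.attention_concentration is not None and self.attention_concentration <= 0:
            raise ValueError("attention_concentration must be positive (or None for equal weights)")
        if not 0 <= self.p_single + self.p_hybrid <= 1:
            raise ValueError("p_single + p_hybrid must lie in [0, 1]")


@dataclass(frozen=True)
class LatentWorld:
    """A sampled world: ground truth for recovery tests."""

    params: WorldParams
    coordinates: np.ndarray  # (n_objects, latent_dim)
    cluster_labels: np.ndarray  # (n_objects,), values 1..n_clusters
    familiarity: np.ndarray  # (n_objects,), per-object P("yes")
    palette: np.ndarray  # (n_objects, 3, 3) uint8 RGB triples
    seed: int

    @property
    def n_objects(self) -> int:
        return self.params.n_objects

    @property
    def object_ids(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_objects + 1))

    def latent_distances(self) -> np.ndarray:
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(self.coordinates))

    def truth_dict(self) -> dict:
        return {
            "cluster_labels": self.cluster_labels.tolist(),
            "coordinates": self.coordinates.tolist(),
            "familiarity": self.familiarity.tolist(),
            "latent_dim": self.params.latent_dim,
            "n_clusters": self.params.n_clusters,
            "seed": self.seed,
        }


def _cluster_sizes(params: WorldParams, rng: np.random.Generator) -> np.ndarray:
    sizes = np.full(params.n_clusters, params.min_cluster_size)
    remaining = params.n_objects - sizes.sum()
    while remaining > 0:
        open_idx = np.nonzero(sizes < params.max_cluster_size)[0]
        sizes[rng.choice(open_idx)] += 1
        remaining -= 1
    return sizes


def _spread_centers(
    n: int, dim: int, rng: np.random.Generator, iters: int = 600
) -> np.ndarray:
    # electrostatic repulsion inside the unit hypercube spreads centers to
    # near-uniform separation, so no planted category is accidentally easy
    # to merge with a neighbour
    X = rng.uniform(0.0, 1.0, size=(n, dim))
    for it in range(iters):
        step = 0.05 * (1 - it / iters) + 0.002
        diff = X[:, None, :] - X[None, :, :]
        d = np.linalg.norm(diff, axis=-1) + np.eye(n)
        force = (diff / (d**3)[..., None]).sum(axis=1)
        X = np.clip(X + step * force / np.abs(force).max(), 0.0, 1.0)
    return X


def _whiten(X: np.ndarray) -> np.ndarray:
    # equalize the RMS spread along every principal axis: the latent shape
    # dimensions are equally salient by construction
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    return U @ np.diag(np.full(len(s), np.sqrt((s**2).mean()))) @ Vt


def make_world(params: WorldParams = WorldParams(), seed: int = 0) -> LatentWorld:
    """Sample a reproducible latent world from structural parameters."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    sizes = _cluster_sizes(params, rng)
    centers = _spread_centers(params.n_clusters, params.latent_dim, rng)
    labels = np.repeat(np.arange(1, params.n_clusters + 1), sizes)
    rng.shuffle(labels)
    coords = centers[labels - 1] + rng.normal(
        0.0, params.cluster_spread, size=(params.n_objects, params.latent_dim)
    )
    if params.whiten:
        coords = _whiten(coords)
    lo, hi = params.familiarity_range
    familiarity = rng.uniform(lo, hi, size=params.n_objects)
    palette = rng.integers(0, 256, size=(params.n_objects, 3, 3), dtype=np.uint8)
    return LatentWorld(
        params=params,
        coordinates=coords,
        cluster_labels=labels,
        familiarity=familiarity,
        palette=palette,
        seed=seed,
    )


def _layout_trial(
    D_trial: np.ndarray,
    behavior: BehaviorParams,
    rng: np.random.Generator,
    layout_seed: int,
) -> np.ndarray:
    """Canvas positions for one trial: 2-d MDS of latent distances, scaled."""
    k = D_trial.shape[0]
    w, h = behavior.canvas
    m = behavior.canvas_margin
    if np.allclose(D_trial, 0.0):
        xy = np.zeros((k, 2))
    else:
        fit = smacof_embed(D_trial, dim=2, n_starts=1, seed=layout_seed)
        xy = fit.coordinates
    xy = xy - xy.min(axis=0)
    span = xy.max(axis=0)
    avail = np.array([w - 2 * m, h - 2 * m])
    scale = float(np.min(avail / np.where(span > 0, span, 1.0)))
    xy = xy * scale
    # center the used bounding box on the canvas
    xy = xy + (np.array([w, h]) - xy.max(axis=0) - xy.min(axis=0)) / 2
    xy = xy + rng.normal(0.0, behavior.placement_noise, size=xy.shape)
    xy[:, 0] = np.clip(xy[:, 0], 0, w)
    xy[:, 1] = np.clip(xy[:, 1], 0, h)
    return xy


def simulate_arrangements(
    world: LatentWorld,
    design: TrialDesign,
    behavior: BehaviorParams = BehaviorParams(),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated arrangement records for every participant and trial.

    Returns a frame with columns ``participant_id``, ``trial_index``,
    ``object_id``, ``x_px``, ``y_px``; participants are labeled
    ``p001, p002, ...``.
    """
    if design.n_objects != world.n_objects:
        raise ValueError("design and world disagree on the number of objects")
    blocks = design.block_lists()
    dim = world.params.latent_dim
    rows: list[dict] = []
    for p in range(behavior.n_participants):
        pid = f"p{p + 1:03d}"
        for t, block in enumerate(blocks, start=1):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(p, t))
            rng = np.random.default_rng(ss)
            layout_seed = int(ss.generate_state(2)[1] % (2**31))
            idx = np.array(block) - 1
            if behavior.attention_concentration is None:
                w = np.ones(dim)
            else:
                w = rng.dirichlet(np.full(dim, behavior.attention_concentration)) * dim
            diffs = world.coordinates[idx][:, None, :] - world.coordinates[idx][None, :, :]
            D_trial = np.sqrt((w * diffs**2).sum(axis=-1))
            xy = _layout_trial(D_trial, behavior, rng, layout_seed)
            for obj, (x, y) in zip(block, xy):
                rows.append(
                    {
                        "participant_id": pid,
                        "trial_index": t,
                        "object_id": obj,
                        "x_px": float(x),
                        "y_px": float(y),
                    }
                )
    return pd.DataFrame(rows)


def _draw_concept(
    counts: dict[str, int], kappa: float, obj: int, rng: np.random.Generator
) -> str:
    """Chinese-restaurant draw over canonical concepts for one object."""
    total = sum(counts.values())
    if kappa == 0:  # every response a fresh concept
        name = f"o{obj}c{len(counts) + 1}"
        counts[name] = counts.get(name, 0) + 1
        return name
    alpha = 1.0 / kappa
    if total == 0 or rng.random() < alpha / (alpha + total):
        name = f"o{obj}c{len(counts) + 1}"
    else:
        names = sorted(counts)
        weights = np.array([counts[n] for n in names], dtype=float)
        name = names[rng.choice(len(names), p=weights / weights.sum())]
    counts[name] = counts.get(name, 0) + 1
    return name


def simulate_naming(
    world: LatentWorld,
    behavior: BehaviorParams = BehaviorParams(),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Simulated naming records plus the synonym map that collapses them.

    Each canonical concept surfaces as one of two spelling variants
    (``<concept>_v1`` / ``<concept>_v2``); the returned map sends both
    back to the canonical token, exercising synonym collapsing downstream.
    ``seen_before`` is Bernoulli in the object's planted familiarity, and
    the naming concentration of object ``o`` is
    ``name_concentration * odds(familiarity_o)``: familiar objects both
    elicit "yes" answers and converge on a shared name, so novelty rate
    and identity agreement are negatively coupled as in real norming data.
    """
    rows: list[dict] = []
    synonym_map: dict[str, str] = {}

    def surface(name: str, rng: np.random.Generator) -> str:
        variant = f"{name}_v{rng.integers(1, 3)}"
        synonym_map[variant] = name
        return variant

    for obj in world.object_ids:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(obj,)))
        counts: dict[str, int] = {}
        fam = float(world.familiarity[obj - 1])
        base = world.params.name_concentration
        # familiarity-linked concentration; guard the degenerate edges
        if fam >= 1.0 or base == np.inf:
            kappa = np.inf
        elif fam <= 0.0 or base == 0.0:
            kappa = 0.0
        else:
            kappa = base * fam / (1.0 - fam)
        for p in range(behavior.n_participants):
            seen = "yes" if rng.random() < fam else "no"
            u = rng.random()
            if u < behavior.p_single:
                concepts = [surface(_draw_concept(counts, kappa, obj, rng), rng)]
            elif u < behavior.p_single + behavior.p_hybrid:
                first = _draw_concept(counts, kappa, obj, rng)
                concepts = [surface(first, rng), surface(f"o{obj}hybrid", rng)]
            else:
                concepts = []
            rows.append(
                {
                    "participant_id": f"p{p + 1:03d}",
                    "object_id": obj,
                    "seen_before": seen,
                    "concepts": ";".join(concepts),
                }
            )
    return pd.DataFrame(rows), synonym_map


def render_object_images(
    world: LatentWorld, out_dir: str | Path | None = None, size: int = 80
) -> dict[int, Image.Image]:
    """Render simple flat-colored RGBA object images from the palette.

    Each object is a composition of an ellipse, a rectangle and a small
    disc in its three palette colors on a transparent background — enough
    surface for the color-similarity pipeline, with colors independent of
    the latent geometry.  When ``out_dir`` is given, images are written as
    ``object_<id>.png``.
    """
    images: dict[int, Image.Image] = {}
    q = size // 8
    for obj in world.object_ids:
        c1, c2, c3 = (tuple(int(v) for v in c) for c in world.palette[obj - 1])
        im = Image.new("RGBA", (size, size), (0, 0, 0, 0))
        draw = ImageDraw.Draw(im)
        draw.ellipse([q, q, size - q, size - q], fill=c1 + (255,))
        draw.rectangle([2 * q, 3 * q, 6 * q, 6 * q], fill=c2 + (255,))
        draw.ellipse([3 * q, 2 * q, 5 * q, 4 * q], fill=c3 + (255,))
        images[obj] = im
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            im.save(out / f"object_{obj}.png")
    return images
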