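"""Color-confound control.

The arrangement task asks for shape-based similarity while the stimuli are
colored, so arrangement-derived distances must be checked against color
similarity.  Each object image is box-downsampled to 20x20, background
pixels (alpha below 0.5 after resampling) are dropped, the rest are
converted to CIELAB (D65, 2 degree observer), and the color dissimilarity
of an object pair is the mean CIEDE2000 difference over the full cross
product of their retained pixels.  A Pearson correlation of these scores
against the embedded distances tests whether color leaked into the
similarity judgments; note both quantities are dissimilarities, so a color
bias would show up as a positive correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import stats
from skimage.color import deltaE_ciede2000, rgb2lab

__all__ = [
    "PixelSet",
    "ColorPairScore",
    "downsample_and_mask",
    "srgb_to_lab",
    "ciede2000",
    "pair_color_score",
    "color_score_matrix",
    "color_shape_correlation",
]

TARGET_SIZE = (20, 20)
ALPHA_THRESHOLD = 0.5


@dataclass(frozen=True)
class PixelSet:
    """Retained CIELAB pixels of one downsampled object image."""

    object_id: int
    pixels: np.ndarray  # (n_pixels, 3) L*, a*, b*

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or len(p) == 0:
            raise ValueError("pixels must be a non-empty (n, 3) LAB array")
        object.__setattr__(self, "pixels", p)


@dataclass(frozen=True)
class ColorPairScore:
    object_i: int
    object_j: int
    mean_delta_e: float


def srgb_to_lab(rgb) -> np.ndarray:
    """Convert 8-bit sRGB to CIELAB (D65 white point, 2 degree observer)."""
    arr = np.asarray(rgb, dtype=float)
    if np.any(arr < 0) or np.any(arr > 255):
        raise ValueError("sRGB components must be in 0..255")
    return rgb2lab(arr / 255.0)


def ciede2000(lab1, lab2) -> float | np.ndarray:
    """CIEDE2000 color difference with kL = kC = kH = 1."""
    return deltaE_ciede2000(np.asarray(lab1, float), np.asarray(lab2, float))


def downsample_and_mask(
    image: Image.Image | str | Path,
    object_id: int = 0,
    target: tuple[int, int] = TARGET_SIZE,
) -> PixelSet:
    """Box-downsample an RGBA image and keep opaque foreground pixels.

    The image is area-average resampled to ``target`` on alpha-premultiplied
    channels (so transparent background does not bleed color into edges);
    pixels whose resampled alpha is below 0.5 are treated as background and
    dropped, the rest are un-premultiplied and converted to CIELAB.
    """
    if not isinstance(image, Image.Image):
        image = Image.open(image)
    rgba = np.asarray(image.convert("RGBA"), dtype=float) / 255.0
    alpha = rgba[..., 3]
    premult = rgba[..., :3] * alpha[..., None]

    def _resize(plane: np.ndarray) -> np.ndarray:
        im = Image.fromarray(plane.astype(np.float32), mode="F")
        return np.asarray(im.resize(target, Image.Resampling.BOX), dtype=float)

    a_small = _resize(alpha)
    keep = a_small >= ALPHA_THRESHOLD
    if not keep.any():
        raise ValueError("image is fully transparent: empty pixel set")
    rgb_small = np.stack([_resize(premult[..., c]) for c in range(3)], axis=-1)
    rgb = np.clip(rgb_small[keep] / a_small[keep][:, None], 0.0, 1.0)
    lab = rgb2lab(rgb)
    return PixelSet(object_id=object_id, pixels=lab)


def pair_color_score(a: PixelSet, b: PixelSet) -> ColorPairScore:
    """Mean CIEDE2000 over the full cross product of two pixel sets."""
    diffs = deltaE_ciede2000(
        a.pixels[:, None, :], b.pixels[None, :, :]
    )
    return ColorPairScore(
        object_i=a.object_id, object_j=b.object_id, mean_delta_e=float(diffs.mean())
    )


def color_score_matrix(pixel_sets: list[PixelSet]) -> np.ndarray:
    """Symmetric matrix of pairwise mean CIEDE2000 scores (zero diagonal)."""
    n = len(pixel_sets)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = pair_color_score(pixel_sets[i], pixel_sets[j]).mean_delta_e
            out[i, j] = out[j, i] = s
    return out


def color_shape_correlation(
    color_scores: np.ndarray, mds_distances: np.ndarray
) -> tuple[float, int, float]:
    """Pearson correlation of per-pair color and shape dissimilarities.

    Returns ``(r, df, p)`` with ``df = n_pairs - 2`` and a two-tailed
    p-value from the t transform.  Both vectors must follow the same pair
    ordering.
    """
    x = np.asarray(color_scores, dtype=float)
    y = np.asarray(mds_distances, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length per-pair vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), len(x) - 2, float(p)
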