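"""Slide scoring: per-patch LumA probabilities, iLumA%, and spatial heatmaps.

The per-slide statistic iLumA% is the percentage of a slide's tumor patches
whose predicted P(LumA) exceeds 0.5; a slide is called *pure* when a strict
majority of patches is classified LumA (iLumA% > 50) and *admixed*
otherwise.  Heatmaps paint each tile with its probability at the patch-grid
resolution, smooth with an isotropic Gaussian (SD 2.5 grid cells,
reflective boundary, unscored cells excluded from the smoothing support via
normalized convolution), then upsample to pixel space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .classifier import Checkpoint, predict_probabilities, tiles_to_array
from .patching import Patch

__all__ = ["SlideScore", "Heatmap", "classify_patches", "slide_iluma",
           "build_heatmap", "score_slides"]


@dataclass
class SlideScore:
    slide_id: str
    n_patches: int
    iluma_pct: float         # percent of patches with P(LumA) > threshold
    call: str                # "pure" | "admixed"


@dataclass
class Heatmap:
    values: np.ndarray       # slide-dimension float raster; NaN = unscored
    sigma: float             # smoothing SD in patch-grid units


def classify_patches(model: Checkpoint, patches: list[Patch]) -> np.ndarray:
    """P(LumA) for each patch, in input order; deterministic per checkpoint."""
    if not patches:
        return np.empty(0)
    sizes = {p.patch_size for p in patches}
    if sizes != {model.patch_size}:
        raise ValueError(
            f"patch size(s) {sorted(sizes)} do not match the checkpoint's "
            f"training patch size {model.patch_size}"
        )
    net = model.build_model()
    x = tiles_to_array([p.pixels for p in patches],
                       model.hyperparams.input_size)
    return predict_probabilities(net, x)


def slide_iluma(probabilities: np.ndarray, threshold: float = 0.5,
                slide_id: str = "") -> SlideScore:
    """iLumA% and the pure/admixed call from per-patch probabilities.

    Counts entries strictly above ``threshold``; the call is *pure* only on
    a strict majority (exactly 50% -> admixed).
    """
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("cannot score a slide with no patches")
    pct = 100.0 * float(np.mean(p > threshold))
    return SlideScore(slide_id=slide_id, n_patches=int(p.size),
                      iluma_pct=pct, call="pure" if pct > 50.0 else "admixed")


def build_heatmap(
    patch_coords: list[tuple[int, int]],
    probabilities: np.ndarray,
    slide_dims: tuple[int, int],
    patch_size: int,
    sigma: float = 2.5,
) -> Heatmap:
    """Stitch patch probabilities into a smoothed slide-sized raster.

    ``sigma`` is in patch-grid units (one cell = one tile): smoothing is
    applied on the tile grid before upsampling, so it genuinely blends
    neighboring patch scores rather than only feathering tile borders.
    Unscored cells stay NaN and contribute nothing to the smoothing support
    (normalized convolution).  On a fully scored grid the reflective
    boundary makes the smoother mean-preserving, and a constant field is a
    fixed point.
    """
    h, w = slide_dims
    probs = np.asarray(probabilities, dtype=float)
    if len(patch_coords) != probs.size:
        raise ValueError("one probability per coordinate required")
    gh, gw = h // patch_size, w // patch_size
    grid = np.full((gh, gw), np.nan)
    for (r, c), p in zip(patch_coords, probs):
        if not (0 <= r <= h - patch_size and 0 <= c <= w - patch_size):
            raise ValueError(f"coordinate ({r}, {c}) outside slide dims {slide_dims}")
        if r % patch_size or c % patch_size:
            raise ValueError(f"coordinate ({r}, {c}) not grid-aligned")
        grid[r // patch_size, c // patch_size] = p
    scored = np.isfinite(grid)
    filled = np.where(scored, grid, 0.0)
    num = gaussian_filter(filled, sigma, mode="reflect")
    den = gaussian_filter(scored.astype(float), sigma, mode="reflect")
    smooth = np.full_like(grid, np.nan)
    ok = scored & (den > 1e-12)
    smooth[ok] = np.clip(num[ok] / den[ok], 0.0, 1.0)
    values = np.full((h, w), np.nan)
    up = np.kron(smooth, np.ones((patch_size, patch_size)))
    values[: gh * patch_size, : gw * patch_size] = up
    return Heatmap(values=values, sigma=sigma)


def render_overlay(slide_image: np.ndarray, heatmap: Heatmap,
                   alpha: float = 0.45) -> np.ndarray:
    """Blend the heatmap (blue = non-LumA, red = LumA) onto the slide RGB."""
    import matplotlib.cm as cm

    out = slide_image.astype(float) / 255.0
    v = heatmap.values
    ok = np.isfinite(v)
    colored = cm.coolwarm(np.nan_to_num(v))[..., :3]
    out[ok] = (1 - alpha) * out[ok] + alpha * colored[ok]
    return (out * 255).astype(np.uint8)


def score_slides(
    model: Checkpoint,
    slide_patches: dict[str, list[Patch]],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score many slides; returns a tidy per-slide table."""
    rows = []
    for sid, patches in slide_patches.items():
        probs = classify_patches(model, patches)
        s = slide_iluma(probs, threshold, slide_id=sid)
        rows.append({"slide_id": sid, "n_patches": s.n_patches,
                     "iluma_pct": s.iluma_pct, "call": s.call})
    return pd.DataFrame(rows)
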