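"""Tile extraction from annotated tumor regions.

Slides are divided into a fixed, nonoverlapping grid of square tiles
anchored at pixel (0, 0); a tile is kept when the tumor-annotation mask
covers at least ``coverage_threshold`` of its area.  Coordinates are
0-based (row, col) top-left corners in row-major order, with half-open
tile spans ``[row, row + patch_size) x [col, col + patch_size)`` — the
same convention the heatmap module uses to stitch scores back.
Remainder margins that do not fit a whole tile are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Patch", "extract_patches", "label_patches", "patch_manifest"]

LABELS = ("LumA", "nonLumA")


@dataclass
class Patch:
    """One fixed-size RGB tile with its slide-level weak label."""

    slide_id: str
    row: int
    col: int
    pixels: np.ndarray           # patch_size x patch_size x 3
    label: str | None = None     # "LumA" | "nonLumA"
    mask_coverage: float = 1.0

    @property
    def patch_size(self) -> int:
        return self.pixels.shape[0]


def extract_patches(
    slide: np.ndarray,
    mask: np.ndarray,
    patch_size: int = 512,
    coverage_threshold: float = 0.75,
    slide_id: str = "",
) -> list[Patch]:
    """Extract grid-aligned nonoverlapping tiles inside the tumor mask.

    Parameters
    ----------
    slide : array
        H x W x 3 RGB image.
    mask : array
        H x W binary tumor annotation; must match the slide's dimensions.
    patch_size : int
        Tile side in pixels (512 at full 40x resolution; smaller for
        desk-scale synthetic slides).
    coverage_threshold : float
        Minimum fraction of tile pixels inside the mask for the tile to be
        kept.

    Returns
    -------
    list of Patch in deterministic row-major order.
    """
    slide = np.asarray(slide)
    mask = np.asarray(mask).astype(bool)
    if slide.shape[:2] != mask.shape:
        raise ValueError(
            f"slide {slide.shape[:2]} and mask {mask.shape} dimensions differ"
        )
    h, w = mask.shape
    patches: list[Patch] = []
    for r in range(0, h - patch_size + 1, patch_size):
        for c in range(0, w - patch_size + 1, patch_size):
            cov = float(mask[r:r + patch_size, c:c + patch_size].mean())
            if cov >= coverage_threshold:
                patches.append(Patch(
                    slide_id=slide_id, row=r, col=c,
                    pixels=slide[r:r + patch_size, c:c + patch_size],
                    mask_coverage=cov,
                ))
    return patches


def label_patches(patches: list[Patch], slide_label: str) -> list[Patch]:
    """Propagate the slide-level class label to every patch (weak labeling)."""
    if slide_label not in LABELS:
        raise ValueError(f"unknown label {slide_label!r}; expected one of {LABELS}")
    for p in patches:
        p.label = slide_label
    return patches


def patch_manifest(patches: list[Patch]) -> pd.DataFrame:
    """Tabulate patches (slide_id, row, col, label, coverage) for on-disk use."""
    return pd.DataFrame(
        [{"slide_id": p.slide_id, "row": p.row, "col": p.col,
          "label": p.label, "coverage": p.mask_coverage} for p in patches]
    )
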