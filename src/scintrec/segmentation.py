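"""Automatic whole-body mask extraction for planar bone scintigrams.

A planar bone scintigram is a grid of nonnegative photon counts.  Off-body
pixels carry only background noise (counts almost always 0 or 1), while
in-body pixels accumulate tracer counts well above that.  The body mask is
therefore recovered with plain morphology, no learning involved:

1. threshold the *raw* counts at a small cutoff (default ``>= 2``),
2. morphological closing then opening (3x3 square element) to bridge small
   gaps and drop isolated noise pixels,
3. discard small connected components (catheter streaks, injection-site
   blobs) relative to the largest component,
4. fill interior holes (cold regions fully surrounded by body),
5. a final closing + opening to separate body from adjacent structures.

The mask is returned as a boolean array in the geometry of the input image
(row-major, origin at the top-left, 0-based indices).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "RawScintigram",
    "MorphologyConfig",
    "SegmentationError",
    "SegmentationResult",
    "to_grayscale",
    "initial_mask",
    "close_then_open",
    "remove_small_components",
    "fill_holes",
    "create_body_mask",
]

VIEWS = ("anterior", "posterior")

#: 8-connectivity structure for foreground component labelling.
_STRUCT_8 = np.ones((3, 3), dtype=bool)


class SegmentationError(RuntimeError):
    """Raised when the mask pipeline fails; carries the offending stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RawScintigram:
    """One view's raw count image.

    Parameters
    ----------
    pixels
        2-D array of nonnegative counts (any numeric dtype).
    view
        ``"anterior"`` or ``"posterior"``.
    """

    pixels: np.ndarray
    view: str = "anterior"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("scintigram must be a nonempty 2-D array")
        if np.any(self.pixels < 0):
            raise ValueError("scintigram counts must be nonnegative")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class MorphologyConfig:
    """Tunable knobs of the body-mask pipeline.

    ``threshold`` applies to the raw count scale, before any unit scaling.
    ``min_component_fraction`` is the area cutoff of the small-component
    filter, as a fraction of the largest component's area.
    """

    threshold: float = 2.0
    structure: np.ndarray = field(
        default_factory=lambda: np.ones((3, 3), dtype=bool)
    )
    close_iterations: int = 1
    open_iterations: int = 1
    min_component_fraction: float = 0.1
    fill_holes: bool = True

    def __post_init__(self):
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.close_iterations < 0 or self.open_iterations < 0:
            raise ValueError("iteration counts must be >= 0")
        if not 0 <= self.min_component_fraction <= 1:
            raise ValueError("min_component_fraction must be in [0, 1]")


@dataclass
class SegmentationResult:
    """Final mask plus the pixel area retained after every stage."""

    mask: np.ndarray
    stage_areas: dict


def _pixels(img: Union[RawScintigram, np.ndarray]) -> np.ndarray:
    return img.pixels if isinstance(img, RawScintigram) else np.asarray(img)


def to_grayscale(img: Union[RawScintigram, np.ndarray]) -> np.ndarray:
    """Min-max scale an image to the unit interval.

    ``(x - min) / (max - min)`` per pixel; a constant image maps to all
    zeros (declared convention for the degenerate range).
    """
    x = _pixels(img).astype(np.float64)
    if x.size == 0:
        raise ValueError("empty image")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def initial_mask(
    img: Union[RawScintigram, np.ndarray], cfg: MorphologyConfig | None = None
) -> np.ndarray:
    """Threshold raw counts: a bit is set iff ``pixel >= cfg.threshold``."""
    cfg = cfg or MorphologyConfig()
    return _pixels(img) >= cfg.threshold


def _close(mask: np.ndarray, structure: np.ndarray, iterations: int) -> np.ndarray:
    # Closing must be extensive even at the image border, so the erosion
    # half treats out-of-image pixels as foreground.
    if iterations == 0:
        return mask.copy()
    out = ndimage.binary_dilation(mask, structure=structure, iterations=iterations)
    return ndimage.binary_erosion(
        out, structure=structure, iterations=iterations, border_value=1
    )


def _open(mask: np.ndarray, structure: np.ndarray, iterations: int) -> np.ndarray:
    if iterations == 0:
        return mask.copy()
    out = ndimage.binary_erosion(
        mask, structure=structure, iterations=iterations, border_value=0
    )
    return ndimage.binary_dilation(out, structure=structure, iterations=iterations)


def close_then_open(mask: np.ndarray, cfg: MorphologyConfig | None = None) -> np.ndarray:
    """Morphological closing (fill small gaps) then opening (drop specks)."""
    cfg = cfg or MorphologyConfig()
    mask = np.asarray(mask, dtype=bool)
    out = _close(mask, cfg.structure, cfg.close_iterations)
    return _open(out, cfg.structure, cfg.open_iterations)


def remove_small_components(
    mask: np.ndarray, cfg: MorphologyConfig | None = None
) -> np.ndarray:
    """Drop 8-connected components smaller than a fraction of the largest.

    Components with area ``< min_component_fraction * largest_area`` are
    removed; the largest component — and any component tied with it — is
    always retained.  An empty mask is returned unchanged with a warning.
    """
    cfg = cfg or MorphologyConfig()
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCT_8)
    if n == 0:
        log.warning("remove_small_components: empty mask")
        return mask.copy()
    areas = np.bincount(labels.ravel())[1:]
    cutoff = cfg.min_component_fraction * areas.max()
    keep = np.flatnonzero(areas >= cutoff) + 1
    return np.isin(labels, keep)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Set background regions not 4-connected to the image border."""
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))


def create_body_mask(
    img: Union[RawScintigram, np.ndarray], cfg: MorphologyConfig | None = None
) -> SegmentationResult:
    """Run the full body-mask pipeline on one raw scintigram.

    Stages: raw-count threshold, closing+opening, small-component removal,
    hole filling, final closing+opening.  Raises
    :class:`SegmentationError` naming the stage that produced an empty
    mask.
    """
    cfg = cfg or MorphologyConfig()
    areas: dict = {}

    def _check(mask: np.ndarray, stage: str) -> np.ndarray:
        areas[stage] = int(mask.sum())
        log.debug("segmentation stage %-18s area=%d", stage, areas[stage])
        if not mask.any():
            raise SegmentationError(stage, "stage produced an empty mask")
        return mask

    mask = _check(initial_mask(img, cfg), "threshold")
    mask = _check(close_then_open(mask, cfg), "close_open")
    mask = _check(remove_small_components(mask, cfg), "component_filter")
    if cfg.fill_holes:
        mask = _check(fill_holes(mask), "fill_holes")
    mask = _check(close_then_open(mask, cfg), "final_close_open")
    return SegmentationResult(mask=mask, stage_areas=areas)
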