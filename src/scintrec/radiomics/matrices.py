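"""Gray-level discretization and the four 2-D texture matrices.

All matrices operate on a :class:`DiscretizedROI`: integer gray levels
``1..Ng`` inside a boolean mask, with 0 marking out-of-mask pixels.  Pixel
pairs, runs, zones and neighbourhoods never cross the mask boundary.

Conventions (documented, configurable where noted):

* GLCM — symmetric co-occurrence counts at Chebyshev distance 1 along the
  four 2-D directions 0°, 45°, 90°, 135°; one normalized matrix per
  direction.
* GLRLM — maximal same-level runs along the same four directions; a run is
  broken by any out-of-mask pixel.
* GLSZM — connected zones of equal level under 8-connectivity; direction
  free.
* NGLDM — per-pixel count of in-mask neighbours within Chebyshev radius
  ``r`` whose level differs by at most ``alpha`` (classic definition,
  ``alpha = 0``, ``r = 1``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "DiscretizedROI",
    "TextureMatrix",
    "DIRECTIONS",
    "discretize",
    "glcm",
    "glrlm",
    "glszm",
    "ngldm",
]

#: Offsets (drow, dcol) for 0°, 45°, 90°, 135° at unit distance.
DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass
class DiscretizedROI:
    """Integer gray levels over a mask; 0 marks out-of-mask pixels."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_count: int

    def __post_init__(self):
        if self.levels.shape != self.mask.shape:
            raise ValueError("levels and mask geometry differ")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class TextureMatrix:
    """A single texture matrix with its construction metadata."""

    kind: str
    values: np.ndarray
    meta: dict = field(default_factory=dict)
    normalized: bool = False


def discretize(img: np.ndarray, mask: np.ndarray, bin_count: int = 32) -> DiscretizedROI:
    """Fixed-bin-count discretization of in-mask intensities.

    ``level = floor((x - min) / range * Ng) + 1`` with the maximum mapped
    to ``Ng``; a constant ROI maps to level 1 with one effective level.
    """
    img = np.asarray(img, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError("image and mask geometry differ")
    if not mask.any():
        raise ValueError("empty mask")
    if bin_count < 1:
        raise ValueError("bin_count must be >= 1")
    vals = img[mask]
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(img.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
    else:
        lv = np.floor((vals - lo) / (hi - lo) * bin_count).astype(np.int32) + 1
        np.clip(lv, 1, bin_count, out=lv)
        levels[mask] = lv
    return DiscretizedROI(
        levels=levels, mask=mask, n_levels=int(levels.max()), bin_count=bin_count
    )


def _shift_slices(shape, dr: int, dc: int):
    """Index slices pairing each pixel ``a`` with its neighbour ``b = a + (dr, dc)``."""
    rows, cols = shape
    ra = slice(max(0, -dr), rows - max(0, dr))
    rb = slice(max(0, dr), rows - max(0, -dr))
    ca = slice(max(0, -dc), cols - max(0, dc))
    cb = slice(max(0, dc), cols - max(0, -dc))
    return (ra, ca), (rb, cb)


def _degenerate(ng: int, kind: str, meta: dict) -> TextureMatrix:
    # No valid pair in this direction: single-entry convention so that the
    # downstream features behave like those of a constant ROI.
    log.warning("%s: no valid pixel pair, using single-entry matrix", kind)
    values = np.zeros((ng, ng)) if kind == "GLCM" else np.zeros((ng, 1))
    values[0, 0] = 1.0
    return TextureMatrix(kind=kind, values=values, meta=meta, normalized=kind == "GLCM")


def glcm(
    roi: DiscretizedROI, distance: int = 1, directions=DIRECTIONS
) -> list[TextureMatrix]:
    """Symmetric, per-direction normalized gray-level co-occurrence matrices."""
    ng = roi.n_levels
    out = []
    for dr, dc in directions:
        meta = {"direction": (dr, dc), "distance": distance}
        (sa, sb) = _shift_slices(roi.levels.shape, dr * distance, dc * distance)
        a = roi.levels[sa]
        b = roi.levels[sb]
        valid = roi.mask[sa] & roi.mask[sb]
        p = np.zeros((ng, ng), dtype=np.float64)
        if valid.any():
            av = a[valid] - 1
            bv = b[valid] - 1
            np.add.at(p, (av, bv), 1.0)
            np.add.at(p, (bv, av), 1.0)
            p /= p.sum()
            out.append(TextureMatrix("GLCM", p, meta, normalized=True))
        else:
            out.append(_degenerate(ng, "GLCM", meta))
    return out


def _run_counts(line: np.ndarray, matrix: np.ndarray) -> None:
    """Accumulate maximal runs of equal nonzero values into ``matrix[g-1, len-1]``."""
    n = line.size
    if n == 0:
        return
    change = np.flatnonzero(line[1:] != line[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [n - 1]))
    vals = line[starts]
    keep = vals > 0
    np.add.at(matrix, (vals[keep] - 1, (ends - starts)[keep]), 1.0)


def _sheared_diagonals(a: np.ndarray) -> np.ndarray:
    """Pack the (1, 1) diagonals of ``a`` into the columns of a padded array."""
    rows, cols = a.shape
    out = np.zeros((rows, rows + cols - 1), dtype=a.dtype)
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    out[r, c - r + rows - 1] = a
    return out


def glrlm(roi: DiscretizedROI, directions=DIRECTIONS) -> list[TextureMatrix]:
    """Gray-level run-length count matrices, one per direction.

    Entry ``(g, r)`` counts the maximal runs of level ``g + 1`` with length
    ``r + 1``; runs are broken wherever the mask is unset.
    """
    lv = np.where(roi.mask, roi.levels, 0)
    ng = roi.n_levels
    max_run = max(lv.shape)
    out = []
    for dr, dc in directions:
        meta = {"direction": (dr, dc)}
        m = np.zeros((ng, max_run), dtype=np.float64)
        if (dr, dc) in ((0, 1), (0, -1)):
            lines = lv
        elif (dr, dc) in ((-1, 0), (1, 0)):
            lines = lv.T
        elif (dr, dc) in ((1, 1), (-1, -1)):
            lines = _sheared_diagonals(lv).T
        elif (dr, dc) in ((-1, 1), (1, -1)):
            lines = _sheared_diagonals(lv[:, ::-1]).T
        else:
            raise ValueError(f"unsupported run direction {(dr, dc)}")
        # Separator column so runs never wrap across line boundaries.
        flat = np.concatenate(
            [np.ascontiguousarray(lines), np.zeros((lines.shape[0], 1), lines.dtype)],
            axis=1,
        ).ravel()
        _run_counts(flat, m)
        last = np.flatnonzero(m.any(axis=0))
        m = m[:, : last[-1] + 1] if last.size else _degenerate(ng, "GLRLM", meta).values
        out.append(TextureMatrix("GLRLM", m, meta, normalized=False))
    return out


def glszm(roi: DiscretizedROI, connectivity: int = 8) -> TextureMatrix:
    """Gray-level size-zone count matrix (8-connected equal-level zones)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCT_8 if connectivity == 8 else ndimage.generate_binary_structure(2, 1)
    lv = np.where(roi.mask, roi.levels, 0)
    ng = roi.n_levels
    zones: list[tuple[int, np.ndarray]] = []
    max_size = 0
    for g in range(1, ng + 1):
        labels, n = ndimage.label(lv == g, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        zones.append((g, sizes))
        max_size = max(max_size, int(sizes.max()))
    m = np.zeros((ng, max(max_size, 1)), dtype=np.float64)
    for g, sizes in zones:
        np.add.at(m, (g - 1, sizes - 1), 1.0)
    return TextureMatrix("GLSZM", m, {"connectivity": connectivity}, normalized=False)


def ngldm(roi: DiscretizedROI, alpha: int = 0, chebyshev_radius: int = 1) -> TextureMatrix:
    """Neighbouring gray-level dependence count matrix.

    For each in-mask pixel, the dependence is the number of in-mask
    neighbours within the Chebyshev radius whose level differs by at most
    ``alpha``.  Entry ``(g, d)`` counts pixels of level ``g + 1`` with
    dependence ``d``.
    """
    if chebyshev_radius < 1:
        raise ValueError("chebyshev_radius must be >= 1")
    ng = roi.n_levels
    dep = np.zeros(roi.levels.shape, dtype=np.int32)
    r = chebyshev_radius
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            if dr == 0 and dc == 0:
                continue
            (sa, sb) = _shift_slices(roi.levels.shape, dr, dc)
            ok = (
                roi.mask[sa]
                & roi.mask[sb]
                & (np.abs(roi.levels[sa].astype(np.int64) - roi.levels[sb]) <= alpha)
            )
            dep[sa] += ok
    n_neigh = (2 * r + 1) ** 2 - 1
    m = np.zeros((ng, n_neigh + 1), dtype=np.float64)
    np.add.at(m, (roi.levels[roi.mask] - 1, dep[roi.mask]), 1.0)
    return TextureMatrix(
        "NGLDM", m, {"alpha": alpha, "chebyshev_radius": r}, normalized=False
    )
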