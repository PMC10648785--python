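"""Radiomics feature formulas and the per-view extraction pipeline.

The shipped catalogue comprises 64 features per view: 18 first-order
statistics plus 17 GLCM, 12 GLRLM, 12 GLSZM and 5 NGLDM texture features.
Processing both whole-body views (anterior -> ``front_``, posterior ->
``back_``) yields 128 named features per patient.

GLCM and GLRLM features are averaged over the four 2-D directions; GLSZM
and NGLDM are direction free.  Gray levels enter the formulas at their
1-based discretized values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import (
    DIRECTIONS,
    DiscretizedROI,
    TextureMatrix,
    discretize,
    glcm,
    glrlm,
    glszm,
    ngldm,
)

__all__ = [
    "FeatureCatalogue",
    "DEFAULT_CATALOGUE",
    "first_order",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngldm_features",
    "extract_view_features",
    "extract_features",
]

FIRSTORDER_NAMES = (
    "Mean",
    "Median",
    "Minimum",
    "Maximum",
    "Range",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Energy",
    "TotalEnergy",
    "RootMeanSquared",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "InterquartileRange",
    "Percentile10",
    "Percentile90",
    "Entropy",
    "Uniformity",
)

GLCM_NAMES = (
    "JointEnergy",
    "JointEntropy",
    "JointAverage",
    "Contrast",
    "Dissimilarity",
    "InverseDifference",
    "InverseDifferenceMoment",
    "Correlation",
    "Autocorrelation",
    "ClusterTendency",
    "ClusterShade",
    "ClusterProminence",
    "SumAverage",
    "SumEntropy",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
)

GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "RunLengthNonUniformity",
    "RunPercentage",
    "RunVariance",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "SizeZoneNonUniformity",
    "ZonePercentage",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

NGLDM_NAMES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "DependenceNonUniformity",
    "DependenceEnergy",
    "DependenceEntropy",
)

VIEW_PREFIX = {"anterior": "front", "posterior": "back"}


@dataclass(frozen=True)
class FeatureCatalogue:
    """Ordered feature names per class; the shipped default totals 64."""

    firstorder: tuple = FIRSTORDER_NAMES
    glcm: tuple = GLCM_NAMES
    glrlm: tuple = GLRLM_NAMES
    glszm: tuple = GLSZM_NAMES
    ngldm: tuple = NGLDM_NAMES

    @property
    def per_view_count(self) -> int:
        return (
            len(self.firstorder)
            + len(self.glcm)
            + len(self.glrlm)
            + len(self.glszm)
            + len(self.ngldm)
        )

    def classes(self):
        return (
            ("firstorder", self.firstorder),
            ("glcm", self.glcm),
            ("glrlm", self.glrlm),
            ("glszm", self.glszm),
            ("ngldm", self.ngldm),
        )


DEFAULT_CATALOGUE = FeatureCatalogue()


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def first_order(
    img: np.ndarray,
    mask: np.ndarray,
    pixel_area: float = 1.0,
    bin_count: int = 32,
) -> dict[str, float]:
    """The 18 first-order statistics of the in-mask intensities.

    Skewness is ``m3 / m2**1.5`` and kurtosis ``m4 / m2**2`` (population
    moments, no excess correction); both are defined as 0 on a constant
    ROI.  Entropy and Uniformity are computed on a fixed-bin-count
    histogram of the in-mask values.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    x = np.asarray(img, dtype=np.float64)[mask]
    n = x.size
    mean = x.mean()
    d = x - mean
    m2 = np.mean(d**2)
    m3 = np.mean(d**3)
    m4 = np.mean(d**4)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    mid = x[(x >= p10) & (x <= p90)]
    # Histogram probabilities over the (possibly degenerate) value range.
    if x.max() > x.min():
        hist, _ = np.histogram(x, bins=bin_count, range=(x.min(), x.max()))
    else:
        hist = np.array([n])
    p = hist / n
    return {
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Variance": float(m2),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(pixel_area * np.sum(x**2)),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(d))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(mid - mid.mean())))
        if mid.size
        else 0.0,
        "InterquartileRange": float(p75 - p25),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Entropy": _entropy(p),
        "Uniformity": float(np.sum(p**2)),
    }


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())  # symmetric matrix: mu_x == mu_y
    sigma2 = float(((i - mu) ** 2 * px).sum())

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    ks = (ii + jj).astype(int)
    pxy_sum = np.bincount(ks.ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    kd = np.abs(ii - jj).astype(int)
    pxy_diff = np.bincount(kd.ravel(), weights=p.ravel(), minlength=ng)

    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    k_diff = np.arange(ng, dtype=np.float64)
    diff_avg = float((k_diff * pxy_diff).sum())

    corr_num = float(((ii - mu) * (jj - mu) * p).sum())
    return {
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": _entropy(p.ravel()),
        "JointAverage": mu,
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "InverseDifference": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "InverseDifferenceMoment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Correlation": corr_num / sigma2 if sigma2 > 0 else 1.0,
        "Autocorrelation": float((ii * jj * p).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "SumAverage": float((k_sum * pxy_sum).sum()),
        "SumEntropy": _entropy(pxy_sum),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _entropy(pxy_diff),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * pxy_diff).sum()),
    }


def glcm_features(matrices: list[TextureMatrix]) -> dict[str, float]:
    """Direction-averaged GLCM features from normalized matrices."""
    per_dir = [_glcm_features_single(m.values) for m in matrices]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_NAMES}


def _rlm_features_single(m: np.ndarray, n_pixels: int) -> dict[str, float]:
    ng, nr = m.shape
    g = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    r = np.arange(1, nr + 1, dtype=np.float64)[None, :]
    ns = m.sum()
    rg = m.sum(axis=1)  # per gray level
    rr = m.sum(axis=0)  # per run length
    p = m / ns
    mu_r = float((r * p).sum())
    return {
        "ShortRunEmphasis": float((m / r**2).sum() / ns),
        "LongRunEmphasis": float((m * r**2).sum() / ns),
        "GrayLevelNonUniformity": float((rg**2).sum() / ns),
        "RunLengthNonUniformity": float((rr**2).sum() / ns),
        "RunPercentage": float(ns / n_pixels),
        "RunVariance": float((((r - mu_r) ** 2) * p).sum()),
        "LowGrayLevelRunEmphasis": float((m / g**2).sum() / ns),
        "HighGrayLevelRunEmphasis": float((m * g**2).sum() / ns),
        "ShortRunLowGrayLevelEmphasis": float((m / (g**2 * r**2)).sum() / ns),
        "ShortRunHighGrayLevelEmphasis": float((m * g**2 / r**2).sum() / ns),
        "LongRunLowGrayLevelEmphasis": float((m * r**2 / g**2).sum() / ns),
        "LongRunHighGrayLevelEmphasis": float((m * g**2 * r**2).sum() / ns),
    }


def glrlm_features(matrices: list[TextureMatrix], n_pixels: int) -> dict[str, float]:
    """Direction-averaged GLRLM features from run-count matrices."""
    per_dir = [_rlm_features_single(m.values, n_pixels) for m in matrices]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}


def glszm_features(matrix: TextureMatrix, n_pixels: int) -> dict[str, float]:
    """GLSZM features from the zone-count matrix."""
    m = matrix.values
    ng, ns_max = m.shape
    g = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    s = np.arange(1, ns_max + 1, dtype=np.float64)[None, :]
    nz = m.sum()
    zg = m.sum(axis=1)
    zs = m.sum(axis=0)
    p = m / nz
    return {
        "SmallAreaEmphasis": float((m / s**2).sum() / nz),
        "LargeAreaEmphasis": float((m * s**2).sum() / nz),
        "GrayLevelNonUniformity": float((zg**2).sum() / nz),
        "SizeZoneNonUniformity": float((zs**2).sum() / nz),
        "ZonePercentage": float(nz / n_pixels),
        "ZoneEntropy": _entropy(p.ravel()),
        "LowGrayLevelZoneEmphasis": float((m / g**2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((m * g**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((m / (g**2 * s**2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((m * g**2 / s**2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((m * s**2 / g**2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((m * g**2 * s**2).sum() / nz),
    }


def ngldm_features(matrix: TextureMatrix) -> dict[str, float]:
    """NGLDM features; the dependence axis is shifted to ``j = d + 1``."""
    m = matrix.values
    ng, nd = m.shape
    j = np.arange(1, nd + 1, dtype=np.float64)[None, :]
    ns = m.sum()
    nj = m.sum(axis=0)
    p = m / ns
    return {
        "SmallDependenceEmphasis": float((m / j**2).sum() / ns),
        "LargeDependenceEmphasis": float((m * j**2).sum() / ns),
        "DependenceNonUniformity": float((nj**2).sum() / ns),
        "DependenceEnergy": float((p**2).sum()),
        "DependenceEntropy": _entropy(p.ravel()),
    }


def extract_view_features(
    img: np.ndarray,
    mask: np.ndarray,
    bin_count: int = 32,
    catalogue: FeatureCatalogue = DEFAULT_CATALOGUE,
    pixel_area: float = 1.0,
) -> dict[str, float]:
    """Unit-scale, discretize and compute the full catalogue for one view.

    Returns ``{"<class>_<Feature>": value}`` with exactly
    ``catalogue.per_view_count`` entries.
    """
    from ..segmentation import to_grayscale

    mask = np.asarray(mask, dtype=bool)
    unit = to_grayscale(img)
    roi = discretize(unit, mask, bin_count=bin_count)
    n_pix = roi.n_pixels

    computed = {
        "firstorder": first_order(unit, mask, pixel_area=pixel_area, bin_count=bin_count),
        "glcm": glcm_features(glcm(roi)),
        "glrlm": glrlm_features(glrlm(roi), n_pix),
        "glszm": glszm_features(glszm(roi), n_pix),
        "ngldm": ngldm_features(ngldm(roi)),
    }
    out: dict[str, float] = {}
    for cls, names in catalogue.classes():
        for name in names:
            out[f"{cls}_{name}"] = computed[cls][name]
    return out


def extract_features(
    anterior: np.ndarray,
    posterior: np.ndarray,
    mask_anterior: np.ndarray,
    mask_posterior: np.ndarray,
    bin_count: int = 32,
    catalogue: FeatureCatalogue = DEFAULT_CATALOGUE,
) -> dict[str, float]:
    """Per-patient feature vector over both views.

    Anterior features are prefixed ``front_`` and posterior ``back_``,
    giving ``2 * catalogue.per_view_count`` uniquely named entries (128
    with the default catalogue).
    """
    out: dict[str, float] = {}
    for prefix, img, mask in (
        ("front", anterior, posterior_mask_guard(mask_anterior)),
        ("back", posterior, posterior_mask_guard(mask_posterior)),
    ):
        feats = extract_view_features(img, mask, bin_count=bin_count, catalogue=catalogue)
        for name, value in feats.items():
            out[f"{prefix}_{name}"] = value
    if not all(np.isfinite(v) for v in out.values()):
        bad = [k for k, v in out.items() if not np.isfinite(v)]
        raise ValueError(f"non-finite feature values: {bad}")
    return out


def posterior_mask_guard(mask) -> np.ndarray:
    if mask is None:
        raise ValueError("both views and masks are required")
    return np.asarray(mask, dtype=bool)


def catalogue_to_dict(catalogue: FeatureCatalogue = DEFAULT_CATALOGUE) -> dict:
    """JSON-serializable dump of the feature catalogue."""
    return {
        "per_view_count": catalogue.per_view_count,
        "classes": {cls: list(names) for cls, names in catalogue.classes()},
    }


def features_to_long(wide) -> "object":
    """Reshape a wide per-patient feature table to (patient_id, feature_name, value)."""
    import pandas as pd

    long = wide.reset_index().melt(
        id_vars="patient_id", var_name="feature_name", value_name="value"
    )
    return long.sort_values(["patient_id", "feature_name"]).reset_index(drop=True)
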