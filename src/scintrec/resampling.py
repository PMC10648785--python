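"""Class rebalancing for the training folds: SMOTE and random resampling.

SMOTE follows the classic procedure: pick a minority point, pick one of
its k Euclidean-nearest minority neighbours, and place a synthetic sample
uniformly at random on the segment between the two.  Alternatives are
plain minority duplication and majority reduction (subsampling without
replacement).  Rebalancing is a training-fold operation only — the
evaluation pipeline never resamples test rows, so synthetic points cannot
leak into held-out data.

Every synthetic row's provenance (seed point, neighbour, interpolation
weight) is returned for audit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = ["SmoteConfig", "ResamplingError", "smote_sample", "rebalance"]

MODES = ("smote", "duplicate_minority", "reduce_majority", "combined")


class ResamplingError(ValueError):
    pass


@dataclass(frozen=True)
class SmoteConfig:
    """k, target minority:majority ratio, mode and seed."""

    k_neighbors: int = 5
    ratio: float = 1.0
    mode: str = "smote"
    seed: int = 0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ResamplingError("k_neighbors must be >= 1")
        if not 0 < self.ratio <= 1:
            raise ResamplingError("ratio must lie in (0, 1]")
        if self.mode not in MODES:
            raise ResamplingError(f"mode must be one of {MODES}")


def smote_sample(
    minority: np.ndarray,
    k: int,
    n_synthetic: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Generate ``n_synthetic`` interpolated minority rows.

    Each synthetic row is ``x_i + lam * (x_j - x_i)`` with ``lam ~
    U(0, 1)`` and ``x_j`` one of the k nearest minority neighbours of the
    randomly chosen seed row ``x_i``.  Returns the rows and a provenance
    table with columns ``seed_row``, ``neighbor_row``, ``lam``.
    """
    minority = np.asarray(minority, dtype=np.float64)
    n_min = len(minority)
    if n_min <= k:
        raise ResamplingError(
            f"minority count {n_min} must exceed k={k}; lower k_neighbors"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority)
    # Drop the self-neighbour in column 0 (ties may reorder, so drop by index).
    neigh = nn.kneighbors(minority, return_distance=False)
    neigh = np.array(
        [[j for j in row if j != i][:k] for i, row in enumerate(neigh)]
    )
    rows = np.empty((n_synthetic, minority.shape[1]))
    prov = []
    for s in range(n_synthetic):
        i = int(rng.integers(n_min))
        j = int(neigh[i][int(rng.integers(k))])
        lam = float(rng.random())
        rows[s] = minority[i] + lam * (minority[j] - minority[i])
        prov.append({"seed_row": i, "neighbor_row": j, "lam": lam})
    return rows, pd.DataFrame(prov, columns=["seed_row", "neighbor_row", "lam"])


def rebalance(
    X: np.ndarray, y: np.ndarray, cfg: SmoteConfig
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Rebalance a (training) matrix to ``cfg.ratio`` minority:majority.

    Original rows are retained in the oversampling modes; the reduction
    mode subsamples the majority class without replacement.  Returns the
    resampled matrix, labels, and the synthetic-row provenance table
    (empty for non-SMOTE modes).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ResamplingError("rebalance requires exactly two classes")
    minority_cls = classes[np.argmin(counts)]
    majority_cls = classes[np.argmax(counts)]
    n_min, n_maj = counts.min(), counts.max()
    rng = np.random.default_rng(cfg.seed)
    prov = pd.DataFrame(columns=["seed_row", "neighbor_row", "lam"])

    min_idx = np.flatnonzero(y == minority_cls)
    maj_idx = np.flatnonzero(y == majority_cls)

    if cfg.mode == "combined":
        # Meet in the middle: subsample the majority halfway toward the
        # minority count, then SMOTE the minority up to the target ratio.
        target_maj = math.ceil((n_maj + n_min) / 2)
        keep_maj = np.sort(rng.choice(maj_idx, size=target_maj, replace=False))
        keep = np.sort(np.concatenate([min_idx, keep_maj]))
        X, y = X[keep], y[keep]
        min_idx = np.flatnonzero(y == minority_cls)
        maj_idx = np.flatnonzero(y == majority_cls)
        n_maj = target_maj

    target_min = math.ceil(cfg.ratio * n_maj)
    if n_min >= target_min and cfg.mode != "reduce_majority":
        return X.copy(), y.copy(), prov

    if cfg.mode in ("smote", "combined"):
        n_new = target_min - n_min
        synth, prov = smote_sample(X[min_idx], cfg.k_neighbors, n_new, rng)
        Xr = np.vstack([X, synth])
        yr = np.concatenate([y, np.full(n_new, minority_cls)])
    elif cfg.mode == "duplicate_minority":
        n_new = target_min - n_min
        dup = min_idx[rng.integers(n_min, size=n_new)]
        Xr = np.vstack([X, X[dup]])
        yr = np.concatenate([y, np.full(n_new, minority_cls)])
    elif cfg.mode == "reduce_majority":
        target_maj = math.floor(n_min / cfg.ratio)
        if target_maj >= n_maj:
            return X.copy(), y.copy(), prov
        keep_maj = rng.choice(maj_idx, size=target_maj, replace=False)
        keep = np.sort(np.concatenate([min_idx, keep_maj]))
        Xr, yr = X[keep].copy(), y[keep].copy()
    else:  # pragma: no cover - guarded by SmoteConfig
        raise ResamplingError(cfg.mode)
    return Xr, yr, prov
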