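"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as plain loops over pixels so it shares no code
path with the package; it is deliberately slow and only run on tiny grids.
"""

import numpy as np


def glcm_oracle(levels, mask, dr, dc):
    """Symmetric normalized co-occurrence matrix by pair enumeration."""
    ng = int(levels[mask].max())
    p = np.zeros((ng, ng))
    rows, cols = levels.shape
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols and mask[r, c] and mask[r2, c2]:
                a, b = levels[r, c] - 1, levels[r2, c2] - 1
                p[a, b] += 1
                p[b, a] += 1
    if p.sum() == 0:
        p[0, 0] = 1.0
        return p
    return p / p.sum()


def glrlm_oracle(levels, mask, dr, dc):
    """Run counts by walking every maximal run start."""
    rows, cols = levels.shape
    lv = np.where(mask, levels, 0)
    ng = int(levels[mask].max())
    runs = {}
    for r in range(rows):
        for c in range(cols):
            if lv[r, c] == 0:
                continue
            pr, pc = r - dr, c - dc
            if 0 <= pr < rows and 0 <= pc < cols and lv[pr, pc] == lv[r, c]:
                continue  # not a run start
            length = 1
            nr, nc = r + dr, c + dc
            while 0 <= nr < rows and 0 <= nc < cols and lv[nr, nc] == lv[r, c]:
                length += 1
                nr += dr
                nc += dc
            runs[(lv[r, c], length)] = runs.get((lv[r, c], length), 0) + 1
    max_len = max((ln for (_, ln) in runs), default=1)
    m = np.zeros((ng, max_len))
    for (g, ln), n in runs.items():
        m[g - 1, ln - 1] = n
    return m


def glszm_oracle(levels, mask):
    """Zone counts by flood fill (8-connectivity) per gray level."""
    rows, cols = levels.shape
    lv = np.where(mask, levels, 0)
    ng = int(levels[mask].max())
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    for r in range(rows):
        for c in range(cols):
            if lv[r, c] == 0 or seen[r, c]:
                continue
            g = lv[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                y, x = stack.pop()
                size += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if (
                            0 <= ny < rows
                            and 0 <= nx < cols
                            and not seen[ny, nx]
                            and lv[ny, nx] == g
                        ):
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            zones.append((g, size))
    max_size = max((s for _, s in zones), default=1)
    m = np.zeros((ng, max_size))
    for g, s in zones:
        m[g - 1, s - 1] += 1
    return m


def ngldm_oracle(levels, mask, alpha=0, radius=1):
    """Dependence counts by explicit neighbourhood loops."""
    rows, cols = levels.shape
    ng = int(levels[mask].max())
    n_neigh = (2 * radius + 1) ** 2 - 1
    m = np.zeros((ng, n_neigh + 1))
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            dep = 0
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    if dy == 0 and dx == 0:
                        continue
                    ny, nx = r + dy, c + dx
                    if (
                        0 <= ny < rows
                        and 0 <= nx < cols
                        and mask[ny, nx]
                        and abs(int(levels[ny, nx]) - int(levels[r, c])) <= alpha
                    ):
                        dep += 1
            m[levels[r, c] - 1, dep] += 1
    return m


def first_order_oracle(values, pixel_area=1.0):
    """Naive first-order statistics of a 1-D sample."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    mid = np.array([v for v in x if p10 <= v <= p90])
    return {
        "Mean": mean,
        "Median": float(np.median(x)),
        "Minimum": float(min(x)),
        "Maximum": float(max(x)),
        "Range": float(max(x) - min(x)),
        "Variance": m2,
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Energy": float(sum(v**2 for v in x)),
        "TotalEnergy": float(pixel_area * sum(v**2 for v in x)),
        "RootMeanSquared": float(np.sqrt(sum(v**2 for v in x) / n)),
        "MeanAbsoluteDeviation": float(sum(abs(v - mean) for v in x) / n),
        "RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(mid - mid.mean()))
        )
        if len(mid)
        else 0.0,
        "InterquartileRange": float(p75 - p25),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
    }


def auc_oracle(scores, labels):
    """AUC by exhaustive pairwise comparison; ties count one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
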