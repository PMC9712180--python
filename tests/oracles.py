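"""Independent brute-force oracles for the texture matrices and statistics.

Everything here is written as plain nested loops / exhaustive enumeration,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import numpy as np

DIRS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]
NEIGHBORS_26 = [
    (i, j, k)
    for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


def _inside(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def naive_glcm(levels: np.ndarray, direction, n_levels: int, distance: int = 1) -> np.ndarray:
    """Symmetric co-occurrence counts: every ordered ROI pair along +/-d."""
    mat = np.zeros((n_levels, n_levels))
    d = tuple(c * distance for c in direction)
    shape = levels.shape
    for idx in np.ndindex(shape):
        if levels[idx] == 0:
            continue
        for sign in (1, -1):
            q = tuple(a + sign * b for a, b in zip(idx, d))
            if _inside(shape, q) and levels[q] > 0:
                mat[levels[idx] - 1, levels[q] - 1] += 1
    return mat


def naive_glrlm(levels: np.ndarray, direction, n_levels: int) -> np.ndarray:
    """Run counts by walking each maximal run from its start voxel."""
    shape = levels.shape
    runs = []
    for idx in np.ndindex(shape):
        g = levels[idx]
        if g == 0:
            continue
        prev = tuple(a - b for a, b in zip(idx, direction))
        if _inside(shape, prev) and levels[prev] == g:
            continue  # not a run start
        length = 1
        cur = idx
        while True:
            nxt = tuple(a + b for a, b in zip(cur, direction))
            if _inside(shape, nxt) and levels[nxt] == g:
                length += 1
                cur = nxt
            else:
                break
        runs.append((g, length))
    max_len = max((l for _, l in runs), default=1)
    mat = np.zeros((n_levels, max_len))
    for g, l in runs:
        mat[g - 1, l - 1] += 1
    return mat


def _zones_bfs(levels: np.ndarray):
    """26-connected same-level zones via breadth-first search."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for idx in np.ndindex(shape):
        if levels[idx] == 0 or seen[idx]:
            continue
        g = levels[idx]
        stack = [idx]
        seen[idx] = True
        voxels = []
        while stack:
            p = stack.pop()
            voxels.append(p)
            for off in NEIGHBORS_26:
                q = tuple(a + b for a, b in zip(p, off))
                if _inside(shape, q) and not seen[q] and levels[q] == g:
                    seen[q] = True
                    stack.append(q)
        zones.append((g, voxels))
    return zones


def naive_glszm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    zones = _zones_bfs(levels)
    max_size = max((len(v) for _, v in zones), default=1)
    mat = np.zeros((n_levels, max_size))
    for g, voxels in zones:
        mat[g - 1, len(voxels) - 1] += 1
    return mat


def _border_dist(levels: np.ndarray, p) -> int:
    """Chebyshev distance to the nearest non-ROI voxel; grid edge is non-ROI."""
    shape = levels.shape
    best = min(
        min(c + 1, n - c) for c, n in zip(p, shape)
    )
    for idx in np.ndindex(shape):
        if levels[idx] == 0:
            d = max(abs(a - b) for a, b in zip(p, idx))
            best = min(best, d)
    return max(1, best)


def naive_gldzm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    zones = _zones_bfs(levels)
    dists = [(g, min(_border_dist(levels, p) for p in voxels)) for g, voxels in zones]
    max_d = max((d for _, d in dists), default=1)
    mat = np.zeros((n_levels, max_d))
    for g, d in dists:
        mat[g - 1, d - 1] += 1
    return mat


def naive_ngldm(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    shape = levels.shape
    mat = np.zeros((n_levels, 27))
    for idx in np.ndindex(shape):
        g = levels[idx]
        if g == 0:
            continue
        k = 0
        for off in NEIGHBORS_26:
            q = tuple(a + b for a, b in zip(idx, off))
            if _inside(shape, q) and levels[q] > 0 and abs(int(levels[q]) - int(g)) <= alpha:
                k += 1
        mat[g - 1, k] += 1
    return mat


def naive_ngtdm(levels: np.ndarray, n_levels: int):
    shape = levels.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for idx in np.ndindex(shape):
        g = levels[idx]
        if g == 0:
            continue
        vals = []
        for off in NEIGHBORS_26:
            q = tuple(a + b for a, b in zip(idx, off))
            if _inside(shape, q) and levels[q] > 0:
                vals.append(levels[q])
        if not vals:
            continue
        n_i[g - 1] += 1
        s_i[g - 1] += abs(g - sum(vals) / len(vals))
    return n_i, s_i


# ---------------------------------------------------------------------------
# Statistics oracles
# ---------------------------------------------------------------------------

def pairwise_auc(pos, neg) -> float:
    """Exhaustive pair enumeration with 0.5 credit for ties."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def anova_icc31(x: np.ndarray):
    """Two-way ANOVA consistency ICC computed longhand with explicit loops."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    ss_rows = 0.0
    for i in range(n):
        rm = sum(x[i]) / k
        ss_rows += k * (rm - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        cm = sum(x[i][j] for i in range(n)) / n
        ss_cols += n * (cm - grand) ** 2
    ss_tot = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)


def youden_scan(scores, labels01):
    """Exhaustive scan over every observed-score cutoff (predict pos if >=)."""
    best = None
    for c in sorted(set(scores)):
        tp = sum(1 for s, y in zip(scores, labels01) if s >= c and y == 1)
        fn = sum(1 for s, y in zip(scores, labels01) if s < c and y == 1)
        tn = sum(1 for s, y in zip(scores, labels01) if s < c and y == 0)
        fp = sum(1 for s, y in zip(scores, labels01) if s >= c and y == 0)
        tpr = tp / (tp + fn)
        tnr = tn / (tn + fp)
        j = tpr + tnr - 1
        if best is None or (j, tnr, c) > (best[0], best[1], best[2]):
            best = (j, tnr, c, tpr)
    return {"cutoff": best[2], "tpr": best[3], "tnr": best[1], "j": best[0]}
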