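"""Gray-level texture matrices on a discretized 3D ROI.

Six matrix families are built from a :class:`~xlung.prep.DiscretizedRoi`:

- GLCM   gray level co-occurrence (per 3D direction, symmetric)
- GLRLM  gray level run length (per 3D direction)
- GLSZM  gray level size zone (direction-free, 26-connected zones)
- GLDZM  gray level distance zone (zone distance to the ROI border)
- NGLDM  neighboring gray level dependence
- NGTDM  neighborhood gray tone difference

All neighborhoods use Chebyshev distance 1 (26-connectivity); GLCM/GLRLM use
the 13 unique 3D direction vectors. Voxels outside the ROI never contribute:
they break runs, are skipped in co-occurrence pairs, and are excluded from
neighbor means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: 13 unique direction vectors of the 26-neighborhood (one per +/- pair)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

#: all 26 neighbor offsets
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class GLCM:
    """Symmetric co-occurrence count matrices, one per direction."""

    directional: dict[tuple[int, int, int], np.ndarray]
    n_levels: int
    distance: int = 1

    def merged(self) -> np.ndarray:
        return sum(self.directional.values())


@dataclass
class GLRLM:
    """Run-length count matrices (levels x run length), one per direction."""

    directional: dict[tuple[int, int, int], np.ndarray]
    n_levels: int
    n_voxels: int

    def merged(self) -> np.ndarray:
        m = max(a.shape[1] for a in self.directional.values())
        out = np.zeros((self.n_levels, m))
        for a in self.directional.values():
            out[:, : a.shape[1]] += a
        return out


@dataclass
class GLSZM:
    matrix: np.ndarray  # levels x zone size
    n_levels: int
    n_voxels: int


@dataclass
class GLDZM:
    matrix: np.ndarray  # levels x zone distance
    n_levels: int
    n_voxels: int


@dataclass
class NGLDM:
    matrix: np.ndarray  # levels x (dependence count 0..26)
    n_levels: int
    n_voxels: int


@dataclass
class NGTDM:
    n_i: np.ndarray  # per-level voxel counts (index 0 = level 1)
    s_i: np.ndarray  # per-level summed |level - neighbor mean|
    n_levels: int
    n_voxels: int


@dataclass
class TextureMatrices:
    glcm: GLCM
    glrlm: GLRLM
    glszm: GLSZM
    gldzm: GLDZM
    ngldm: NGLDM
    ngtdm: NGTDM


def _shifted_pairs(levels: np.ndarray, d: tuple[int, int, int], distance: int = 1):
    """Index slices selecting voxel pairs (a, a + distance*d) inside the grid."""
    sl_a, sl_b = [], []
    for step in d:
        s = step * distance
        if s > 0:
            sl_a.append(slice(None, -s))
            sl_b.append(slice(s, None))
        elif s < 0:
            sl_a.append(slice(-s, None))
            sl_b.append(slice(None, s))
        else:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
    return levels[tuple(sl_a)], levels[tuple(sl_b)]


def build_glcm(roi, distance: int = 1) -> GLCM:
    """Symmetric GLCM counts for the 13 unique directions at Chebyshev distance 1."""
    if distance < 1:
        raise ValueError("distance must be >= 1")
    levels = roi.gray_levels
    if (levels > 0).sum() < 2:
        raise ValueError("GLCM needs an ROI with at least 2 voxels")
    ng = roi.n_bins
    out = {}
    for d in DIRECTIONS_13:
        a, b = _shifted_pairs(levels, d, distance)
        ok = (a > 0) & (b > 0)
        ai, bi = a[ok] - 1, b[ok] - 1
        mat = np.zeros((ng, ng))
        np.add.at(mat, (ai, bi), 1.0)
        mat = mat + mat.T  # symmetric accumulation: both voxel orders
        out[d] = mat
    return GLCM(out, ng, distance)


def _runs_along(levels: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """Run-length counts (levels x max run) along direction d.

    Dynamic programming: R[v] = 1 + R[v + d] when the next voxel along d is in
    the ROI with the same level, else 1. A run is counted at its start voxel
    (no ROI predecessor of the same level along -d).
    """
    ng = int(levels.max())
    shape = levels.shape
    run = np.where(levels > 0, 1, 0).astype(np.int32)
    # iterate along the first axis with a nonzero step so each update is vectorized
    axis = next(i for i, s in enumerate(d) if s != 0)
    step = d[axis]
    idxs = range(shape[axis] - 1, -1, -1) if step > 0 else range(shape[axis])

    def plane(i):
        sl = [slice(None)] * 3
        sl[axis] = i
        return tuple(sl)

    off = list(d)
    off[axis] = 0  # in-plane part of the offset

    def shift_plane(arr2d, off3):
        # shift a 2D plane by the in-plane components of the 3D offset
        o = [off3[i] for i in range(3) if i != axis]
        out = np.zeros_like(arr2d)
        src = [slice(None)] * 2
        dst = [slice(None)] * 2
        for k, s in enumerate(o):
            if s > 0:
                src[k] = slice(s, None)
                dst[k] = slice(None, -s)
            elif s < 0:
                src[k] = slice(None, s)
                dst[k] = slice(-s, None)
        out[tuple(dst)] = arr2d[tuple(src)]
        return out

    for i in idxs:
        j = i + step
        if j < 0 or j >= shape[axis]:
            continue
        cur = levels[plane(i)]
        nxt = shift_plane(levels[plane(j)], d)
        nxt_run = shift_plane(run[plane(j)], d)
        same = (cur > 0) & (cur == nxt)
        r = run[plane(i)]
        run[plane(i)] = np.where(same, 1 + nxt_run, r)

    # starts: ROI voxel whose predecessor along -d is outside ROI or differs
    prev = np.zeros_like(levels)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for k, s in enumerate(d):
        if s > 0:
            src[k] = slice(None, -s)
            dst[k] = slice(s, None)
        elif s < 0:
            src[k] = slice(-s, None)
            dst[k] = slice(None, s)
    prev[tuple(dst)] = levels[tuple(src)]
    start = (levels > 0) & (prev != levels)

    lv = levels[start] - 1
    rl = run[start]
    max_run = int(rl.max()) if rl.size else 1
    mat = np.zeros((ng, max_run))
    np.add.at(mat, (lv, rl - 1), 1.0)
    return mat


def build_glrlm(roi) -> GLRLM:
    levels = roi.gray_levels
    n_vox = int((levels > 0).sum())
    if n_vox == 0:
        raise ValueError("GLRLM needs a nonempty ROI")
    out = {d: _runs_along(levels, d) for d in DIRECTIONS_13}
    # pad all matrices to common run-length dimension and n_bins rows
    m = max(a.shape[1] for a in out.values())
    for d, a in out.items():
        full = np.zeros((roi.n_bins, m))
        full[: a.shape[0], : a.shape[1]] = a
        out[d] = full
    return GLRLM(out, roi.n_bins, n_vox)


def _zones(levels: np.ndarray, n_bins: int):
    """Yield (level, zone_size, zone_voxel_index_tuple) for 26-connected zones."""
    for g in range(1, n_bins + 1):
        binary = levels == g
        if not binary.any():
            continue
        lab, n = ndimage.label(binary, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        yield g, lab, n, sizes


def build_glszm(roi) -> GLSZM:
    levels = roi.gray_levels
    n_vox = int((levels > 0).sum())
    if n_vox == 0:
        raise ValueError("GLSZM needs a nonempty ROI")
    entries = []
    max_size = 1
    for g, lab, n, sizes in _zones(levels, roi.n_bins):
        for s in sizes:
            entries.append((g, int(s)))
            max_size = max(max_size, int(s))
    mat = np.zeros((roi.n_bins, max_size))
    for g, s in entries:
        mat[g - 1, s - 1] += 1.0
    return GLSZM(mat, roi.n_bins, n_vox)


def roi_border_distance(mask: np.ndarray) -> np.ndarray:
    """Chebyshev distance of each ROI voxel to the nearest non-ROI voxel.

    The image border counts as outside the ROI, so edge voxels get distance 1.
    """
    padded = np.pad(mask, 1, constant_values=False)
    dist = ndimage.distance_transform_cdt(padded, metric="chessboard")
    return dist[1:-1, 1:-1, 1:-1]


def build_gldzm(roi) -> GLDZM:
    levels = roi.gray_levels
    n_vox = int((levels > 0).sum())
    if n_vox == 0:
        raise ValueError("GLDZM needs a nonempty ROI")
    dist = roi_border_distance(levels > 0)
    entries = []
    max_d = 1
    for g, lab, n, sizes in _zones(levels, roi.n_bins):
        mins = ndimage.minimum(dist, labels=lab, index=np.arange(1, n + 1))
        for dmin in np.atleast_1d(mins):
            d = max(1, int(dmin))
            entries.append((g, d))
            max_d = max(max_d, d)
    mat = np.zeros((roi.n_bins, max_d))
    for g, d in entries:
        mat[g - 1, d - 1] += 1.0
    return GLDZM(mat, roi.n_bins, n_vox)


def build_ngldm(roi, alpha: int = 0, distance: int = 1) -> NGLDM:
    """Dependence counts: neighbors within the 26-neighborhood whose level
    differs from the center by at most ``alpha``. The center voxel itself is
    never counted, so dependence ranges 0..26."""
    if distance < 1:
        raise ValueError("distance must be >= 1")
    levels = roi.gray_levels
    n_vox = int((levels > 0).sum())
    if n_vox == 0:
        raise ValueError("NGLDM needs a nonempty ROI")
    dep = np.zeros(levels.shape, dtype=np.int32)
    for off in OFFSETS_26:
        a, b = _shifted_pairs(levels, off, distance)
        ok = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        sl_a = _slices_for(off, distance, levels.shape)
        dep[sl_a] += ok.astype(np.int32)
    mat = np.zeros((roi.n_bins, 27))
    roi_sel = levels > 0
    np.add.at(mat, (levels[roi_sel] - 1, dep[roi_sel]), 1.0)
    return NGLDM(mat, roi.n_bins, n_vox)


def _slices_for(d, distance, shape):
    sl = []
    for step in d:
        s = step * distance
        if s > 0:
            sl.append(slice(None, -s))
        elif s < 0:
            sl.append(slice(-s, None))
        else:
            sl.append(slice(None))
    return tuple(sl)


def build_ngtdm(roi, distance: int = 1) -> NGTDM:
    """Per-level occurrence counts and summed |level - mean of ROI neighbors|.

    Voxels with no ROI neighbor within the 26-neighborhood are excluded.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    levels = roi.gray_levels
    if not (levels > 0).any():
        raise ValueError("NGTDM needs a nonempty ROI")
    nb_sum = np.zeros(levels.shape, dtype=np.float64)
    nb_cnt = np.zeros(levels.shape, dtype=np.float64)
    for off in OFFSETS_26:
        a, b = _shifted_pairs(levels, off, distance)
        ok = (a > 0) & (b > 0)
        sl_a = _slices_for(off, distance, levels.shape)
        nb_sum[sl_a] += np.where(ok, b, 0)
        nb_cnt[sl_a] += ok
    valid = (levels > 0) & (nb_cnt > 0)
    diff = np.zeros(levels.shape)
    diff[valid] = np.abs(levels[valid] - nb_sum[valid] / nb_cnt[valid])
    ng = roi.n_bins
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    lv = levels[valid] - 1
    np.add.at(n_i, lv, 1.0)
    np.add.at(s_i, lv, diff[valid])
    return NGTDM(n_i, s_i, ng, int(n_i.sum()))


def build_all(roi, alpha: int = 0, distance: int = 1) -> TextureMatrices:
    """Build all six texture matrices from one discretized ROI."""
    return TextureMatrices(
        glcm=build_glcm(roi, distance),
        glrlm=build_glrlm(roi),
        glszm=build_glszm(roi),
        gldzm=build_gldzm(roi),
        ngldm=build_ngldm(roi, alpha, distance),
        ngtdm=build_ngtdm(roi, distance),
    )
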