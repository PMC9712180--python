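"""The 154-feature radiomic signature: 17 histogram + 137 texture features.

Feature identifiers are stable V-codes assigned from a declarative registry:

====================  ============  =========
family                count         V-codes
====================  ============  =========
HIST                  17            V1-V17
GLCM (averaged)       26            V18-V43
GLCM (merged)         26            V44-V69
GLRLM (averaged)      16            V70-V85
GLRLM (merged)        16            V86-V101
GLSZM                 16            V102-V117
GLDZM                 16            V118-V133
NGLDM                 16            V134-V149
NGTDM                 5             V150-V154
====================  ============  =========

Anchors: V1 mean, V2 standard deviation, V4 skewness, V5 kurtosis, V16 root
mean square (all histogram); V108 gray level non-uniformity normalized
(GLSZM); V141 dependence count non-uniformity (NGLDM).

Histogram features are computed on raw HU within the re-segmented ROI;
texture features on probability-normalized matrices, except the count-based
non-uniformities which use raw counts. Entropies use log base 2. Kurtosis is
Pearson (non-excess; a normal distribution scores 3).

GLCM and GLRLM are featurized under two aggregation schemes: *averaged*
(features per 3D direction, then averaged over the 13 directions) and
*merged* (count matrices summed over directions, then featurized).
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import texture
from .prep import RoiMask, Volume

logger = logging.getLogger(__name__)

META_COLUMNS = ["subject_id", "domain", "label", "observer", "repeat"]

# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

HIST_NAMES = [
    "mean", "standard_deviation", "median", "skewness", "kurtosis",
    "minimum", "percentile_10", "percentile_90", "maximum",
    "interquartile_range", "range", "mean_absolute_deviation",
    "robust_mean_absolute_deviation", "median_absolute_deviation",
    "coefficient_of_variation", "root_mean_square", "energy",
]

GLCM_NAMES = [
    "joint_maximum", "joint_average", "joint_variance", "joint_entropy",
    "difference_average", "difference_variance", "difference_entropy",
    "sum_average", "sum_variance", "sum_entropy",
    "angular_second_moment", "contrast", "dissimilarity",
    "inverse_difference", "inverse_difference_normalized",
    "inverse_difference_moment", "inverse_difference_moment_normalized",
    "inverse_variance", "correlation", "autocorrelation",
    "cluster_tendency", "cluster_shade", "cluster_prominence",
    "information_correlation_1", "information_correlation_2",
    "maximal_correlation_coefficient",
]

GLRLM_NAMES = [
    "short_runs_emphasis", "long_runs_emphasis",
    "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis", "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis", "long_run_high_gray_level_emphasis",
    "gray_level_non_uniformity", "gray_level_non_uniformity_normalized",
    "run_length_non_uniformity", "run_length_non_uniformity_normalized",
    "run_percentage", "gray_level_variance", "run_length_variance",
    "run_entropy",
]

GLSZM_NAMES = [
    "small_zone_emphasis", "large_zone_emphasis",
    "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
    "gray_level_non_uniformity", "zone_size_non_uniformity",
    "gray_level_non_uniformity_normalized", "zone_size_non_uniformity_normalized",
    "small_zone_low_gray_level_emphasis", "small_zone_high_gray_level_emphasis",
    "large_zone_low_gray_level_emphasis", "large_zone_high_gray_level_emphasis",
    "zone_percentage", "gray_level_variance", "zone_size_variance",
    "zone_size_entropy",
]

GLDZM_NAMES = [
    "small_distance_emphasis", "large_distance_emphasis",
    "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
    "gray_level_non_uniformity", "zone_distance_non_uniformity",
    "gray_level_non_uniformity_normalized", "zone_distance_non_uniformity_normalized",
    "small_distance_low_gray_level_emphasis", "small_distance_high_gray_level_emphasis",
    "large_distance_low_gray_level_emphasis", "large_distance_high_gray_level_emphasis",
    "zone_percentage", "gray_level_variance", "zone_distance_variance",
    "zone_distance_entropy",
]

NGLDM_NAMES = [
    "low_dependence_emphasis", "high_dependence_emphasis",
    "low_gray_level_count_emphasis", "high_gray_level_count_emphasis",
    "gray_level_non_uniformity", "gray_level_non_uniformity_normalized",
    "dependence_count_percentage", "dependence_count_non_uniformity",
    "dependence_count_non_uniformity_normalized",
    "low_dependence_low_gray_level_emphasis", "low_dependence_high_gray_level_emphasis",
    "high_dependence_low_gray_level_emphasis", "high_dependence_high_gray_level_emphasis",
    "gray_level_variance", "dependence_count_variance",
    "dependence_count_entropy",
]

NGTDM_NAMES = ["coarseness", "contrast", "busyness", "complexity", "strength"]


@dataclass(frozen=True)
class FeatureDef:
    feature_id: str  # V-code
    family: str      # HIST, GLCM_avg, GLCM_merged, GLRLM_avg, GLRLM_merged, GLSZM, GLDZM, NGLDM, NGTDM
    name: str


def _build_registry() -> list[FeatureDef]:
    blocks = [
        ("HIST", HIST_NAMES),
        ("GLCM_avg", GLCM_NAMES),
        ("GLCM_merged", GLCM_NAMES),
        ("GLRLM_avg", GLRLM_NAMES),
        ("GLRLM_merged", GLRLM_NAMES),
        ("GLSZM", GLSZM_NAMES),
        ("GLDZM", GLDZM_NAMES),
        ("NGLDM", NGLDM_NAMES),
        ("NGTDM", NGTDM_NAMES),
    ]
    reg, v = [], 1
    for family, names in blocks:
        for name in names:
            reg.append(FeatureDef(f"V{v}", family, name))
            v += 1
    return reg


REGISTRY: list[FeatureDef] = _build_registry()
FEATURE_IDS: list[str] = [d.feature_id for d in REGISTRY]
FAMILY_OF: dict[str, str] = {d.feature_id: d.family for d in REGISTRY}
NAME_OF: dict[str, str] = {d.feature_id: d.name for d in REGISTRY}

_ANCHORS = {
    "V1": ("HIST", "mean"),
    "V2": ("HIST", "standard_deviation"),
    "V4": ("HIST", "skewness"),
    "V5": ("HIST", "kurtosis"),
    "V16": ("HIST", "root_mean_square"),
    "V108": ("GLSZM", "gray_level_non_uniformity_normalized"),
    "V141": ("NGLDM", "dependence_count_non_uniformity"),
}
assert len(REGISTRY) == 154, "feature registry must define exactly 154 features"
for _vid, (_fam, _name) in _ANCHORS.items():
    assert (FAMILY_OF[_vid], NAME_OF[_vid]) == (_fam, _name), f"anchor {_vid} misplaced"


def registry_frame() -> pd.DataFrame:
    """The registry as a DataFrame (feature_id, family, name)."""
    return pd.DataFrame([d.__dict__ for d in REGISTRY])


# ---------------------------------------------------------------------------
# Histogram features
# ---------------------------------------------------------------------------

def histogram_features(vol: Volume, mask: RoiMask) -> OrderedDict[str, float]:
    """17 first-order statistics of raw HU within the ROI."""
    x = vol.data[mask.data]
    if x.size < 2:
        raise ValueError("histogram features need at least 2 ROI voxels")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    p10, p90 = np.percentile(x, [10, 90])
    med = float(np.median(x))
    if sd > 0:
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x, fisher=False))
    else:
        skew, kurt = 0.0, 0.0
    robust = x[(x >= p10) & (x <= p90)]
    out = OrderedDict()
    out["mean"] = mean
    out["standard_deviation"] = sd
    out["median"] = med
    out["skewness"] = skew
    out["kurtosis"] = kurt
    out["minimum"] = float(x.min())
    out["percentile_10"] = float(p10)
    out["percentile_90"] = float(p90)
    out["maximum"] = float(x.max())
    out["interquartile_range"] = float(np.percentile(x, 75) - np.percentile(x, 25))
    out["range"] = float(x.max() - x.min())
    out["mean_absolute_deviation"] = float(np.mean(np.abs(x - mean)))
    out["robust_mean_absolute_deviation"] = (
        float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0
    )
    out["median_absolute_deviation"] = float(np.mean(np.abs(x - med)))
    out["coefficient_of_variation"] = sd / mean if mean != 0 else 0.0
    out["root_mean_square"] = float(np.sqrt(np.mean(x**2)))
    out["energy"] = float(np.sum(x**2))
    return out


# ---------------------------------------------------------------------------
# GLCM features
# ---------------------------------------------------------------------------

def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def glcm_features(counts: np.ndarray) -> OrderedDict[str, float]:
    """26 features of one symmetric co-occurrence count matrix."""
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty co-occurrence matrix")
    P = counts / total
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)  # = py by symmetry
    mu = float(np.sum(I * P))
    # difference and sum distributions
    k_diff = np.arange(ng)
    p_diff = np.array([P[np.abs(I - J) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([P[(I + J) == k].sum() for k in k_sum])

    out = OrderedDict()
    out["joint_maximum"] = float(P.max())
    out["joint_average"] = mu
    out["joint_variance"] = float(np.sum((I - mu) ** 2 * P))
    out["joint_entropy"] = _entropy2(P.ravel())
    da = float(np.sum(k_diff * p_diff))
    out["difference_average"] = da
    out["difference_variance"] = float(np.sum((k_diff - da) ** 2 * p_diff))
    out["difference_entropy"] = _entropy2(p_diff)
    sa = float(np.sum(k_sum * p_sum))
    out["sum_average"] = sa
    out["sum_variance"] = float(np.sum((k_sum - sa) ** 2 * p_sum))
    out["sum_entropy"] = _entropy2(p_sum)
    out["angular_second_moment"] = float(np.sum(P**2))
    out["contrast"] = float(np.sum((I - J) ** 2 * P))
    out["dissimilarity"] = float(np.sum(np.abs(I - J) * P))
    out["inverse_difference"] = float(np.sum(P / (1 + np.abs(I - J))))
    out["inverse_difference_normalized"] = float(np.sum(P / (1 + np.abs(I - J) / ng)))
    out["inverse_difference_moment"] = float(np.sum(P / (1 + (I - J) ** 2)))
    out["inverse_difference_moment_normalized"] = float(
        np.sum(P / (1 + (I - J) ** 2 / ng**2))
    )
    off = I != J
    out["inverse_variance"] = float(np.sum(P[off] / (I[off] - J[off]) ** 2))
    var_x = float(np.sum((i - mu) ** 2 * px))
    if var_x > 0:
        out["correlation"] = float(
            (np.sum(I * J * P) - mu**2) / var_x
        )
    else:
        out["correlation"] = 1.0
    out["autocorrelation"] = float(np.sum(I * J * P))
    out["cluster_tendency"] = float(np.sum((I + J - 2 * mu) ** 2 * P))
    out["cluster_shade"] = float(np.sum((I + J - 2 * mu) ** 3 * P))
    out["cluster_prominence"] = float(np.sum((I + J - 2 * mu) ** 4 * P))
    # information measures of correlation
    hxy = out["joint_entropy"]
    hx = _entropy2(px)
    pxpy = np.outer(px, px)
    nz = (P > 0) & (pxpy > 0)
    hxy1 = float(-np.sum(P[nz] * np.log2(pxpy[nz])))
    nz2 = pxpy > 0
    hxy2 = float(-np.sum(pxpy[nz2] * np.log2(pxpy[nz2])))
    out["information_correlation_1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    out["information_correlation_2"] = float(
        np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * np.log(2) * (hxy2 - hxy))))
    )
    out["maximal_correlation_coefficient"] = _mcc(P, px)
    return out


def _mcc(P: np.ndarray, px: np.ndarray) -> float:
    """Haralick maximal correlation coefficient: sqrt of the second-largest
    eigenvalue of Q(i,j) = sum_k P(i,k) P(j,k) / (px(i) px(k))."""
    keep = px > 0
    if keep.sum() < 2:
        return 1.0
    Psub = P[np.ix_(keep, keep)]
    pxs = px[keep]
    Q = (Psub / pxs[:, None]) @ (Psub / pxs[None, :]).T
    ev = np.sort(np.real(np.linalg.eigvals(Q)))
    lam2 = max(0.0, min(1.0, float(ev[-2])))
    return float(np.sqrt(lam2))


# ---------------------------------------------------------------------------
# Generic zone/run-style features
# ---------------------------------------------------------------------------

def _szm_style(counts: np.ndarray, n_vox: float, kind: str,
               col_index: np.ndarray | None = None) -> OrderedDict[str, float]:
    """Shared feature math for GLRLM/GLSZM/GLDZM/NGLDM matrices.

    ``counts`` has rows = gray levels (1..Ng) and columns indexed by the
    second variable (run length, zone size, zone distance, or dependence
    count). ``col_index`` supplies the numeric value of each column (defaults
    to 1..m); NGLDM passes k+1 so dependence 0 keeps emphasis weights finite.
    """
    ns = counts.sum()
    if ns <= 0:
        raise ValueError("empty texture matrix")
    ng, m = counts.shape
    i = np.arange(1, ng + 1)
    j = col_index if col_index is not None else np.arange(1, m + 1)
    I, J = np.meshgrid(i, j, indexing="ij")
    p = counts / ns
    ri = counts.sum(axis=1)
    cj = counts.sum(axis=0)
    pi = ri / ns
    pj = cj / ns
    mu_i = float(np.sum(i * pi))
    mu_j = float(np.sum(j * pj))

    names = _SZM_NAME_MAP[kind]
    out = OrderedDict()
    out[names["sje"]] = float(np.sum(p / J**2))
    out[names["lje"]] = float(np.sum(p * J**2))
    out[names["lgl"]] = float(np.sum(pi / i**2))
    out[names["hgl"]] = float(np.sum(pi * i**2))
    out[names["sjlgl"]] = float(np.sum(p / (I**2 * J**2)))
    out[names["sjhgl"]] = float(np.sum(p * I**2 / J**2))
    out[names["ljlgl"]] = float(np.sum(p * J**2 / I**2))
    out[names["ljhgl"]] = float(np.sum(p * I**2 * J**2))
    out[names["glnu"]] = float(np.sum(ri**2) / ns)
    out[names["glnun"]] = float(np.sum(ri**2) / ns**2)
    out[names["jnu"]] = float(np.sum(cj**2) / ns)
    out[names["jnun"]] = float(np.sum(cj**2) / ns**2)
    out[names["pct"]] = float(ns / n_vox)
    out[names["glv"]] = float(np.sum((I - mu_i) ** 2 * p))
    out[names["jv"]] = float(np.sum((J - mu_j) ** 2 * p))
    out[names["ent"]] = _entropy2(p.ravel())
    return out


_SZM_NAME_MAP = {
    "GLRLM": dict(
        sje="short_runs_emphasis", lje="long_runs_emphasis",
        lgl="low_gray_level_run_emphasis", hgl="high_gray_level_run_emphasis",
        sjlgl="short_run_low_gray_level_emphasis", sjhgl="short_run_high_gray_level_emphasis",
        ljlgl="long_run_low_gray_level_emphasis", ljhgl="long_run_high_gray_level_emphasis",
        glnu="gray_level_non_uniformity", glnun="gray_level_non_uniformity_normalized",
        jnu="run_length_non_uniformity", jnun="run_length_non_uniformity_normalized",
        pct="run_percentage", glv="gray_level_variance", jv="run_length_variance",
        ent="run_entropy",
    ),
    "GLSZM": dict(
        sje="small_zone_emphasis", lje="large_zone_emphasis",
        lgl="low_gray_level_zone_emphasis", hgl="high_gray_level_zone_emphasis",
        sjlgl="small_zone_low_gray_level_emphasis", sjhgl="small_zone_high_gray_level_emphasis",
        ljlgl="large_zone_low_gray_level_emphasis", ljhgl="large_zone_high_gray_level_emphasis",
        glnu="gray_level_non_uniformity", glnun="gray_level_non_uniformity_normalized",
        jnu="zone_size_non_uniformity", jnun="zone_size_non_uniformity_normalized",
        pct="zone_percentage", glv="gray_level_variance", jv="zone_size_variance",
        ent="zone_size_entropy",
    ),
    "GLDZM": dict(
        sje="small_distance_emphasis", lje="large_distance_emphasis",
        lgl="low_gray_level_zone_emphasis", hgl="high_gray_level_zone_emphasis",
        sjlgl="small_distance_low_gray_level_emphasis", sjhgl="small_distance_high_gray_level_emphasis",
        ljlgl="large_distance_low_gray_level_emphasis", ljhgl="large_distance_high_gray_level_emphasis",
        glnu="gray_level_non_uniformity", glnun="gray_level_non_uniformity_normalized",
        jnu="zone_distance_non_uniformity", jnun="zone_distance_non_uniformity_normalized",
        pct="zone_percentage", glv="gray_level_variance", jv="zone_distance_variance",
        ent="zone_distance_entropy",
    ),
    "NGLDM": dict(
        sje="low_dependence_emphasis", lje="high_dependence_emphasis",
        lgl="low_gray_level_count_emphasis", hgl="high_gray_level_count_emphasis",
        sjlgl="low_dependence_low_gray_level_emphasis", sjhgl="low_dependence_high_gray_level_emphasis",
        ljlgl="high_dependence_low_gray_level_emphasis", ljhgl="high_dependence_high_gray_level_emphasis",
        glnu="gray_level_non_uniformity", glnun="gray_level_non_uniformity_normalized",
        jnu="dependence_count_non_uniformity", jnun="dependence_count_non_uniformity_normalized",
        pct="dependence_count_percentage", glv="gray_level_variance",
        jv="dependence_count_variance", ent="dependence_count_entropy",
    ),
}


def ngtdm_features(m: texture.NGTDM) -> OrderedDict[str, float]:
    """Coarseness, contrast, busyness, complexity, strength."""
    nv = m.n_i.sum()
    if nv <= 0:
        raise ValueError("empty NGTDM")
    p = m.n_i / nv
    s = m.s_i
    lev = np.arange(1, m.n_levels + 1, dtype=float)
    nz = p > 0
    ngp = int(nz.sum())
    ps = float(np.sum(p * s))
    out = OrderedDict()
    out["coarseness"] = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        ii, jj = np.meshgrid(lev[nz], lev[nz], indexing="ij")
        pp = np.outer(p[nz], p[nz])
        out["contrast"] = float(
            np.sum(pp * (ii - jj) ** 2) / (ngp * (ngp - 1)) * (s.sum() / nv)
        )
        denom = float(np.sum(np.abs(np.subtract.outer(lev[nz] * p[nz], lev[nz] * p[nz]))))
        out["busyness"] = ps / denom if denom > 0 else 0.0
        si, sj = np.meshgrid(s[nz], s[nz], indexing="ij")
        pi2, pj2 = np.meshgrid(p[nz], p[nz], indexing="ij")
        out["complexity"] = float(
            np.sum(np.abs(ii - jj) * (pi2 * si + pj2 * sj) / (pi2 + pj2)) / nv
        )
        ssum = float(s.sum())
        out["strength"] = (
            float(np.sum((pi2 + pj2) * (ii - jj) ** 2)) / ssum if ssum > 0 else 0.0
        )
    else:
        out["contrast"] = 0.0
        out["busyness"] = 0.0
        out["complexity"] = 0.0
        out["strength"] = 0.0
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _averaged(feature_fn, matrices: dict) -> OrderedDict[str, float]:
    # directions without a single valid pair (sparse ROIs) carry no signal
    per_dir = [feature_fn(m) for m in matrices.values() if m.sum() > 0]
    if not per_dir:
        raise ValueError("no direction produced a nonempty matrix")
    keys = per_dir[0].keys()
    return OrderedDict((k, float(np.mean([d[k] for d in per_dir]))) for k in keys)


def texture_features(mats: texture.TextureMatrices) -> OrderedDict[tuple[str, str], float]:
    """All 137 texture features keyed by (family, name)."""
    out: OrderedDict[tuple[str, str], float] = OrderedDict()

    for name, v in _averaged(glcm_features, mats.glcm.directional).items():
        out[("GLCM_avg", name)] = v
    for name, v in glcm_features(mats.glcm.merged()).items():
        out[("GLCM_merged", name)] = v

    nv = mats.glrlm.n_voxels
    avg = _averaged(lambda m: _szm_style(m, nv, "GLRLM"), mats.glrlm.directional)
    for name, v in avg.items():
        out[("GLRLM_avg", name)] = v
    merged = _szm_style(mats.glrlm.merged(), nv * len(mats.glrlm.directional), "GLRLM")
    for name, v in merged.items():
        out[("GLRLM_merged", name)] = v

    for name, v in _szm_style(mats.glszm.matrix, mats.glszm.n_voxels, "GLSZM").items():
        out[("GLSZM", name)] = v
    for name, v in _szm_style(mats.gldzm.matrix, mats.gldzm.n_voxels, "GLDZM").items():
        out[("GLDZM", name)] = v
    # NGLDM columns are dependence counts 0..26; weights use k+1 to stay finite
    ngldm_cols = np.arange(1, mats.ngldm.matrix.shape[1] + 1, dtype=float)
    for name, v in _szm_style(
        mats.ngldm.matrix, mats.ngldm.n_voxels, "NGLDM", col_index=ngldm_cols
    ).items():
        out[("NGLDM", name)] = v
    for name, v in ngtdm_features(mats.ngtdm).items():
        out[("NGTDM", name)] = v

    assert len(out) == 137
    return out


def extract_features(
    vol: Volume,
    mask: RoiMask,
    target_mm: float,
    hu_range: tuple[float, float] = (-1000.0, 200.0),
    bin_width: float = 50.0,
    alpha: int = 0,
    distance: int = 1,
    subject: str = "<unknown>",
) -> OrderedDict[str, float]:
    """Prepare one subject and compute the full 154-feature vector (V-codes)."""
    from .prep import prepare_subject

    rvol, smask, droi = prepare_subject(
        vol, mask, target_mm, hu_range, bin_width, subject=subject
    )
    logger.info("subject %s: %d ROI voxels after preparation", subject, droi.n_voxels())
    hist = histogram_features(rvol, smask)
    tex = texture_features(texture.build_all(droi, alpha=alpha, distance=distance))

    values: dict[tuple[str, str], float] = {("HIST", k): v for k, v in hist.items()}
    values.update(tex)
    out = OrderedDict()
    for d in REGISTRY:
        out[d.feature_id] = values[(d.family, d.name)]
    return out


def extract_all(cohort, config) -> pd.DataFrame:
    """Extract features for every entry of a cohort into a FeatureTable.

    ``cohort`` is an iterable of dicts with keys ``subject_id``, ``domain``,
    ``label``, ``observer``, ``repeat`` and either in-memory ``volume``/``mask``
    objects or ``volume_path``/``mask_path``. ``config`` maps each domain to a
    target spacing and holds the HU window / bin width.

    Any subject that fails preprocessing aborts the run with its id; rows are
    never silently dropped.
    """
    from .prep import read_mask, read_volume

    rows = []
    for entry in cohort:
        sid = entry["subject_id"]
        vol = entry.get("volume")
        mask = entry.get("mask")
        if vol is None:
            vol = read_volume(entry["volume_path"])
        if mask is None:
            mask = read_mask(entry["mask_path"])
        target = config.target_spacing_mm[entry["domain"]]
        try:
            feats = extract_features(
                vol, mask, target,
                hu_range=config.hu_range, bin_width=config.bin_width_hu,
                alpha=config.ngldm_alpha, distance=config.distance,
                subject=str(sid),
            )
        except Exception as exc:  # no silent row drops
            raise RuntimeError(f"feature extraction failed for subject {sid}: {exc}") from exc
        row = {k: entry.get(k) for k in META_COLUMNS}
        row.update(feats)
        rows.append(row)
    table = pd.DataFrame(rows)
    n_feat = len([c for c in table.columns if c not in META_COLUMNS])
    assert n_feat == 154, f"expected 154 feature columns, got {n_feat}"
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]
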