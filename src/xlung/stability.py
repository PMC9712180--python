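"""Delineation-stability analysis: intraclass correlation filtering.

Every radiomic feature is scored for robustness against intra- and
interobserver mask variability with the two-way mixed, consistency,
single-rater intraclass correlation — ICC(3,1) in the Shrout & Fleiss
taxonomy:

    ICC = (MS_R - MS_E) / (MS_R + (k - 1) MS_E)

where MS_R is the between-subject mean square and MS_E the residual mean
square of the two-way ANOVA decomposition with k raters. The consistency
variant ignores additive rater bias, which is the behaviour delineation
studies need (a systematically larger contour should not destabilize a
feature). A feature is retained only if its ICC meets the threshold
(default 0.75) in all four setting x domain cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FAMILY_OF, feature_columns


@dataclass
class IccResult:
    feature_id: str
    setting: str  # {"intra", "inter"}
    domain: str
    icc: float  # NaN when undefined (zero between-subject variance)
    ms_between: float
    ms_error: float


def icc_consistency(ratings: np.ndarray) -> tuple[float, float, float]:
    """ICC(3,1) of a subjects x raters grid; returns (icc, MS_R, MS_E).

    The ICC is NaN when the between-subject variance is zero (undefined;
    treated as unstable downstream).
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings contain missing or non-finite cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    # raters in perfect agreement (bias-free): consistent by definition, even
    # for a feature that is constant across subjects
    if np.all(x == x[:, [0]]):
        return 1.0, float(ms_r), float(ms_e)
    denom = ms_r + (k - 1) * ms_e
    if ms_r <= 0 or denom <= 0:
        return float("nan"), float(ms_r), float(ms_e)
    return float((ms_r - ms_e) / denom), float(ms_r), float(ms_e)


def _rating_grid(table: pd.DataFrame, feature_id: str, setting: str) -> np.ndarray:
    """subjects x raters grid for one feature.

    intra: repeated delineations of observer 1 act as raters;
    inter: first-repeat delineations of each observer act as raters.
    """
    if setting == "intra":
        sub = table[table["observer"] == 1]
        rater_col = "repeat"
    elif setting == "inter":
        sub = table[table["repeat"] == 1]
        rater_col = "observer"
    else:
        raise ValueError(f"unknown setting {setting!r}")
    grid = sub.pivot_table(index="subject_id", columns=rater_col, values=feature_id)
    grid = grid.dropna(axis=0, how="any")
    if grid.shape[1] < 2:
        raise ValueError(f"no {setting}-observer stability cells in the table")
    return grid.to_numpy()


def stability_filter(
    table: pd.DataFrame, threshold: float = 0.75
) -> tuple[list[str], list[IccResult], pd.DataFrame]:
    """Filter features by delineation stability.

    ``table`` is a FeatureTable whose stability subset carries multiple
    observers/repeats per subject in both domains. Returns the retained
    feature ids, all per-cell ICC results, and a per-family summary of
    unstable-feature proportions.

    A feature is retained iff ICC >= threshold in every (setting, domain)
    cell; an undefined ICC counts as unstable.
    """
    domains = sorted(table["domain"].unique())
    feats = feature_columns(table)
    results: list[IccResult] = []
    retained: list[str] = []
    for fid in feats:
        ok = True
        for domain in domains:
            dom_tab = table[table["domain"] == domain]
            # keep only subjects that actually have stability variants
            multi = dom_tab.groupby("subject_id").size()
            stab_ids = multi[multi > 1].index
            dom_tab = dom_tab[dom_tab["subject_id"].isin(stab_ids)]
            if dom_tab.empty:
                raise ValueError(f"domain {domain}: no stability subset present")
            for setting in ("intra", "inter"):
                grid = _rating_grid(dom_tab, fid, setting)
                icc, ms_r, ms_e = icc_consistency(grid)
                results.append(IccResult(fid, setting, domain, icc, ms_r, ms_e))
                if not (icc >= threshold):  # NaN fails too
                    ok = False
        if ok:
            retained.append(fid)
    unstable = {r.feature_id for r in results if not (r.icc >= threshold)}
    fam = pd.DataFrame(
        {"feature_id": feats, "family": [FAMILY_OF[f] for f in feats]}
    )
    fam["unstable"] = fam["feature_id"].isin(unstable)
    summary = fam.groupby("family")["unstable"].mean().rename("unstable_fraction").reset_index()
    return retained, results, summary


def stability_report(results: list[IccResult]) -> pd.DataFrame:
    """Wide per-feature report: one ICC column per (setting, domain) cell."""
    df = pd.DataFrame([r.__dict__ for r in results])
    wide = df.pivot_table(index="feature_id", columns=["setting", "domain"], values="icc")
    wide.columns = [f"icc_{s}_{d}" for s, d in wide.columns]
    wide = wide.reset_index()
    wide["family"] = wide["feature_id"].map(FAMILY_OF)
    return wide


def aggregation_redundancy(
    table: pd.DataFrame,
    threshold: float = 0.8,
    keep: str = "averaged",
    enabled: bool = True,
) -> tuple[list[str], dict[str, float]]:
    """Drop one GLCM/GLRLM aggregation variant when the two are redundant.

    For each family, the consistency ICC between the averaged and merged
    variant of every feature is computed across subjects (2 raters) and
    summarized by the family median. When the summary meets ``threshold``,
    the non-kept variant's columns are dropped. Returns the surviving
    feature ids and the per-family summary ICCs.
    """
    from .features import GLCM_NAMES, GLRLM_NAMES

    feats = feature_columns(table)
    if not enabled:
        return feats, {}
    drop_suffix = "merged" if keep == "averaged" else "avg"
    summaries: dict[str, float] = {}
    dropped: set[str] = set()
    for fam, names in (("GLCM", GLCM_NAMES), ("GLRLM", GLRLM_NAMES)):
        iccs = []
        pair_ids = []
        for name in names:
            avg_id = _fid_for(f"{fam}_avg", name)
            mrg_id = _fid_for(f"{fam}_merged", name)
            if avg_id not in feats or mrg_id not in feats:
                continue
            grid = table[[avg_id, mrg_id]].to_numpy()
            icc, _, _ = icc_consistency(grid)
            iccs.append(icc)
            pair_ids.append(_fid_for(f"{fam}_{drop_suffix}", name))
        if not iccs:
            continue
        summary = float(np.nanmedian(iccs))
        summaries[fam] = summary
        if summary >= threshold:
            dropped.update(pair_ids)
    kept = [f for f in feats if f not in dropped]
    return kept, summaries


def _fid_for(family: str, name: str) -> str:
    from .features import REGISTRY

    for d in REGISTRY:
        if d.family == family and d.name == name:
            return d.feature_id
    raise KeyError((family, name))
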