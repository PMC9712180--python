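"""Per-feature directional AUC and cross-domain correlation of predictive power.

The AUC convention is directional: AUC = P(value in positive class > value in
negative class), with ties credited 0.5 — the normalized Mann-Whitney U
statistic. Values below 0.5 are *not* flipped; an AUC of 0.3 in one domain
and 0.7 in the other signals an opposite effect direction, which is exactly
what the cross-domain comparison needs to detect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FAMILY_OF, feature_columns


@dataclass
class AucResult:
    feature_id: str
    domain: str
    auc: float
    n_pos: int
    n_neg: int


def directional_auc(values, labels, positive: str = "ild") -> float:
    """P(random positive value > random negative value), mid-rank ties.

    Computed from the rank-sum form of the Mann-Whitney U statistic.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    pos = values[labels == positive]
    neg = values[labels != positive]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be nonempty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def auc_table(table: pd.DataFrame, feature_ids=None, positive: str = "ild") -> pd.DataFrame:
    """Directional AUC of every feature, per domain."""
    feats = feature_ids if feature_ids is not None else feature_columns(table)
    rows = []
    for domain in sorted(table["domain"].unique()):
        sub = table[table["domain"] == domain]
        y = sub["label"].to_numpy()
        n_pos = int((y == positive).sum())
        n_neg = int((y != positive).sum())
        for fid in feats:
            rows.append(
                dict(
                    feature_id=fid,
                    family=FAMILY_OF.get(fid, "?"),
                    domain=domain,
                    auc=directional_auc(sub[fid].to_numpy(), y, positive),
                    n_pos=n_pos,
                    n_neg=n_neg,
                )
            )
    return pd.DataFrame(rows)


def cross_domain_correlation(aucs: pd.DataFrame) -> dict:
    """Pearson correlation of per-feature AUCs between the two domains.

    ``aucs`` is the output of :func:`auc_table` restricted to stable features.
    Returns the overall r, a per-family breakdown, and the matched scatter
    data (one row per feature).
    """
    domains = sorted(aucs["domain"].unique())
    if len(domains) != 2:
        raise ValueError(f"need exactly 2 domains, got {domains}")
    a, b = domains
    wide = aucs.pivot_table(index="feature_id", columns="domain", values="auc")
    wide = wide.dropna()
    if len(wide) < 3:
        raise ValueError("need at least 3 matched features to correlate")
    r, _ = stats.pearsonr(wide[a], wide[b])
    wide = wide.reset_index()
    wide["family"] = wide["feature_id"].map(FAMILY_OF)
    per_family = {}
    for fam, grp in wide.groupby("family"):
        if len(grp) >= 3 and grp[a].std() > 0 and grp[b].std() > 0:
            per_family[fam], _ = stats.pearsonr(grp[a], grp[b])
    return {
        "pearson_r": float(r),
        "per_family_r": {k: float(v) for k, v in per_family.items()},
        "scatter": wide,
        "domains": (a, b),
    }
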