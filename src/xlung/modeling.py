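"""Transfer modeling: train in a source domain, test and re-optimize in a target.

Three architectures are compared:

- MEAN: logistic regression on mean lung intensity only (V1);
- MSSK: logistic regression on the first four moments of the intensity
  distribution (mean V1, standard deviation V2, skewness V4, kurtosis V5);
- ML:   logistic regression with embedded feature selection — correlation
  pruning at a tunable Pearson threshold, then an L1-regularized logistic
  selector whose top-k coefficients feed the final L2 classifier.

Feature selection and tuning run inside 4-times repeated 5-fold
cross-validation with randomized hyperparameter search; standardization
statistics always come from the training folds only. Testing applies the
frozen source model (including source standardization) to the target domain;
re-optimization refits classifier weights in the target under the same CV
while keeping the source-selected features frozen. Threshold diagnostics are
reported at the cutoff maximizing Youden's J = TPR + TNR - 1, with stratified
bootstrap percentile confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold

from .features import feature_columns
from .univariate import directional_auc

FIXED_FEATURES = {"MEAN": ["V1"], "MSSK": ["V1", "V2", "V4", "V5"]}
POSITIVE_LABEL = "ild"


@dataclass
class ModelSpec:
    architecture: str = "ML"  # {"MEAN", "MSSK", "ML"}
    n_hyperparameter_samples: int = 500
    cv_repeats: int = 4
    cv_folds: int = 5
    corr_threshold_range: tuple[float, float] = (0.6, 0.99)
    k_range: tuple[int, int] = (1, 10)
    c_range: tuple[float, float] = (1e-3, 1e3)
    selector: str = "logistic"  # {"logistic", "tree"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("MEAN", "MSSK", "ML"):
            raise ValueError(f"unknown architecture {self.architecture!r}")


@dataclass
class FittedModel:
    spec: ModelSpec
    feature_ids: list[str]
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    classifier: LogisticRegression
    auc_tuning_mean: float
    auc_tuning_sd: float
    hyperparams: dict = field(default_factory=dict)

    def scores(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_ids if f not in table.columns]
        if missing:
            raise KeyError(f"target table lacks model features: {missing}")
        X = table[self.feature_ids].to_numpy(dtype=np.float64)
        Xs = (X - self.scaler_mean) / self.scaler_std
        return self.classifier.decision_function(Xs)


def _standardize(train: np.ndarray, *others):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return tuple(((a - mu) / sd) for a in (train, *others)) + (mu, sd)


def _labels01(labels) -> np.ndarray:
    return (np.asarray(labels) == POSITIVE_LABEL).astype(int)


def _auc01(scores: np.ndarray, y01: np.ndarray) -> float:
    labels = np.where(y01 == 1, POSITIVE_LABEL, "control")
    return directional_auc(scores, labels)


def _fold_aucs(X: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """Per-feature directional AUC on a training fold."""
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        out[j] = _auc01(X[:, j], y01)
    return out


def correlation_prune(
    corr: np.ndarray, aucs: np.ndarray, threshold: float
) -> np.ndarray:
    """Greedy pruning of highly correlated feature pairs.

    Features are visited in decreasing order of univariate discrimination
    (|AUC - 0.5|); a feature is kept only if its absolute Pearson correlation
    with every already-kept feature stays below the threshold. Returns the
    indices of kept features.
    """
    order = np.argsort(-np.abs(aucs - 0.5), kind="stable")
    kept: list[int] = []
    for j in order:
        if all(abs(corr[j, k]) < threshold for k in kept):
            kept.append(j)
    return np.array(sorted(kept), dtype=int)


def _select_features(
    Xs: np.ndarray, y01: np.ndarray, pruned: np.ndarray, k: int, selector: str
) -> np.ndarray:
    """Importance-based selection of k features among the pruned set."""
    if selector == "logistic":
        sel = LogisticRegression(l1_ratio=1.0, C=1.0, solver="liblinear", max_iter=200)
        sel.fit(Xs[:, pruned], y01)
        imp = np.abs(sel.coef_[0])
    elif selector == "tree":
        from sklearn.ensemble import GradientBoostingClassifier

        sel = GradientBoostingClassifier(n_estimators=50, max_depth=2, random_state=0)
        sel.fit(Xs[:, pruned], y01)
        imp = sel.feature_importances_
    else:
        raise ValueError(f"unknown selector {selector!r}")
    k = min(k, len(pruned))
    top = np.argsort(-imp, kind="stable")[:k]
    return pruned[np.sort(top)]


def _sample_hyperparams(spec: ModelSpec, rng: np.random.Generator) -> list[dict]:
    lo, hi = np.log(spec.c_range[0]), np.log(spec.c_range[1])
    samples = []
    for _ in range(spec.n_hyperparameter_samples):
        h = {"C": float(np.exp(rng.uniform(lo, hi)))}
        if spec.architecture == "ML":
            h["corr_threshold"] = float(rng.uniform(*spec.corr_threshold_range))
            h["k"] = int(rng.integers(spec.k_range[0], spec.k_range[1] + 1))
        samples.append(h)
    return samples


def tune(spec: ModelSpec, source: pd.DataFrame) -> FittedModel:
    """Cross-validated randomized search on the source domain, then a full refit.

    Returns the model refit on all source data with the winning configuration,
    carrying the winning configuration's mean +/- SD cross-validation AUC.
    """
    feats = feature_columns(source)
    if spec.architecture in FIXED_FEATURES:
        feats = FIXED_FEATURES[spec.architecture]
    X = source[feats].to_numpy(dtype=np.float64)
    y = _labels01(source["label"])
    if y.min() == y.max():
        raise ValueError("source domain must contain both classes")

    rkf = RepeatedStratifiedKFold(
        n_splits=spec.cv_folds, n_repeats=spec.cv_repeats,
        random_state=spec.seed % (2**31),
    )
    folds = []
    for tr, va in rkf.split(X, y):
        Xtr, Xva, mu, sd = _standardize(X[tr], X[va])
        fold = {"Xtr": Xtr, "Xva": Xva, "ytr": y[tr], "yva": y[va]}
        if spec.architecture == "ML":
            fold["aucs"] = _fold_aucs(Xtr, y[tr])
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(Xtr, rowvar=False)
            fold["corr"] = np.nan_to_num(corr, nan=0.0)
            fold["prune_cache"] = {}
        folds.append(fold)

    rng = np.random.default_rng(spec.seed)
    samples = _sample_hyperparams(spec, rng)

    best = None
    for h in samples:
        fold_scores = []
        for fold in folds:
            Xtr, ytr = fold["Xtr"], fold["ytr"]
            if spec.architecture == "ML":
                key = round(h["corr_threshold"], 6)
                pruned = fold["prune_cache"].get(key)
                if pruned is None:
                    pruned = correlation_prune(fold["corr"], fold["aucs"], h["corr_threshold"])
                    fold["prune_cache"][key] = pruned
                sel = _select_features(Xtr, ytr, pruned, h["k"], spec.selector)
            else:
                sel = np.arange(Xtr.shape[1])
            clf = LogisticRegression(C=h["C"], max_iter=500)
            clf.fit(Xtr[:, sel], ytr)
            val = clf.decision_function(fold["Xva"][:, sel])
            fold_scores.append(_auc01(val, fold["yva"]))
        mean_auc = float(np.mean(fold_scores))
        if best is None or mean_auc > best[0]:
            best = (mean_auc, float(np.std(fold_scores)), h)

    mean_auc, sd_auc, h = best
    # final refit on all source data with the winning configuration
    Xs, mu, sd = _standardize(X)[0], X.mean(axis=0), np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    if spec.architecture == "ML":
        aucs = _fold_aucs(Xs, y)
        with np.errstate(invalid="ignore"):
            corr = np.nan_to_num(np.corrcoef(Xs, rowvar=False), nan=0.0)
        pruned = correlation_prune(corr, aucs, h["corr_threshold"])
        sel = _select_features(Xs, y, pruned, h["k"], spec.selector)
    else:
        sel = np.arange(Xs.shape[1])
    clf = LogisticRegression(C=h["C"], max_iter=500)
    clf.fit(Xs[:, sel], y)
    return FittedModel(
        spec=spec,
        feature_ids=[feats[j] for j in sel],
        scaler_mean=mu[sel],
        scaler_std=sd[sel],
        classifier=clf,
        auc_tuning_mean=mean_auc,
        auc_tuning_sd=sd_auc,
        hyperparams=h,
    )


def _stratified_bootstrap_ci(
    stat_fn, scores: np.ndarray, y01: np.ndarray, n_boot: int, rng, level: float = 0.95
):
    pos = np.flatnonzero(y01 == 1)
    neg = np.flatnonzero(y01 == 0)
    vals = []
    for _ in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, size=pos.size), rng.choice(neg, size=neg.size)]
        )
        vals.append(stat_fn(scores[idx], y01[idx]))
    vals = np.asarray(vals, dtype=np.float64)
    lo, hi = np.nanpercentile(vals, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


def test_transfer(
    model: FittedModel, target: pd.DataFrame, n_boot: int = 2000, seed: int = 0
) -> dict:
    """Apply the frozen source model to the target domain.

    Returns the testing AUC with a stratified bootstrap percentile CI.
    """
    scores = model.scores(target)
    y = _labels01(target["label"])
    if y.min() == y.max():
        raise ValueError("target domain must contain both classes")
    auc = _auc01(scores, y)
    rng = np.random.default_rng(seed)
    lo, hi = _stratified_bootstrap_ci(_auc01, scores, y, n_boot, rng)
    return {"auc_testing": float(auc), "ci95": (lo, hi), "scores": scores, "labels01": y}


def reoptimize(model: FittedModel, target: pd.DataFrame, seed: int = 0) -> dict:
    """Re-optimize the classifier in the target domain on the frozen signature.

    The feature list selected in the source is never re-selected; the
    standardization, the regularization strength, and the logistic weights
    are re-estimated under the same repeated CV and randomized search as
    tuning.
    """
    feats = model.feature_ids
    X = target[feats].to_numpy(dtype=np.float64)
    y = _labels01(target["label"])
    spec = model.spec
    rkf = RepeatedStratifiedKFold(
        n_splits=spec.cv_folds, n_repeats=spec.cv_repeats, random_state=seed % (2**31)
    )
    folds = []
    for tr, va in rkf.split(X, y):
        Xtr, Xva, _, _ = _standardize(X[tr], X[va])
        folds.append((Xtr, Xva, y[tr], y[va]))
    rng = np.random.default_rng(seed)
    lo, hi = np.log(spec.c_range[0]), np.log(spec.c_range[1])
    best = None
    for _ in range(spec.n_hyperparameter_samples):
        c = float(np.exp(rng.uniform(lo, hi)))
        aucs = []
        for Xtr, Xva, ytr, yva in folds:
            clf = LogisticRegression(C=c, max_iter=500)
            clf.fit(Xtr, ytr)
            aucs.append(_auc01(clf.decision_function(Xva), yva))
        mean_auc = float(np.mean(aucs))
        if best is None or mean_auc > best[0]:
            best = (mean_auc, float(np.std(aucs)), c)
    mean_auc, sd_auc, c = best
    Xs, mu, sd = _standardize(X)[0], X.mean(axis=0), np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    clf = LogisticRegression(C=c, max_iter=500)
    clf.fit(Xs, y)
    refit = FittedModel(
        spec=spec, feature_ids=feats, scaler_mean=mu, scaler_std=sd,
        classifier=clf, auc_tuning_mean=mean_auc, auc_tuning_sd=sd_auc,
        hyperparams=dict(model.hyperparams, C=c),
    )
    return {
        "auc_reopt_mean": mean_auc,
        "auc_reopt_sd": sd_auc,
        "model": refit,
    }


# ---------------------------------------------------------------------------
# Threshold diagnostics (Youden's J)
# ---------------------------------------------------------------------------

def _youden_point(scores: np.ndarray, y01: np.ndarray):
    """Cutoff maximizing J = TPR + TNR - 1 over observed score thresholds.

    Predict positive when score >= cutoff. Ties on J resolve to the higher
    specificity, then to the higher cutoff.
    """
    cand = np.unique(scores)
    best = None
    for c in cand:
        pred = scores >= c
        tp = int(np.sum(pred & (y01 == 1)))
        fn = int(np.sum(~pred & (y01 == 1)))
        tn = int(np.sum(~pred & (y01 == 0)))
        fp = int(np.sum(pred & (y01 == 0)))
        tpr = tp / (tp + fn)
        tnr = tn / (tn + fp)
        j = tpr + tnr - 1.0
        key = (j, tnr, c)
        if best is None or key > best[0]:
            best = (key, c, tpr, tnr, tp, fn, tn, fp)
    return best[1:]


def _diag_at_cutoff(scores, y01):
    cutoff, tpr, tnr, tp, fn, tn, fp = _youden_point(scores, y01)
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    npv = tn / (tn + fn) if (tn + fn) > 0 else float("nan")
    lr_pos = tpr / (1 - tnr) if tnr < 1 else math.inf
    lr_neg = (1 - tpr) / tnr if tnr > 0 else math.inf
    return dict(cutoff=cutoff, tpr=tpr, tnr=tnr, ppv=ppv, npv=npv,
                lr_pos=lr_pos, lr_neg=lr_neg)


def threshold_diagnostics(
    scores, labels, n_boot: int = 2000, seed: int = 0, positive: str = POSITIVE_LABEL
) -> dict:
    """Youden-optimal operating point diagnostics with bootstrap 95% CIs.

    Returns TPR, TNR, PPV, NPV, LR+ and LR- at the cutoff maximizing
    Youden's J. LR+ is +inf when TNR = 1 on the point estimate; its CI is
    taken over the bootstrap resamples (infinities participate as +inf).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if np.issubdtype(labels.dtype, np.number) or labels.dtype == bool:
        y01 = labels.astype(int)
    else:
        y01 = (labels == positive).astype(int)
    if y01.min() == y01.max():
        raise ValueError("both classes must be present")
    point = _diag_at_cutoff(scores, y01)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y01 == 1)
    neg = np.flatnonzero(y01 == 0)
    boot = {k: [] for k in ("tpr", "tnr", "ppv", "npv", "lr_pos", "lr_neg")}
    for _ in range(n_boot):
        idx = np.concatenate([rng.choice(pos, size=pos.size), rng.choice(neg, size=neg.size)])
        d = _diag_at_cutoff(scores[idx], y01[idx])
        for k in boot:
            boot[k].append(d[k])
    out = dict(point)
    huge = 1e300  # stand-in for +inf so percentile interpolation stays defined
    for k, vals in boot.items():
        arr = np.asarray(vals, dtype=np.float64)
        arr = np.where(np.isposinf(arr), huge, arr)
        lo, hi = np.nanpercentile(arr, [2.5, 97.5])
        out[f"{k}_ci95"] = tuple(math.inf if v >= huge else float(v) for v in (lo, hi))
    return out


def sign_report(model: FittedModel) -> dict:
    """Sign of each standardized coefficient of a linear final classifier."""
    clf = model.classifier
    if not hasattr(clf, "coef_"):
        return {"applicable": False}
    coefs = clf.coef_[0]
    return {
        "applicable": True,
        "signs": {f: int(np.sign(c)) for f, c in zip(model.feature_ids, coefs)},
        "coefficients": {f: float(c) for f, c in zip(model.feature_ids, coefs)},
    }


# ---------------------------------------------------------------------------
# End-to-end transfer report
# ---------------------------------------------------------------------------

def transfer_report(
    spec: ModelSpec,
    source: pd.DataFrame,
    target: pd.DataFrame,
    seed: int = 0,
    n_boot: int = 2000,
) -> dict:
    """Tune on source, test on target, re-optimize in target, report diagnostics."""
    model = tune(spec, source)
    test = test_transfer(model, target, n_boot=n_boot, seed=seed)
    reopt = reoptimize(model, target, seed=seed)
    diag = threshold_diagnostics(test["scores"], test["labels01"], n_boot=n_boot, seed=seed + 1)
    return {
        "architecture": spec.architecture,
        "selected_features": model.feature_ids,
        "hyperparams": model.hyperparams,
        "auc_tuning_mean": model.auc_tuning_mean,
        "auc_tuning_sd": model.auc_tuning_sd,
        "auc_testing": test["auc_testing"],
        "auc_testing_ci95": test["ci95"],
        "auc_reopt_mean": reopt["auc_reopt_mean"],
        "auc_reopt_sd": reopt["auc_reopt_sd"],
        "diagnostics": diag,
        "model": model,
        "reopt_model": reopt["model"],
    }
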