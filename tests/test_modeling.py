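"""Model tuning, transfer, re-optimization, and Youden threshold diagnostics."""

import numpy as np
import pandas as pd
import pytest

import oracles
from xlung import modeling
from xlung.features import FEATURE_IDS


def make_table(n=60, effects=None, seed=0, domain="microct",
               shift=None, scale=None, n_feat=20):
    """Tabular synthetic cohort: Gaussian features with per-feature class effects."""
    rng = np.random.default_rng(seed)
    effects = np.asarray(effects if effects is not None else rng.normal(0, 1.2, n_feat))
    n_feat = len(effects)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(0, 1, (n, n_feat)) + np.outer(y, effects)
    if shift is not None:
        X = X + np.asarray(shift)
    if scale is not None:
        X = X * np.asarray(scale)
    cols = FEATURE_IDS[:n_feat]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "subject_id", [f"{domain}_{i}" for i in range(n)])
    df.insert(1, "domain", domain)
    df.insert(2, "label", np.where(y == 1, "ild", "control"))
    df.insert(3, "observer", 1)
    df.insert(4, "repeat", 1)
    return df


def _spec(arch="ML", samples=25, seed=0):
    return modeling.ModelSpec(architecture=arch, n_hyperparameter_samples=samples,
                              seed=seed)


class TestTune:
    def test_mean_uses_exactly_one_predictor(self):
        model = modeling.tune(_spec("MEAN"), make_table())
        assert model.feature_ids == ["V1"]

    def test_mssk_uses_the_four_moments(self):
        model = modeling.tune(_spec("MSSK"), make_table())
        assert model.feature_ids == ["V1", "V2", "V4", "V5"]

    @pytest.mark.parametrize("arch", ["MEAN", "MSSK", "ML"])
    def test_separable_source_high_tuning_auc(self, arch):
        # V1 alone separates the classes by 6 SD
        effects = np.zeros(12)
        effects[0] = 6.0
        table = make_table(n=60, effects=effects, seed=1)
        model = modeling.tune(_spec(arch, samples=15), table)
        assert model.auc_tuning_mean >= 0.95

    def test_same_seed_identical_result(self):
        table = make_table(seed=3)
        a = modeling.tune(_spec("ML", seed=11), table)
        b = modeling.tune(_spec("ML", seed=11), table)
        assert a.feature_ids == b.feature_ids
        assert a.auc_tuning_mean == b.auc_tuning_mean
        assert a.hyperparams == b.hyperparams

    def test_single_class_source_errors(self):
        table = make_table()
        table["label"] = "control"
        with pytest.raises(ValueError):
            modeling.tune(_spec("MEAN"), table)


class TestCorrelationPrune:
    def test_keeps_higher_auc_of_correlated_pair(self):
        corr = np.array([[1.0, 0.95], [0.95, 1.0]])
        aucs = np.array([0.9, 0.6])
        kept = modeling.correlation_prune(corr, aucs, threshold=0.8)
        assert kept.tolist() == [0]

    def test_uncorrelated_features_all_kept(self):
        corr = np.eye(4)
        aucs = np.array([0.6, 0.7, 0.4, 0.55])
        kept = modeling.correlation_prune(corr, aucs, threshold=0.8)
        assert kept.tolist() == [0, 1, 2, 3]


class TestTransfer:
    def test_degenerate_transfer_target_equals_source(self):
        table = make_table(n=80, seed=5)
        model = modeling.tune(_spec("ML", samples=15), table)
        out = modeling.test_transfer(model, table, n_boot=200)
        train_auc = modeling._auc01(model.scores(table),
                                    modeling._labels01(table["label"]))
        assert out["auc_testing"] == pytest.approx(train_auc)

    def test_label_permuted_target_is_chance_level(self):
        table = make_table(n=80, seed=6)
        model = modeling.tune(_spec("MEAN"), table)
        rng = np.random.default_rng(0)
        permuted = table.copy()
        permuted["label"] = rng.permutation(permuted["label"].to_numpy())
        out = modeling.test_transfer(model, permuted, n_boot=500, seed=1)
        lo, hi = out["ci95"]
        assert lo <= 0.5 <= hi

    def test_missing_feature_column_errors(self):
        table = make_table()
        model = modeling.tune(_spec("MEAN"), table)
        with pytest.raises(KeyError):
            model.scores(table.drop(columns=["V1"]))

    def test_heterogeneous_distortion_degrades_ml_transfer(self):
        """Feature-wise shifts and rescalings (domain shift) must lower the
        frozen multivariate model's target AUC relative to a clean target."""
        rng = np.random.default_rng(9)
        effects = rng.normal(0, 0.8, 15)
        source = make_table(n=80, effects=effects, seed=10)
        clean = make_table(n=80, effects=effects, seed=20, domain="hrct")
        distorted = make_table(n=80, effects=effects * rng.uniform(0.2, 1.0, 15),
                               seed=20, domain="hrct",
                               shift=rng.normal(0, 2, 15),
                               scale=rng.uniform(0.5, 2, 15))
        model = modeling.tune(_spec("ML", samples=20, seed=2), source)
        auc_clean = modeling.test_transfer(model, clean, n_boot=50)["auc_testing"]
        auc_dist = modeling.test_transfer(model, distorted, n_boot=50)["auc_testing"]
        assert auc_dist < auc_clean


class TestReoptimize:
    def test_features_frozen_from_source(self):
        source = make_table(n=60, seed=7)
        target = make_table(n=60, seed=8, domain="hrct")
        model = modeling.tune(_spec("ML", samples=15), source)
        out = modeling.reoptimize(model, target)
        assert out["model"].feature_ids == model.feature_ids

    def test_target_equals_source_recovers_tuning_auc(self):
        table = make_table(n=80, effects=[3.0] + [0.0] * 9, seed=12)
        model = modeling.tune(_spec("MEAN"), table)
        out = modeling.reoptimize(model, table)
        assert out["auc_reopt_mean"] == pytest.approx(model.auc_tuning_mean, abs=0.05)

    def test_pure_shift_absorbed_by_refit(self):
        effects = [2.5, 1.5, 0.0, 0.0]
        source = make_table(n=80, effects=effects, seed=13)
        target = make_table(n=80, effects=effects, seed=14, domain="hrct",
                            shift=[4.0, -3.0, 1.0, 0.0], scale=[2.0, 0.5, 1.0, 1.0])
        model = modeling.tune(_spec("ML", samples=15), source)
        reopt = modeling.reoptimize(model, target)
        assert reopt["auc_reopt_mean"] >= model.auc_tuning_mean - 0.1


class TestYouden:
    def test_perfect_separation(self):
        d = modeling.threshold_diagnostics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], n_boot=50)
        assert d["tpr"] == 1.0 and d["tnr"] == 1.0
        assert np.isinf(d["lr_pos"])

    def test_anti_informative_scores(self):
        # scores are the flipped labels: best achievable J is 0
        d = modeling.threshold_diagnostics([0.0, 0.0, 1.0, 1.0], [1, 1, 0, 0], n_boot=50)
        assert d["tpr"] + d["tnr"] == pytest.approx(1.0)

    def test_toy_set_matches_exhaustive_scan(self):
        scores = [0.9, 0.8, 0.4, 0.3, 0.2]
        y = [1, 1, 1, 0, 0]
        expected = oracles.youden_scan(scores, y)
        d = modeling.threshold_diagnostics(scores, y, n_boot=50)
        assert d["cutoff"] == expected["cutoff"]
        assert d["tpr"] == pytest.approx(expected["tpr"])
        assert d["tnr"] == pytest.approx(expected["tnr"])

    @pytest.mark.parametrize("seed", range(20))
    def test_fuzz_against_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 25)
        scores = rng.integers(0, 8, n).astype(float) / 7
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        expected = oracles.youden_scan(scores.tolist(), y.tolist())
        d = modeling.threshold_diagnostics(scores, y, n_boot=10)
        assert d["tpr"] + d["tnr"] - 1 == pytest.approx(expected["j"], abs=1e-12)
        assert d["cutoff"] == expected["cutoff"]

    def test_likelihood_ratio_identities(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=40) + np.repeat([0, 1], 20)
        y = np.repeat([0, 1], 20)
        d = modeling.threshold_diagnostics(scores, y, n_boot=50)
        if d["tnr"] < 1:
            assert d["lr_pos"] == pytest.approx(d["tpr"] / (1 - d["tnr"]))
        assert d["lr_neg"] == pytest.approx((1 - d["tpr"]) / d["tnr"])


class TestSignReport:
    def test_negated_feature_flips_sign(self):
        effects = [2.0, -1.5, 0.3, 1.0, 0.5]
        table = make_table(n=100, effects=effects, seed=15)
        spec = modeling.ModelSpec(architecture="MSSK", n_hyperparameter_samples=10)
        model = modeling.tune(spec, table)
        signs = modeling.sign_report(model)["signs"]
        flipped = table.copy()
        flipped["V2"] = -flipped["V2"]
        model2 = modeling.tune(spec, flipped)
        signs2 = modeling.sign_report(model2)["signs"]
        assert signs["V2"] == -signs2["V2"]
        assert signs["V1"] == signs2["V1"]

    def test_zero_effect_feature_has_smallest_coefficient(self):
        effects = [3.0, 2.0, 0.0, -2.0, 0.0]  # V5 carries no signal
        table = make_table(n=200, effects=effects, seed=16)
        spec = modeling.ModelSpec(architecture="MSSK", n_hyperparameter_samples=10)
        model = modeling.tune(spec, table)
        coefs = modeling.sign_report(model)["coefficients"]
        assert abs(coefs["V5"]) == min(abs(c) for c in coefs.values())


def test_bootstrap_ci_coverage_near_nominal():
    """Empirical coverage of the 95% stratified bootstrap AUC CI stays
    within [0.90, 0.99] on a Gaussian two-class calibration simulation."""
    from scipy.stats import norm

    delta = 1.0
    true_auc = norm.cdf(delta / np.sqrt(2))
    rng = np.random.default_rng(2024)
    hits = 0
    m = 120
    for _ in range(m):
        scores = np.concatenate([rng.normal(0, 1, 40), rng.normal(delta, 1, 40)])
        y = np.repeat([0, 1], 40)
        lo, hi = modeling._stratified_bootstrap_ci(
            modeling._auc01, scores, y, n_boot=400, rng=rng)
        hits += lo <= true_auc <= hi
    assert 0.90 <= hits / m <= 0.99
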