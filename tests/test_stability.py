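"""ICC consistency, stability filtering, and aggregation redundancy."""

import numpy as np
import pandas as pd
import pytest

import oracles
from xlung import features, stability


class TestIccConsistency:
    def test_identical_raters_give_one(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 3))
        icc, ms_r, ms_e = stability.icc_consistency(x)
        assert icc == pytest.approx(1.0)

    def test_additive_rater_bias_ignored(self):
        base = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        x = np.column_stack([base, base + 10.0, base - 3.0])
        icc, _, _ = stability.icc_consistency(x)
        assert icc == pytest.approx(1.0)

    def test_fixed_integer_grid_matches_longhand_anova(self):
        x = np.array([
            [9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2], [10, 5, 6],
        ], dtype=float)
        icc, _, _ = stability.icc_consistency(x)
        assert icc == pytest.approx(oracles.anova_icc31(x), abs=1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_random_grids_match_oracle_to_1e10(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1)) * 2
        icc, _, _ = stability.icc_consistency(x)
        assert icc == pytest.approx(oracles.anova_icc31(x), abs=1e-10)

    def test_matches_pingouin_icc3(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(77)
        x = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 1.5
        df = pd.DataFrame(x).reset_index().melt(
            id_vars="index", var_name="rater", value_name="score")
        res = pg.intraclass_corr(df, targets="index", raters="rater", ratings="score")
        # two-way consistency, single rater: pingouin's ICC(C,1) == ICC(3,1)
        expected = float(res.loc[res["Type"] == "ICC(C,1)", "ICC"].iloc[0])
        icc, _, _ = stability.icc_consistency(x)
        assert icc == pytest.approx(expected, abs=1e-9)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 4)) + rng.normal(size=(8, 1))
        a, _, _ = stability.icc_consistency(x)
        b, _, _ = stability.icc_consistency(3.7 * x - 120.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_between_subject_variance_is_undefined(self):
        # subjects indistinguishable, raters systematically different
        x = np.tile([1.0, 2.0, 3.0], (5, 1))
        icc, _, _ = stability.icc_consistency(x)
        assert np.isnan(icc)

    def test_perfectly_agreeing_raters_are_consistent_even_for_constant_feature(self):
        icc, _, _ = stability.icc_consistency(np.ones((5, 3)))
        assert icc == 1.0


def _toy_table(jitter=0.0, seed=0, n_subj=8):
    """Minimal FeatureTable with stability variants in two domains."""
    rng = np.random.default_rng(seed)
    rows = []
    for domain in ("microct", "hrct"):
        for s in range(n_subj):
            base = rng.normal(size=154) * 10
            for obs, rep in [(1, 1), (1, 2), (2, 1), (3, 1)]:
                noise = rng.normal(size=154) * jitter
                row = dict(subject_id=f"{domain}_{s}", domain=domain,
                           label="ild" if s % 2 else "control",
                           observer=obs, repeat=rep)
                row.update({fid: base[i] + noise[i]
                            for i, fid in enumerate(features.FEATURE_IDS)})
                rows.append(row)
    return pd.DataFrame(rows)


class TestStabilityFilter:
    def test_zero_perturbation_retains_all_154(self):
        table = _toy_table(jitter=0.0)
        retained, results, summary = stability.stability_filter(table, 0.75)
        assert len(retained) == 154
        assert (summary["unstable_fraction"] == 0).all()

    def test_impossible_threshold_retains_none(self):
        table = _toy_table(jitter=0.0)
        retained, _, _ = stability.stability_filter(table, 1.01)
        assert retained == []

    def test_minus_infinity_threshold_is_identity(self):
        table = _toy_table(jitter=0.5)
        retained, _, _ = stability.stability_filter(table, float("-inf"))
        assert retained == features.FEATURE_IDS

    def test_heavy_noise_destabilizes(self):
        table = _toy_table(jitter=40.0, seed=4)
        retained, _, _ = stability.stability_filter(table, 0.75)
        assert len(retained) < 154


class TestAggregationRedundancy:
    def test_identical_variants_dropped(self):
        table = _toy_table(jitter=0.0)
        # make merged identical to averaged
        for fam, names in (("GLCM", features.GLCM_NAMES), ("GLRLM", features.GLRLM_NAMES)):
            for name in names:
                a = stability._fid_for(f"{fam}_avg", name)
                m = stability._fid_for(f"{fam}_merged", name)
                table[m] = table[a]
        main = table[(table.observer == 1) & (table.repeat == 1)]
        kept, summaries = stability.aggregation_redundancy(main, threshold=0.8)
        assert summaries["GLCM"] == pytest.approx(1.0)
        assert summaries["GLRLM"] == pytest.approx(1.0)
        assert len(kept) == 154 - 42  # merged GLCM (26) + merged GLRLM (16) dropped
        assert not any(features.FAMILY_OF[f].endswith("merged") for f in kept)

    def test_independent_columns_both_kept(self):
        table = _toy_table(jitter=0.0, seed=11, n_subj=40)
        main = table[(table.observer == 1) & (table.repeat == 1)]
        kept, summaries = stability.aggregation_redundancy(main, threshold=0.8)
        # independent random columns: near-zero ICC, nothing dropped
        assert abs(summaries["GLCM"]) < 0.4
        assert len(kept) == 154

    def test_disabled_passes_everything_through(self):
        table = _toy_table(jitter=0.0)
        main = table[(table.observer == 1) & (table.repeat == 1)]
        kept, summaries = stability.aggregation_redundancy(main, enabled=False)
        assert len(kept) == 154
        assert summaries == {}


def test_gldzm_less_stable_than_histogram_under_heavy_jitter():
    """Distance zones depend on where the ROI border sits; with the phantom
    embedded in lung-equivalent surroundings (so including or excluding a
    boundary shell leaves the HU histogram statistically unchanged), heavy
    boundary jitter must destabilize GLDZM features at least as much as
    histogram features."""
    from xlung import synthetic
    from xlung.pipeline import ExtractionConfig

    rng = np.random.default_rng(13)
    obs = synthetic.ObserverPerturbation(n_observers=3, n_repeats=2,
                                         boundary_jitter_mm=3.0,
                                         erosion_dilation_prob=0.0)
    entries = []
    for s in range(8):  # heterogeneous subjects: per-subject parenchyma shift
        label = "ild" if s % 2 else "control"
        # plain-gamma lung (no vessel/tail/benign-patch components), so the
        # comparison isolates pure boundary dependence
        cfg = synthetic.PhantomConfig(
            grid_shape=(48, 48, 48), spacing_mm=(1.0, 1.0, 1.0),
            noise_sigma_hu=5.0,
            healthy_mu_hu=-750 + rng.normal(0, 40),
            healthy_sigma_hu=80 * (1 + rng.normal(0, 0.1)),
            vessel_rate=0.0, hv_frac=0.0, control_patch_rate=0.0,
            seed=13)
        vol, mask = synthetic.generate_phantom(cfg, label, seed=1000 + s)
        # lung-equivalent surroundings: outside voxels drawn from the same
        # parenchymal distribution as the inside
        outside = ~mask.data
        inside_vals = vol.data[mask.data]
        vol.data[outside] = rng.choice(inside_vals, size=int(outside.sum()))
        for o, r in [(1, 1), (1, 2), (2, 1), (3, 1)]:
            m = synthetic.perturb_mask(mask, obs, seed=s * 10 + o * 3 + r)
            entries.append(dict(subject_id=f"s{s}", domain="microct", label=label,
                                observer=o, repeat=r, volume=vol, mask=m))
    table = features.extract_all(entries, ExtractionConfig(target_spacing_mm={"microct": 1.0}))
    table2 = table.copy()
    table2["domain"] = "hrct"
    retained, results, summary = stability.stability_filter(
        pd.concat([table, table2], ignore_index=True), 0.75)
    fam = summary.set_index("family")["unstable_fraction"]
    assert fam["GLDZM"] >= fam["HIST"]
    assert fam["GLDZM"] > 0
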