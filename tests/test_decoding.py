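"""Cross-condition ridge decoding and group statistics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Ridge

import bundleval as bv
from bundleval import decoding
from bundleval.decoding import (
    DecodingConfig,
    ridge_normal_equations,
    zscore_by_condition,
)


@pytest.fixture(scope="module")
def subject_data(catalog, clean_linear_wtp, small_schedule):
    def _make(scheme, seed=0, subject_id=1):
        return bv.simulate_voxel_patterns(
            small_schedule, clean_linear_wtp, scheme, seed=seed,
            subject_id=subject_id,
        )
    return _make


class TestZscore:
    def test_two_point_case(self):
        out = zscore_by_condition([2.0, 4.0], ["item", "item"])
        assert np.allclose(out, [-1.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=50)
        tt = np.array(["item"] * 25 + ["bundle"] * 25)
        once = zscore_by_condition(v, tt)
        twice = zscore_by_condition(once, tt)
        assert np.allclose(once, twice, atol=1e-12)

    def test_per_condition_moments(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 20, size=100)
        tt = np.array(["item", "bundle"] * 50)
        out = zscore_by_condition(v, tt)
        for t in ("item", "bundle"):
            assert out[tt == t].mean() == pytest.approx(0.0, abs=1e-12)
            assert out[tt == t].std() == pytest.approx(1.0, abs=1e-12)

    def test_constant_condition_rejected(self):
        with pytest.raises(ValueError):
            zscore_by_condition([3.0, 3.0, 1.0, 2.0],
                                ["item", "item", "bundle", "bundle"])


class TestRidgeOracle:
    def test_matches_normal_equations(self):
        rng = np.random.default_rng(2)
        for alpha in (1.0, 1e3):
            X = rng.normal(size=(40, 10))
            y = rng.normal(size=40)
            model = Ridge(alpha=alpha).fit(X, y)
            w, b = ridge_normal_equations(X, y, alpha)
            assert np.allclose(model.coef_, w, atol=1e-8)
            assert model.intercept_ == pytest.approx(b, abs=1e-8)


class TestCrossDecode:
    def test_noiseless_shared_code_all_splits(self, subject_data):
        data = subject_data(bv.CodingScheme(scheme="zscore", noise_sd=0.0,
                                            n_voxels=50))
        res = bv.cross_decode(data)
        assert len(res) == 4
        assert (res.accuracy > 0.99).all()
        assert (res.n_folds == 15).all()

    def test_condition_specific_code_dissociates(self, subject_data):
        scheme = bv.CodingScheme(scheme="zscore", noise_sd=0.3,
                                 separate_directions=True, n_voxels=50)
        res = subject_res = bv.cross_decode(subject_data(scheme, seed=5))
        acc = dict(zip(res.split, res.accuracy))
        assert acc["train_item_test_item"] > 0.8
        assert acc["train_bundle_test_bundle"] > 0.8
        assert abs(acc["train_item_test_bundle"]) < 0.15
        assert abs(acc["train_bundle_test_item"]) < 0.15

    def test_null_code_near_chance(self, subject_data):
        res = bv.cross_decode(
            subject_data(bv.CodingScheme(scheme="null", noise_sd=1.0,
                                         n_voxels=50), seed=6)
        )
        # ~2.6 sd null band for a mean of 15 per-fold correlations
        assert (res.accuracy.abs() < 0.15).all()
        assert abs(res.accuracy.mean()) < 0.05

    def test_shuffled_labels_centered_on_zero(self, subject_data):
        data = subject_data(bv.CodingScheme(scheme="zscore", noise_sd=0.5,
                                            n_voxels=40), seed=7)
        rng = np.random.default_rng(8)
        accs = []
        for _ in range(10):
            shuffled = bv.VoxelPatternDataset(
                data.patterns,
                data.meta.assign(value=rng.permutation(data.meta.value.values)),
                data.roi_label,
            )
            accs.append(bv.cross_decode(shuffled).accuracy.mean())
        assert abs(np.mean(accs)) < 0.05

    def test_accuracy_nonincreasing_in_noise(self, subject_data):
        within = []
        for noise in (0.0, 0.5, 2.0, 8.0):
            res = bv.cross_decode(
                subject_data(bv.CodingScheme(scheme="zscore", noise_sd=noise,
                                             n_voxels=40), seed=9)
            )
            within.append(
                res.set_index("split").accuracy["train_item_test_item"])
        assert all(a >= b - 0.02 for a, b in zip(within, within[1:]))

    def test_needs_two_runs(self, subject_data):
        data = subject_data(bv.CodingScheme(n_voxels=5))
        one_run = (data.meta.day == 1) & (data.meta.run == 1)
        sub = bv.VoxelPatternDataset(
            data.patterns[one_run.to_numpy()],
            data.meta[one_run].reset_index(drop=True))
        with pytest.raises(ValueError, match="runs"):
            bv.cross_decode(sub)


def _results_frame(acc_by_subject, roi="vmPFC", split="train_item_test_item"):
    rows = []
    for s, acc in enumerate(acc_by_subject, start=1):
        for sp in decoding.SPLITS:
            rows.append({"subject_id": s, "roi_label": roi, "split": sp,
                         "accuracy": acc if sp == split else acc / 2})
    return pd.DataFrame(rows)


class TestGroupStats:
    def test_all_positive_exact_signed_rank_p(self):
        # 14 subjects, all accuracies positive: two-sided exact p = 2 / 2^14
        rng = np.random.default_rng(3)
        res = _results_frame(rng.uniform(0.05, 0.4, size=14))
        table = decoding.group_decoding_tests(res)
        p = table.loc[(table.split == "train_item_test_item"), "p_raw"].iloc[0]
        assert p == pytest.approx(2 / 2**14, rel=1e-9)
        assert p == pytest.approx(0.000122, abs=1e-6)

    def test_all_zero_accuracies_not_significant(self):
        res = _results_frame(np.zeros(8))
        table = decoding.group_decoding_tests(res)
        assert (table.p_raw == 1.0).all()
        assert not table.significant.any()

    def test_single_roi_bh_equals_raw(self):
        rng = np.random.default_rng(4)
        res = _results_frame(rng.normal(0.1, 0.2, size=10))
        table = decoding.group_decoding_tests(res)
        assert np.allclose(table.p_fdr, table.p_raw)

    def test_condition_difference_rows_present(self):
        rng = np.random.default_rng(5)
        res = _results_frame(rng.uniform(0.1, 0.3, size=10))
        table = decoding.group_decoding_tests(res)
        assert (table.split.str.startswith("diff_")).sum() == 2

    def test_too_few_subjects_rejected(self):
        res = _results_frame([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="subjects"):
            decoding.group_decoding_tests(res)


class TestVoxelwiseRegression:
    def test_zscore_generated_data_prefers_zscore_variant(self, catalog):
        # additive bundle values give distinctly wider bundle distributions
        # (sd ratio ~1.4), so absolute and z-scored codes are separable
        spec = bv.GenerativeBundleSpec(
            family="linear", params={"beta0": 0.0, "beta1": 1.0, "beta2": 1.0},
            noise_sd=0.0, item_noise_sd=0.0, re_sd_intercept=0.0,
            re_sd_slope=0.0, censor_bids=False)
        wtp = bv.simulate_wtp_dataset(spec, catalog, n_subjects=3, seed=2)
        sched = bv.build_trial_schedule(catalog, wtp, seed=3)
        data = bv.simulate_voxel_patterns(
            sched, wtp, bv.CodingScheme(scheme="zscore", noise_sd=0.5,
                                        n_voxels=40), seed=10, subject_id=1)
        table = bv.voxelwise_value_regression(data)
        best = table.sort_values("loglik_sum", ascending=False).variant.iloc[0]
        assert best == "zscore_by_condition"

    def test_null_data_gains_nothing_over_nuisance(self, subject_data):
        data = subject_data(bv.CodingScheme(scheme="null", noise_sd=1.0,
                                            n_voxels=40), seed=11)
        table = bv.voxelwise_value_regression(data).set_index("variant")
        null_ll = table.loc["null", "loglik_sum"]
        for v in table.index.drop("null"):
            # one extra regressor per voxel: gains bounded by chance-level
            # chi-square improvement (~3.3 per voxel at the 99% quantile)
            assert table.loc[v, "loglik_sum"] - null_ll < 3.3 * 40

    def test_single_condition_affine_invariance(self, subject_data):
        data = subject_data(bv.CodingScheme(scheme="absolute", noise_sd=0.5,
                                            n_voxels=20), seed=12)
        items = (data.meta.trial_type == "item").to_numpy()
        sub = bv.VoxelPatternDataset(data.patterns[items],
                                     data.meta[items].reset_index(drop=True))
        table = bv.voxelwise_value_regression(
            sub, variants=("absolute", "zscore_by_condition")).set_index("variant")
        assert table.loc["absolute", "mean_r2"] == pytest.approx(
            table.loc["zscore_by_condition", "mean_r2"], abs=1e-10)
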