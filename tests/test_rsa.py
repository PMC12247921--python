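"""Representational similarity analysis: DSMs, model fits, attenuation."""

import numpy as np
import pandas as pd
import pytest

import bundleval as bv
from bundleval import rsa
from bundleval.rsa import DSM, full_normalization_values, random_trial_table


def _dataset(patterns, days):
    n = len(patterns)
    meta = pd.DataFrame({
        "day": days,
        "run": 1,
        "trial_type": ["item"] * n,
        "value": np.arange(n, dtype=float),
        "button_side": ["left"] * n,
        "subject_id": 1,
    })
    return bv.VoxelPatternDataset(np.asarray(patterns, float), meta)


class TestNeuralDSM:
    def test_identical_patterns_zero_distance(self):
        data = _dataset([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]], [1, 2, 3])
        dsm = bv.compute_neural_dsm(data)
        assert dsm.dissimilarities[0] == 0.0

    def test_three_four_five(self):
        data = _dataset([[0.0, 0.0], [3.0, 4.0], [9.0, 9.0]], [1, 2, 3])
        dsm = bv.compute_neural_dsm(data)
        assert dsm.dissimilarities[0] == pytest.approx(5.0)

    def test_valid_pair_count_three_days_ten_trials(self):
        rng = np.random.default_rng(0)
        data = _dataset(rng.normal(size=(30, 4)), np.repeat([1, 2, 3], 10))
        dsm = bv.compute_neural_dsm(data)
        assert dsm.dissimilarities.size == 435
        assert int(dsm.valid.sum()) == 435 - 3 * 45  # == 300

    def test_matches_brute_force_on_8_trials(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 5))
        data = _dataset(X, [1, 1, 2, 2, 3, 3, 4, 4])
        dsm = bv.compute_neural_dsm(data)
        for k, (i, j) in enumerate(zip(dsm.pair_i, dsm.pair_j)):
            brute = np.sqrt(((X[i] - X[j]) ** 2).sum())
            assert dsm.dissimilarities[k] == pytest.approx(brute, abs=1e-10)
            assert dsm.valid[k] == (data.meta.day[i] != data.meta.day[j])

    def test_single_day_rejected(self):
        data = _dataset(np.eye(4), [1, 1, 1, 1])
        with pytest.raises(ValueError):
            bv.compute_neural_dsm(data)


class TestModelDSM:
    def test_absolute_difference(self):
        dsm = bv.build_model_dsm([3.0, 5.0], ["item", "item"], family="absolute")
        assert dsm.dissimilarities[0] == pytest.approx(2.0)

    def test_subtractive_cross_condition_zero(self):
        values = [2.0, 4.0, 6.0, 8.0]
        tts = ["item", "item", "bundle", "bundle"]
        dsm = bv.build_model_dsm(values, tts, family="subtractive")
        # pair (low item, low bundle): |(2-3) - (6-7)| = 0
        k = [i for i, (a, b) in enumerate(zip(dsm.pair_i, dsm.pair_j))
             if (a, b) == (0, 2)][0]
        assert dsm.dissimilarities[k] == pytest.approx(0.0, abs=1e-12)

    def test_zscore_affine_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(0, 20, size=30)
        tts = np.array(["item", "bundle"] * 15)
        base = bv.build_model_dsm(values, tts, family="zscore")
        for _ in range(5):
            a, b = rng.uniform(0.5, 3.0), rng.uniform(-5, 5)
            rescaled = np.where(tts == "item", a * values + b, values)
            dsm = bv.build_model_dsm(rescaled, tts, family="zscore")
            assert np.allclose(dsm.dissimilarities, base.dissimilarities,
                               atol=1e-10)

    def test_constant_condition_under_zscore_rejected(self):
        with pytest.raises(ValueError):
            bv.build_model_dsm([1.0, 1.0, 2.0, 3.0],
                               ["item", "item", "bundle", "bundle"],
                               family="zscore")


class TestFullNormalizationValues:
    def _trials(self, value, trial_type):
        return pd.DataFrame({"value": [value], "trial_type": [trial_type]})

    def test_reduces_to_absolute(self):
        trials = self._trials(7.0, "item")
        out = full_normalization_values(
            trials, {"b1": 2.0, "b2": 0.0, "sigma": 1.0})
        assert out[0] == pytest.approx(14.0)

    def test_item_substitution(self):
        out = full_normalization_values(
            self._trials(4.0, "item"),
            {"b1": 1.0, "b2": -0.5, "sigma": 1.0, "w_v": 1.0})
        assert out[0] == pytest.approx(0.8)

    def test_bundle_attenuation_by_half(self):
        out = full_normalization_values(
            self._trials(4.0, "bundle"),
            {"b1": 1.0, "b2": -0.5, "sigma": 1.0, "w_v": 1.0})
        assert out[0] == pytest.approx(0.4)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            full_normalization_values(
                self._trials(4.0, "item"),
                {"b1": 1.0, "sigma": 1.0, "w_v": -1.0})


TRUE_PARAMS = {"a0": 1.0, "a1": 0.2, "a2": 0.3, "b1": 0.8, "b2": -0.4,
               "sigma": 1.0, "w_v": 0.1, "w_avg": 0.0, "w_1": 0.0}


class TestRSAFitting:
    def test_zero_noise_parameter_recovery(self):
        trials = random_trial_table(30, 3, seed=1)
        neural = rsa.simulate_neural_dsm(trials, TRUE_PARAMS, 0.0, seed=2)
        fit = bv.fit_rsa_model(neural, trials, "full_normalization", seed=3)
        for k in ("a0", "a1", "a2", "b1", "b2", "w_v"):
            assert fit.params[k] == pytest.approx(TRUE_PARAMS[k], abs=1e-3)
        assert fit.bundle_coefficient == pytest.approx(0.4, abs=1e-3)

    def test_null_data_value_coefficients_near_zero(self):
        null_params = {"a0": 1.0, "a1": 0.2, "a2": 0.3}
        b1s = []
        for seed in range(20):
            trials = random_trial_table(20, 3, seed=seed)
            neural = rsa.simulate_neural_dsm(trials, null_params, 0.3,
                                             seed=100 + seed, family="null")
            fit = bv.fit_rsa_model(neural, trials, "absolute", seed=seed)
            b1s.append(fit.params["b1"])
        b1s = np.array(b1s)
        assert abs(b1s.mean()) < 3 * b1s.std(ddof=1) / np.sqrt(len(b1s)) + 0.02

    def test_value_term_on_null_data_raises_bic(self):
        trials = random_trial_table(25, 3, seed=4)
        neural = rsa.simulate_neural_dsm(trials, {"a0": 1.0, "a1": 0.2,
                                                  "a2": 0.3}, 0.3, seed=5,
                                         family="null")
        null_fit = bv.fit_rsa_model(neural, trials, "null")
        abs_fit = bv.fit_rsa_model(neural, trials, "absolute")
        assert abs_fit.bic > null_fit.bic

    def test_mismatched_trials_rejected(self):
        trials = random_trial_table(10, 2, seed=6)
        neural = rsa.simulate_neural_dsm(trials, TRUE_PARAMS, 0.1, seed=7)
        with pytest.raises(ValueError):
            bv.fit_rsa_model(neural, trials.iloc[:-1], "absolute")


class TestModelComparison:
    GEN = {
        "full_normalization": TRUE_PARAMS,
        "absolute": {"a0": 1.0, "a1": 0.2, "a2": 0.3, "b1": 0.3},
        "zscore": {"a0": 1.0, "a1": 0.2, "a2": 0.3, "b1": 0.8},
        "null": {"a0": 1.0, "a1": 0.2, "a2": 0.3},
    }

    @pytest.mark.parametrize("gen_family", list(GEN))
    def test_generating_family_wins(self, gen_family):
        wins = 0
        for seed in range(5):
            trials = random_trial_table(30, 3, seed=seed)
            neural = rsa.simulate_neural_dsm(
                trials, self.GEN[gen_family], noise_sd=0.25,
                seed=50 + seed, family=gen_family)
            table = bv.compare_rsa_models(neural, trials, seed=seed)
            table = table[table.converged]
            if gen_family == "null":
                wins += (table.delta_bic >= 0).all()
            else:
                wins += table.family.iloc[0] == gen_family
        assert wins >= 4

    def test_null_must_be_included(self):
        trials = random_trial_table(10, 2, seed=8)
        neural = rsa.simulate_neural_dsm(trials, TRUE_PARAMS, 0.1, seed=9)
        with pytest.raises(ValueError):
            bv.compare_rsa_models(neural, trials, families=("absolute",))


class TestAttenuation:
    def _cohort_fits(self, b2, n_subjects=14, noise=0.25, seed0=0):
        fits = []
        for s in range(n_subjects):
            params = dict(TRUE_PARAMS, b2=b2)
            trials = random_trial_table(25, 3, seed=seed0 + s)
            neural = rsa.simulate_neural_dsm(trials, params, noise,
                                             seed=seed0 + 500 + s)
            fits.append(bv.fit_rsa_model(neural, trials, "full_normalization",
                                         seed=seed0 + s))
        return fits

    def test_attenuated_cohort_detected(self):
        res = bv.test_coefficient_attenuation(self._cohort_fits(b2=-0.4))
        assert res["mean_difference"] < 0
        assert res["p"] < 0.05

    def test_degenerate_identical_fits(self):
        fits = self._cohort_fits(b2=0.0, n_subjects=1) * 6
        res = bv.test_coefficient_attenuation(
            pd.DataFrame({"b_item": [0.5] * 6, "b_bundle": [0.5] * 6}))
        assert res["p"] == 1.0
        assert res["mean_difference"] == 0.0

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            bv.test_coefficient_attenuation(
                pd.DataFrame({"b_item": [0.5] * 3, "b_bundle": [0.4] * 3}))
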