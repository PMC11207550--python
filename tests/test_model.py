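"""Calibration model tests: centring, the prediction equation, AIC selection, strategies."""

import numpy as np
import pytest

import nirtherm as nt
from nirtherm.exceptions import ConfigError, DataFormatError
from nirtherm.model import (
    PLSModel,
    aic_press,
    center_by_phantom,
    fit_calibration,
    predict,
    select_latent_variables,
)

from conftest import true_spectra


def toy_model(b, mean_spec=None, mean_temp=22.0):
    b = np.asarray(b, float)
    return PLSModel(
        b=b,
        n_latent=1,
        mean_spectrum_cal=np.zeros_like(b) if mean_spec is None else np.asarray(mean_spec, float),
        mean_temperature_cal=mean_temp,
        per_phantom_means={},
        centering_mode="pooled",
        training_ids=(1,),
    )


class TestCentering:
    def test_single_phantom_modes_agree(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 27))
        y = rng.uniform(20, 24, 8)
        pids = np.ones(8, int)
        xc1, yc1, *_ = center_by_phantom(x, y, pids, "per_phantom")
        xc2, yc2, *_ = center_by_phantom(x, y, pids, "pooled")
        np.testing.assert_allclose(xc1, xc2, atol=1e-12)
        np.testing.assert_allclose(yc1, yc2, atol=1e-12)

    def test_offset_between_phantoms_removed(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(6, 27))
        x = np.vstack([base, base + 0.5])
        y = np.tile(np.linspace(20, 24, 6), 2)
        pids = np.repeat([1, 2], 6)
        xc, _, _, _, _ = center_by_phantom(x, y, pids, "per_phantom")
        np.testing.assert_allclose(xc[:6], xc[6:], atol=1e-12)

    def test_per_phantom_blocks_have_zero_mean(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 27))
        y = rng.uniform(20, 24, 12)
        pids = np.repeat([1, 2, 3], 4)
        xc, _, _, _, _ = center_by_phantom(x, y, pids, "per_phantom")
        for pid in (1, 2, 3):
            np.testing.assert_allclose(xc[pids == pid].mean(axis=0), 0.0, atol=1e-12)

    def test_temperatures_centred_by_pooled_mean(self):
        y = np.array([20.0, 22.0, 22.0, 24.0])
        _, yc, _, _, pooled_temp = center_by_phantom(
            np.zeros((4, 27)) + np.arange(4)[:, None], y, np.repeat([1, 2], 2), "per_phantom"
        )
        assert pooled_temp == pytest.approx(22.0)
        np.testing.assert_allclose(yc, y - 22.0)


class TestPredictEquation:
    def test_mean_spectrum_returns_mean_temperature(self):
        m = toy_model(np.ones(27), mean_spec=np.full(27, 0.4), mean_temp=21.7)
        assert predict(m, np.full(27, 0.4)) == pytest.approx(21.7)

    def test_zero_vector_returns_mean_everywhere(self):
        m = toy_model(np.zeros(27), mean_temp=22.3)
        rng = np.random.default_rng(0)
        out = predict(m, rng.normal(size=(5, 27)))
        np.testing.assert_allclose(out, 22.3)

    def test_single_channel_linearity(self):
        b = np.zeros(27)
        b[11] = 4.0
        m = toy_model(b)
        a = np.zeros(27)
        a2 = a.copy()
        a2[11] += 0.05
        assert predict(m, a2) - predict(m, a) == pytest.approx(4.0 * 0.05)

    def test_wrong_length_rejected(self):
        with pytest.raises(DataFormatError):
            predict(toy_model(np.zeros(27)), np.zeros(26))

    def test_prediction_equation_consistency_for_fitted_models(self, uniform_noiseless_df):
        df = uniform_noiseless_df
        for mode in ("pooled", "per_phantom"):
            model = fit_calibration(
                df[[f"a{k:02d}" for k in range(1, 28)]].to_numpy(),
                df["assigned_temp_C"].to_numpy(),
                df["phantom_id"].to_numpy(),
                h=1,
                mode=mode,
            )
            assert predict(model, model.mean_spectrum_cal) == pytest.approx(
                model.mean_temperature_cal, abs=1e-10
            )


class TestLatentVariableSelection:
    @staticmethod
    def _grouped(n_groups=4, per_group=15, seed=0):
        rng = np.random.default_rng(seed)
        pids = np.repeat(np.arange(1, n_groups + 1), per_group)
        t = np.tile(np.linspace(20, 24, per_group), n_groups)
        return rng, pids, t

    def test_noiseless_single_factor_selects_h1(self):
        rng, pids, t = self._grouped()
        direction = rng.normal(size=27)
        x = np.outer(t - 22.0, direction)
        curve = select_latent_variables(x, t, pids, h_max=5)
        assert curve.selected_h == 1

    def test_two_factor_data_selects_h2_matching_exhaustive_aic(self):
        rng = np.random.default_rng(7)
        pids = np.repeat(np.arange(1, 5), 20)
        n = pids.size
        f1 = np.tile(np.linspace(-1, 1, 20), 4)
        f2 = rng.normal(size=n)
        d1, d2 = rng.normal(size=27), rng.normal(size=27)
        x = np.outer(f1, d1) + np.outer(f2, d2) + rng.normal(0, 1e-3, (n, 27))
        t = 22.0 + 1.5 * f1 + 0.8 * f2 + rng.normal(0, 0.02, n)
        curve = select_latent_variables(x, t, pids, h_max=6)
        assert curve.selected_h == 2
        # independent exhaustive minimisation over the returned PRESS curve
        brute = [
            n * np.log(max(p / n, 1e-12)) + 2 * (h + 1)
            for h, p in zip(curve.h_values, curve.press)
        ]
        assert curve.selected_h == int(curve.h_values[int(np.argmin(brute))])

    def test_aic_arithmetic(self):
        assert aic_press(100, 4.0, 3) == pytest.approx(100 * np.log(0.04) + 8, abs=1e-10)
        assert aic_press(100, 4.0, 3) == pytest.approx(-313.89, abs=0.01)

    def test_selected_h_minimises_aic(self, default_dataset):
        df, _ = default_dataset
        curve = select_latent_variables(
            df[[f"a{k:02d}" for k in range(1, 28)]].to_numpy(),
            df["assigned_temp_C"].to_numpy(),
            df["phantom_id"].to_numpy(),
            h_max=8,
        )
        assert curve.aic[curve.selected_h - 1] == pytest.approx(curve.aic.min())
        assert np.all(curve.press >= 0)

    def test_needs_three_phantoms(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ConfigError):
            select_latent_variables(
                rng.normal(size=(10, 27)), rng.uniform(20, 24, 10), np.repeat([1, 2], 5)
            )

    def test_oversized_h_max_truncates_with_warning(self):
        rng, pids, t = self._grouped(n_groups=3, per_group=4)
        x = np.outer(t - 22, rng.normal(size=27)) + rng.normal(0, 1e-4, (12, 27))
        with pytest.warns(UserWarning, match="truncat"):
            curve = select_latent_variables(x, t, pids, h_max=10)
        assert curve.h_values.max() <= 7


class TestSplitStrategy:
    def test_phantom3_calibration_steps(self):
        # the first three steps of the phantom-3 profile are 20, 23, 21 degC
        assert nt.study_phantoms()[2].step_profile_C[:3] == (20.0, 23.0, 21.0)
        assert nt.study_phantoms()[2].step_profile_C[3:] == (24.0, 22.0)

    def test_partition_counts(self, uniform_noiseless_df):
        res = nt.run_split_strategy(uniform_noiseless_df)
        n_cal = len(res.plan.calibration_index)
        n_pred = len(res.plan.prediction_index)
        assert n_cal + n_pred == len(uniform_noiseless_df)
        cal_steps = set(uniform_noiseless_df.iloc[res.plan.calibration_index]["step_index"])
        assert cal_steps == {0, 1, 2}

    def test_noiseless_prediction_r2_is_one(self, uniform_noiseless_df):
        res = nt.run_split_strategy(uniform_noiseless_df)
        assert res.prediction_metrics.r_squared == pytest.approx(1.0, abs=1e-6)
        assert res.prediction_metrics.sep <= 1e-5

    def test_missing_steps_error_names_phantom(self, uniform_noiseless_df):
        df = uniform_noiseless_df
        broken = df[~((df["phantom_id"] == 3) & (df["step_index"] > 0))]
        with pytest.raises(ConfigError, match="3"):
            nt.run_split_strategy(broken)

    def test_summary_mentions_key_metrics(self, uniform_noiseless_df):
        text = nt.run_split_strategy(uniform_noiseless_df).summary()
        for token in ("SECV", "SEP", "RSEP", "latent"):
            assert token in text


class TestLOPOStrategy:
    def test_one_row_per_phantom_with_table_columns(self, uniform_noiseless_df):
        res = nt.run_lopo_strategy(uniform_noiseless_df)
        assert list(res.table["held_out_phantom"]) == list(range(1, 8))
        assert list(res.table.columns) == [
            "held_out_phantom",
            "latent_variables",
            "secv_C",
            "sep_C",
            "rsep_pct",
            "r2_calibration",
            "r2_prediction",
            "bias_C",
        ]

    def test_noiseless_biases_vanish(self, uniform_noiseless_df):
        res = nt.run_lopo_strategy(uniform_noiseless_df)
        assert np.abs(res.table["bias_C"].to_numpy()).max() <= 1e-6

    def test_offset_on_held_out_spectra_shifts_only_its_bias(self, uniform_noiseless_df):
        res = nt.run_lopo_strategy(uniform_noiseless_df)
        holdout = res.holdouts[2]
        spectra = uniform_noiseless_df[
            uniform_noiseless_df["phantom_id"] == holdout.held_out
        ][[f"a{k:02d}" for k in range(1, 28)]].to_numpy()
        shifted = holdout.results.metrics(spectra + 0.02, holdout.reference)
        expected_shift = 0.02 * holdout.results.params.sum()
        assert shifted.bias - holdout.metrics.bias == pytest.approx(expected_shift, abs=1e-8)
        # the other phantoms' fitted models never see the perturbed spectra, so
        # their predictions are bit-identical to the unperturbed run
        res2 = nt.run_lopo_strategy(uniform_noiseless_df)
        for a, b in zip(res.holdouts, res2.holdouts):
            np.testing.assert_array_equal(a.predicted, b.predicted)

    def test_fewer_than_three_phantoms_rejected(self, uniform_noiseless_df):
        df = uniform_noiseless_df[uniform_noiseless_df["phantom_id"] <= 2]
        with pytest.raises(ConfigError):
            nt.run_lopo_strategy(df)

    def test_sep_close_to_true_temperature_floor(self, default_dataset):
        # predictions scored against assigned temperatures cannot be much worse
        # than against the generator's true temperatures (assignment error is
        # far below the prediction error)
        df, ledger = default_dataset
        res = nt.run_lopo_strategy(df)
        merged = df.merge(
            ledger[["phantom_id", "step_index", "recording_index", "true_temperature_C"]],
            on=["phantom_id", "step_index", "recording_index"],
        )
        for holdout in res.holdouts:
            rows = merged[merged["phantom_id"] == holdout.held_out]
            true_t = rows["true_temperature_C"].to_numpy()
            sep_true = nt.sep(true_t, holdout.predicted)
            assert holdout.metrics.sep <= 3 * sep_true


class TestResultsObject:
    def test_fit_with_fixed_h_has_no_cv_curve(self, default_dataset):
        df, _ = default_dataset
        mod = nt.TemperatureCalibration.from_dataframe(df)
        res = mod.fit(n_latent=2)
        assert res.n_latent == 2
        assert res.cv_curve is None
        with pytest.raises(ConfigError):
            res.cv_metrics()

    def test_summary_lists_cv_curve(self, uniform_noiseless_df):
        res = nt.TemperatureCalibration.from_dataframe(uniform_noiseless_df).fit()
        text = res.summary()
        assert "latent variables" in text
        assert "AIC" in text
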