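"""Sensitivity maps: gradient correctness, SmoothGrad identities, and the
noise-calibration procedure."""

import warnings

import numpy as np
import pandas as pd
import pytest

from xbrainage import nn
from xbrainage.phantom import AtlasSpec, build_atlas
from xbrainage.saliency import (SaliencyConfig, calibrate_noise,
                                default_noise_grid, smoothgrad,
                                vanilla_gradient)


def linear_model(weights):
    """f(x) = sum_v w_v x_v as a Sequential; gradient is w everywhere."""
    w = np.asarray(weights, dtype=float)
    rng = np.random.default_rng(0)
    dense = nn.Dense(w.size, 1, rng)
    dense.W.value = w.reshape(-1, 1).copy()
    dense.b.value[...] = 2.0
    return nn.Sequential([nn.Flatten(), dense])


class TestVanillaGradient:
    def test_linear_model_gradient_equals_weights_exactly(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=(1, 6, 6, 6))
        model = linear_model(w)
        g = vanilla_gradient(model, rng.normal(size=(1, 6, 6, 6)))
        np.testing.assert_array_equal(g, w)

    def test_constant_model_gradient_is_zero(self):
        model = linear_model(np.zeros((1, 4, 4, 4)))
        g = vanilla_gradient(model, np.ones((1, 4, 4, 4)))
        np.testing.assert_array_equal(g, 0.0)

    def test_finite_difference_oracle_on_trained_model(self, trained_small_model):
        model = trained_small_model["model"]
        vol = trained_small_model["volumes"][3]
        g = vanilla_gradient(model, vol)
        rng = np.random.default_rng(8)
        h = 1e-4
        for idx in rng.choice(vol.size, size=20, replace=False):
            vp, vm = vol.copy(), vol.copy()
            vp.flat[idx] += h
            vm.flat[idx] -= h
            num = (model.forward(vp[None])[0, 0]
                   - model.forward(vm[None])[0, 0]) / (2 * h)
            ana = g.flat[idx]
            assert ana == pytest.approx(num, rel=1e-3, abs=1e-8)

    def test_non_scalar_output_rejected(self):
        rng = np.random.default_rng(0)
        model = nn.Sequential([nn.Flatten(), nn.Dense(8, 2, rng)])
        with pytest.raises(ValueError, match="scalar"):
            vanilla_gradient(model, np.zeros((1, 2, 2, 2)))


class TestSmoothGrad:
    def test_degenerate_config_reduces_to_vanilla(self, trained_small_model):
        model = trained_small_model["model"]
        vol = trained_small_model["volumes"][0]
        sg = smoothgrad(model, vol,
                        SaliencyConfig(noise_level=0.0, n_samples=1, seed=0))
        vg = vanilla_gradient(model, vol)
        assert np.max(np.abs(sg - vg)) < 1e-6

    def test_linear_model_map_is_noise_invariant(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=(1, 5, 5, 5))
        model = linear_model(w)
        vol = rng.normal(size=(1, 5, 5, 5))
        for level in (0.0, 0.1, 0.5):
            sg = smoothgrad(model, vol,
                            SaliencyConfig(noise_level=level, n_samples=5,
                                           seed=3))
            assert np.max(np.abs(sg - w)) < 1e-6

    def test_map_equals_mean_of_individual_sample_maps(self, trained_small_model):
        model = trained_small_model["model"]
        vol = trained_small_model["volumes"][1]
        cfg = SaliencyConfig(noise_level=0.1, n_samples=4, seed=5)
        sg = smoothgrad(model, vol, cfg)
        # regenerate the identical noise batch and extract each sample's map
        sigma = cfg.noise_level * (vol.max() - vol.min())
        rng = np.random.default_rng([cfg.seed, 0x5A71])
        batch = np.repeat(vol[None], 4, axis=0)
        batch += rng.normal(0.0, sigma, batch.shape)
        singles = [vanilla_gradient(model, batch[i]) for i in range(4)]
        np.testing.assert_allclose(sg, np.mean(singles, axis=0), atol=1e-12)

    def test_absolute_mode_rectifies_before_averaging(self):
        rng = np.random.default_rng(4)
        w = rng.normal(size=(1, 4, 4, 4))
        model = linear_model(w)
        vol = rng.normal(size=(1, 4, 4, 4))
        sg = smoothgrad(model, vol,
                        SaliencyConfig(noise_level=0.2, n_samples=3, seed=1,
                                       reduce="absolute"))
        np.testing.assert_allclose(sg, np.abs(w), atol=1e-12)

    def test_sample_count_stabilizes_the_map(self, trained_small_model):
        model = trained_small_model["model"]
        vol = trained_small_model["volumes"][2]
        variances = []
        for n in (1, 8, 64):
            means = [smoothgrad(model, vol,
                                SaliencyConfig(noise_level=0.2, n_samples=n,
                                               seed=s)).mean()
                     for s in range(6)]
            variances.append(np.var(means))
        assert variances[0] > variances[1] > variances[2]

    def test_constant_volume_warns_but_proceeds(self, trained_small_model):
        model = trained_small_model["model"]
        vol = np.zeros((1, 16, 16, 16))
        with pytest.warns(RuntimeWarning, match="sigma"):
            sg = smoothgrad(model, vol,
                            SaliencyConfig(noise_level=0.3, n_samples=2, seed=0))
        assert np.all(np.isfinite(sg))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SaliencyConfig(noise_level=0.6)
        with pytest.raises(ValueError):
            SaliencyConfig(n_samples=0)
        with pytest.raises(ValueError):
            SaliencyConfig(reduce="rms")


class TestCalibration:
    def test_default_grid_is_0_to_50_percent_in_2_percent_steps(self):
        grid = default_noise_grid()
        assert len(grid) == 26
        assert grid[0] == 0.0
        assert grid[-1] == 0.5
        np.testing.assert_allclose(np.diff(grid), 0.02, atol=1e-12)

    def test_report_covers_grid_and_chosen_level_maximizes(
            self, trained_small_model):
        model = trained_small_model["model"]
        vols = list(trained_small_model["volumes"][:6])
        ages = trained_small_model["ages"][:6]
        atlas = trained_small_model["atlas"]
        rep = calibrate_noise(model, vols, ages, atlas,
                              grid=[0.0, 0.1, 0.2],
                              cfg=SaliencyConfig(n_samples=2, seed=9))
        assert list(rep.scores.index) == [0.0, 0.1, 0.2]
        assert rep.scores[rep.chosen_level] == rep.scores.max()

    def test_tie_breaks_to_smallest_level_for_linear_model(self):
        # a linear model's maps are identical at every level -> exact ties
        rng = np.random.default_rng(3)
        w = rng.normal(size=(1, 16, 16, 16))
        model = linear_model(w)
        atlas, _ = build_atlas(AtlasSpec((16, 16, 16), 4, seed=2))
        vols = [rng.normal(size=(1, 16, 16, 16)) for _ in range(4)]
        ages = np.array([25.0, 40.0, 55.0, 70.0])
        rep = calibrate_noise(model, vols, ages, atlas, grid=[0.0, 0.1, 0.2],
                              cfg=SaliencyConfig(n_samples=2, seed=1))
        assert rep.chosen_level == 0.0

    def test_scores_reproducible_from_per_roi_table(self, trained_small_model):
        model = trained_small_model["model"]
        vols = list(trained_small_model["volumes"][:5])
        ages = trained_small_model["ages"][:5]
        rep = calibrate_noise(model, vols, ages, trained_small_model["atlas"],
                              grid=[0.0, 0.15], cfg=SaliencyConfig(n_samples=2,
                                                                   seed=4))
        recomputed = rep.table.groupby("level")["r"].apply(
            lambda r: np.mean(np.abs(r)))
        for level, score in rep.scores.items():
            assert abs(recomputed.loc[level] - score) < 1e-10

    def test_shape_mismatch_and_degenerate_inputs_rejected(
            self, trained_small_model):
        model = trained_small_model["model"]
        atlas = trained_small_model["atlas"]
        good = [np.zeros((1, 16, 16, 16))] * 3
        with pytest.raises(ValueError, match="grid"):
            calibrate_noise(model, [np.zeros((1, 8, 8, 8))] * 3,
                            np.array([20.0, 40.0, 60.0]), atlas)
        with pytest.raises(ValueError, match="variance"):
            calibrate_noise(model, good, np.array([50.0, 50.0, 50.0]), atlas)
        with pytest.raises(ValueError, match=">= 3"):
            calibrate_noise(model, good[:2], np.array([20.0, 40.0]), atlas)


def test_maps_are_independent_of_bias_correction(trained_small_model):
    """The gradient path uses raw model output; correcting predictions
    downstream must not change the sensitivity maps."""
    from xbrainage.brainage import (apply_bias_correction,
                                    build_prediction_table,
                                    fit_bias_correction)
    from xbrainage.models import predict_age

    model = trained_small_model["model"]
    vols = trained_small_model["volumes"][:10]
    cohort = trained_small_model["cohort"].iloc[:10]
    cfg = SaliencyConfig(noise_level=0.1, n_samples=3, seed=6)
    before = smoothgrad(model, vols[0], cfg)
    pred = predict_age(model, vols)
    table = build_prediction_table(cohort, pred)
    bias = fit_bias_correction(table["gap_raw"], table["age"])
    apply_bias_correction(table, bias)
    after = smoothgrad(model, vols[0], cfg)
    np.testing.assert_array_equal(before, after)
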