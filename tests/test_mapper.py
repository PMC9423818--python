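"""Latent inversion: loss closed forms, fixed point, frozen weights,
residual binarization and sequence-level calls."""

import numpy as np
import pytest

from hemoflow.mapper import (
    MapperConfig,
    binarize_residual,
    discrimination_loss,
    map_to_latent,
    residual_loss,
    score_frame_sequence,
    total_loss,
)
from hemoflow.types import ContractError

from conftest import otsu_exhaustive


class TestResidualLoss:
    def test_identical_images_score_zero(self):
        x = np.random.default_rng(0).uniform(-1, 1, (64, 64))
        assert residual_loss(x, x) == 0.0

    def test_maximally_opposed_images_score_one(self):
        assert residual_loss(np.ones((64, 64)), -np.ones((64, 64))) == 1.0

    def test_matches_brute_force_pixel_loop(self):
        rng = np.random.default_rng(7)
        x, gz = rng.uniform(-1, 1, (8, 8)), rng.uniform(-1, 1, (8, 8))
        expected = 0.0
        for i in range(8):
            for j in range(8):
                expected += abs(x[i, j] - gz[i, j])
        assert residual_loss(x, gz, normalized=False) == pytest.approx(expected)
        assert residual_loss(x, gz) == pytest.approx(expected / (64 * 2))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            residual_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestDiscriminationLoss:
    """Closed-form sigmoid cross-entropy against target 'real' = 1."""

    def test_zero_logit_gives_ln2(self, tiny_model):
        self._force_logit(tiny_model, 0.0)
        val = discrimination_loss(np.zeros((1, 1, 64, 64)), tiny_model)
        assert val == pytest.approx(np.log(2), abs=1e-6)

    def test_negative_logit_closed_form(self, tiny_model):
        self._force_logit(tiny_model, -2.0)
        val = discrimination_loss(np.zeros((1, 1, 64, 64)), tiny_model)
        assert val == pytest.approx(np.log(1 + np.e**2), abs=1e-5)

    def test_large_positive_logit_vanishes(self, tiny_model):
        self._force_logit(tiny_model, 30.0)
        val = discrimination_loss(np.zeros((1, 1, 64, 64)), tiny_model)
        assert val == pytest.approx(0.0, abs=1e-9)

    @staticmethod
    def _force_logit(model, value):
        final = model.discriminator.layers[-1]
        final.params["w"] = np.zeros_like(final.params["w"])
        final.params["b"] = np.full_like(final.params["b"], value)

    @pytest.fixture(autouse=True)
    def _restore(self, tiny_model):
        final = tiny_model.discriminator.layers[-1]
        saved = {k: v.copy() for k, v in final.params.items()}
        yield
        final.params.update(saved)


class TestTotalLoss:
    @pytest.mark.parametrize(
        "lr, ld, gamma, want",
        [
            (0.37, 5.0, 0.0, 0.37),
            (0.37, 5.0, 1.0, 5.0),
            (0.2, 0.6, 0.1, 0.24),
        ],
    )
    def test_weighted_combination(self, lr, ld, gamma, want):
        assert total_loss(lr, ld, gamma) == pytest.approx(want)

    def test_gamma_out_of_range_rejected(self):
        with pytest.raises(ContractError):
            total_loss(0.1, 0.1, 1.5)


class TestMapToLatent:
    def test_fixed_point_of_generator_image(self, tiny_model):
        """Querying with x = G(z*) starting at z* leaves nothing to explain:
        residual ~ 0 and the score reduces to the discrimination term."""
        rng = np.random.default_rng(21)
        z_star = tiny_model.sample_latent(1, rng)
        x = tiny_model.generate(z_star)[0, 0]
        cfg = MapperConfig(n_steps=1, gamma=0.1, seed=0)
        res = map_to_latent(x, tiny_model, cfg, z_init=z_star)
        assert res.residual.max() < 1e-3
        assert res.score <= cfg.gamma * res.discrimination_loss + 1e-3

    def test_gamma_zero_score_is_pure_residual_loss(self, tiny_model):
        rng = np.random.default_rng(22)
        x = rng.uniform(-0.5, 0.5, (64, 64))
        cfg = MapperConfig(n_steps=5, gamma=0.0, seed=1)
        res = map_to_latent(x, tiny_model, cfg)
        assert res.score == pytest.approx(min(res.residual_loss, 1.0))

    def test_weights_frozen_bit_identical(self, tiny_model):
        g_before = {k: v.copy() for k, v in tiny_model.generator.state_dict().items()}
        d_before = {
            k: v.copy() for k, v in tiny_model.discriminator.state_dict().items()
        }
        x = np.random.default_rng(3).uniform(-1, 1, (64, 64))
        map_to_latent(x, tiny_model, MapperConfig(n_steps=10, seed=2))
        for k, v in tiny_model.generator.state_dict().items():
            np.testing.assert_array_equal(v, g_before[k])
        for k, v in tiny_model.discriminator.state_dict().items():
            np.testing.assert_array_equal(v, d_before[k])

    def test_score_bounds_and_trajectory_length(self, tiny_model):
        rng = np.random.default_rng(4)
        for gamma in (0.0, 0.1, 1.0):
            x = rng.uniform(-1, 1, (64, 64))
            cfg = MapperConfig(n_steps=7, gamma=gamma, seed=5)
            res = map_to_latent(x, tiny_model, cfg)
            assert 0.0 <= res.score <= 1.0
            assert len(res.loss_trajectory) == 7
            assert np.all(res.residual >= 0)

    def test_more_steps_reach_lower_loss_in_median(self, tiny_model, small_dataset):
        """Descent makes progress: median final loss at phi=200 is no worse
        than at phi=20 on the same queries (not asserted per query)."""
        images, _, _ = small_dataset
        queries = [img.pixels for img in images[:6]]
        finals = {}
        for steps in (20, 200):
            cfg = MapperConfig(n_steps=steps, gamma=0.1, seed=6)
            finals[steps] = [
                map_to_latent(q, tiny_model, cfg).loss_trajectory[-1]
                for q in queries
            ]
        assert np.median(finals[200]) <= np.median(finals[20])

    def test_restarts_keep_best_final_loss(self, tiny_model):
        x = np.random.default_rng(8).uniform(-1, 1, (64, 64))
        single = map_to_latent(x, tiny_model, MapperConfig(n_steps=10, seed=7))
        multi = map_to_latent(
            x, tiny_model, MapperConfig(n_steps=10, seed=7, n_restarts=3)
        )
        assert multi.loss_trajectory[-1] <= single.loss_trajectory[-1] + 1e-12

    def test_determinism(self, tiny_model):
        x = np.random.default_rng(9).uniform(-1, 1, (64, 64))
        cfg = MapperConfig(n_steps=15, seed=10)
        r1 = map_to_latent(x, tiny_model, cfg)
        r2 = map_to_latent(x, tiny_model, cfg)
        assert r1.score == r2.score
        np.testing.assert_array_equal(r1.final_z, r2.final_z)

    def test_invalid_config_rejected(self):
        with pytest.raises(ContractError):
            MapperConfig(gamma=1.5)
        with pytest.raises(ContractError):
            MapperConfig(n_steps=0)


class TestBinarizeResidual:
    def test_all_zero_residuals_give_empty_maps(self):
        maps, thr = binarize_residual([np.zeros((8, 8)), np.zeros((8, 8))])
        assert thr == 0.0
        assert all(not m.any() for m in maps)

    def test_two_level_residual_splits_at_otsu_threshold(self):
        res = np.zeros((10, 10))
        res[:, 5:] = 0.8
        maps, thr = binarize_residual([res])
        assert 0.0 < thr < 0.8
        np.testing.assert_array_equal(maps[0], res == 0.8)
        assert thr == pytest.approx(otsu_exhaustive(res.ravel()), abs=1e-12)

    def test_percentile_rule(self):
        rng = np.random.default_rng(0)
        res = rng.uniform(0, 1, (32, 32))
        maps, thr = binarize_residual([res], rule="percentile", percentile=90)
        assert np.sum(maps[0]) == pytest.approx(0.1 * res.size, rel=0.1)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ContractError):
            binarize_residual([np.ones((4, 4))], rule="magic")


class TestScoreFrameSequence:
    def test_all_empty_frames_is_no_hemorrhage(self):
        maps = [np.zeros((4, 4), bool)] * 5
        assert score_frame_sequence(maps) == "no-hemorrhage"

    def test_all_nonempty_frames_is_hemorrhage(self):
        maps = [np.ones((4, 4), bool)] * 5
        assert score_frame_sequence(maps) == "hemorrhage"

    def test_persistence_fraction_boundary(self):
        nonempty = np.ones((4, 4), bool)
        empty = np.zeros((4, 4), bool)
        maps = [nonempty] * 7 + [empty] * 3
        assert score_frame_sequence(maps, 0.8) == "no-hemorrhage"
        assert score_frame_sequence(maps, 0.7) == "hemorrhage"
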