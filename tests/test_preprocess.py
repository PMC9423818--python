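"""Doppler preprocessing: autocorrelation inversion, Kasai velocity decoding,
Otsu masking and ROI standardization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemoflow.preprocess import (
    apply_mask,
    compute_autocorrelation,
    compute_power,
    compute_velocity,
    extract_roi,
    otsu_mask,
)
from hemoflow.types import (
    ContractError,
    DataIntegrityError,
    DegenerateInputError,
    NoFlowError,
    QuadratureFrame,
    VelocityMap,
)

from conftest import otsu_exhaustive


def _frame(rxx, rxy, power_db, f_nyquist=1.0):
    return QuadratureFrame(
        rxx=np.atleast_2d(rxx), rxy=np.atleast_2d(rxy),
        power_db=np.atleast_2d(power_db), f_nyquist=f_nyquist,
    )


class TestAutocorrelation:
    @pytest.mark.parametrize(
        "power_db, rxx, rxy, want_r00, want_r01",
        [
            (0.0, 0.3, 0.1, 1.0, 0.3 + 0.1j),
            (10.0, 1.0, 0.0, 10.0, 10.0 + 0.0j),
            (20.0, 0.0, -0.5, 100.0, 0.0 - 50.0j),
        ],
    )
    def test_db_inversion_and_rescaling(self, power_db, rxx, rxy, want_r00, want_r01):
        r00, r01 = compute_autocorrelation(_frame(rxx, rxy, power_db))
        assert r00[0, 0] == pytest.approx(want_r00)
        assert r01[0, 0] == pytest.approx(want_r01)

    def test_nonfinite_input_rejected_with_pixel_location(self):
        with pytest.raises(DataIntegrityError, match=r"row=0, col=1"):
            _frame([[0.1, np.nan]], [[0.0, 0.0]], [[0.0, 0.0]])

    def test_unit_circle_violation_rejected(self):
        with pytest.raises(DataIntegrityError, match="> 1"):
            _frame([[0.9]], [[0.9]], [[0.0]])


class TestVelocity:
    @pytest.mark.parametrize(
        "r01, want",
        [
            (1.0 + 0.0j, 0.0),          # zero phase
            (0.0 + 1.0j, 0.25),         # phase pi/2
            (-1.0 + 0.0j, 0.5),         # phase pi maps to +f_nyquist
            (0.0 - 1.0j, -0.25),        # phase -pi/2
        ],
    )
    def test_phase_to_velocity(self, r01, want):
        vel = compute_velocity(np.array([[r01]]), f_nyquist=0.5)
        assert vel[0, 0] == pytest.approx(want)

    def test_zero_signal_gets_zero_velocity(self):
        vel = compute_velocity(np.array([[0.0 + 0.0j]]), f_nyquist=1.0)
        assert vel[0, 0] == 0.0

    def test_invalid_nyquist_rejected(self):
        with pytest.raises(ContractError):
            compute_velocity(np.array([[1.0 + 0j]]), f_nyquist=0.0)

    @settings(deadline=None, max_examples=30)
    @given(
        v=st.floats(min_value=-0.99, max_value=0.99),
        fnyq=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_velocity_roundtrip(self, v, fnyq):
        """Encoding velocity as a phase and decoding recovers it exactly."""
        phase = v * np.pi
        r01 = np.array([[np.exp(1j * phase)]])
        assert compute_velocity(r01, fnyq)[0, 0] == pytest.approx(v * fnyq, abs=1e-9)


class TestPower:
    def test_identity_passthrough(self):
        r00 = np.full((3, 4), 3.5)
        out = compute_power(r00)
        np.testing.assert_array_equal(out, r00)
        assert out is not r00

    def test_negative_power_rejected(self):
        with pytest.raises(DataIntegrityError):
            compute_power(np.array([[-1.0]]))


class TestOtsuMask:
    def test_two_level_raster_splits_exactly(self):
        rng = np.random.default_rng(0)
        raster = rng.choice([0.0, 100.0], size=(50, 50))
        mask = otsu_mask(raster)
        np.testing.assert_array_equal(mask, raster == 100.0)

    def test_bimodal_mixture_recovers_components(self):
        rng = np.random.default_rng(42)
        labels = rng.uniform(size=10_000) < 0.5
        values = np.where(labels, rng.normal(60, 3, 10_000), rng.normal(10, 3, 10_000))
        mask = otsu_mask(values.reshape(100, 100))
        mislabeled = np.mean(mask.ravel() != labels)
        assert mislabeled <= 0.01

    def test_constant_raster_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            otsu_mask(np.full((8, 8), 7.0))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        raster = np.concatenate(
            [rng.normal(10, 4, 500), rng.normal(45, 6, 500)]
        ).reshape(20, 50)
        mask = otsu_mask(raster)
        thr = otsu_exhaustive(raster)
        np.testing.assert_array_equal(mask, raster > thr)


class TestApplyMask:
    def test_all_true_mask_changes_nothing(self):
        vel = np.random.default_rng(0).uniform(-1, 1, (6, 6))
        out = apply_mask(vel, np.ones((6, 6), bool))
        np.testing.assert_array_equal(out.cf_vel, vel)

    def test_all_false_mask_zeroes_everything(self):
        vel = np.random.default_rng(0).uniform(-1, 1, (6, 6))
        out = apply_mask(vel, np.zeros((6, 6), bool))
        assert np.all(out.cf_vel == 0)

    def test_checkerboard_zeroes_exactly_the_masked_half(self):
        vel = np.ones((4, 4))
        mask = np.indices((4, 4)).sum(axis=0) % 2 == 0
        out = apply_mask(vel, mask)
        np.testing.assert_array_equal(out.cf_vel, np.where(mask, 1.0, 0.0))
        np.testing.assert_array_equal(out.mask, mask)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            apply_mask(np.zeros((3, 3)), np.ones((4, 4), bool))


def _vmap(vel, mask, fnyq=1.0):
    return VelocityMap(
        cf_vel=vel, cf_power=np.abs(vel), mask=mask, f_nyquist=fnyq
    )


class TestExtractRoi:
    def test_uniform_square_component(self):
        vel = np.zeros((100, 100))
        mask = np.zeros((100, 100), bool)
        vel[45:55, 45:55] = 1.0
        mask[45:55, 45:55] = True
        img = extract_roi(_vmap(vel, mask))
        assert img.pixels.shape == (64, 64)
        # uniform region is scale-invariant under resize
        assert img.pixels[32, 32] == pytest.approx(1.0)

    def test_largest_component_wins(self):
        vel = np.zeros((100, 100))
        mask = np.zeros((100, 100), bool)
        mask[5:10, 5:15] = True        # 50 px, velocity +0.5
        vel[5:10, 5:15] = 0.5
        mask[40:60, 40:65] = True      # 500 px, velocity -0.5
        vel[40:60, 40:65] = -0.5
        img = extract_roi(_vmap(vel, mask))
        # ROI must be built from the big negative-flow component only
        assert np.all(img.pixels <= 0)

    def test_rectangular_component_padded_to_square(self):
        # 10 rows x 30 cols of flow: pre-resize canvas is 30x30 with the
        # 10 content rows centered (rows 10..19)
        vel = np.zeros((50, 50))
        mask = np.zeros((50, 50), bool)
        vel[20:30, 10:40] = 0.8
        mask[20:30, 10:40] = True
        img = extract_roi(_vmap(vel, mask), out_size=30)
        content_rows = np.where(np.any(img.pixels != 0, axis=1))[0]
        assert content_rows.min() >= 9 and content_rows.max() <= 20
        assert np.all(img.pixels[:9] == 0) and np.all(img.pixels[21:] == 0)

    def test_empty_mask_raises_no_flow(self):
        with pytest.raises(NoFlowError):
            extract_roi(_vmap(np.zeros((10, 10)), np.zeros((10, 10), bool)))

    @pytest.mark.parametrize("seed", range(8))
    def test_output_contract_for_arbitrary_components(self, seed):
        """Output is always exactly 64x64 with values in [-1, 1]."""
        rng = np.random.default_rng(seed)
        h, w = rng.integers(40, 120, 2)
        vel = rng.uniform(-2.0, 2.0, (h, w))
        mask = np.zeros((h, w), bool)
        r, c = rng.integers(0, h - 5), rng.integers(0, w - 5)
        dh, dw = rng.integers(2, min(h - r, 30)), rng.integers(2, min(w - c, 30))
        mask[r : r + dh, c : c + dw] = True
        img = extract_roi(_vmap(np.where(mask, vel, 0.0), mask, fnyq=2.0))
        assert img.pixels.shape == (64, 64)
        assert np.all(np.abs(img.pixels) <= 1.0)
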