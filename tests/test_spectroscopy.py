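"""Spectral unmixing: baseline split, attenuation, least-squares inversion."""

import numpy as np
import pytest

from oispipe.config import SpectroConfig
from oispipe.errors import ConfigError, InputError, NumericalError
from oispipe.spectroscopy import (
    HemoMaps,
    ReflectanceStack,
    absorbance_change,
    compute_baseline_concentrations,
    spatial_response_map,
    unmix,
)
from oispipe.synthetic import render_reflectance


@pytest.mark.parametrize(
    "total,sat,expected",
    [(100, 0.80, (80, 20)), (100, 0.90, (90, 10)), (100, 1.00, (100, 0))],
)
def test_baseline_split(total, sat, expected):
    hbo0, hbr0 = compute_baseline_concentrations(total, sat)
    assert (hbo0, hbr0) == pytest.approx(expected)
    assert hbo0 + hbr0 == pytest.approx(total)


def test_baseline_split_rejects_bad_saturation():
    with pytest.raises(InputError):
        compute_baseline_concentrations(100, 1.2)
    with pytest.raises(InputError):
        compute_baseline_concentrations(100, -0.1)


def _stack(data, wavelengths=(494, 560, 575, 595), **kw):
    return ReflectanceStack(
        data=data, wavelengths_nm=np.asarray(wavelengths, float), **kw
    )


class TestAbsorbanceChange:
    def test_identity_when_r_equals_baseline(self):
        data = np.full((4, 10, 3, 3), 50.0)
        dA = absorbance_change(_stack(data), (0, 5))
        assert np.allclose(dA, 0.0)

    def test_closed_form_single_pixel(self):
        data = np.full((4, 10, 2, 2), 10.0)
        data[0, 5, 0, 0] = 10.0 * np.exp(-1.0)
        dA = absorbance_change(_stack(data), (0, 5))
        assert dA[0, 5, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_per_pixel_loop_oracle(self):
        rng = np.random.default_rng(7)
        data = rng.uniform(5.0, 50.0, size=(4, 10, 8, 8))
        window = (2, 6)
        dA = absorbance_change(_stack(data), window)
        # independent brute-force loop
        for w in range(4):
            for x in range(8):
                for y in range(8):
                    r0 = data[w, window[0] : window[1], x, y].mean()
                    for t in range(10):
                        expected = -np.log(data[w, t, x, y] / r0)
                        assert abs(dA[w, t, x, y] - expected) < 1e-12

    def test_rejects_nonpositive_intensity(self):
        data = np.full((4, 6, 2, 2), 5.0)
        data[1, 3, 0, 1] = 0.0
        with pytest.raises(InputError, match="frame 3"):
            _stack(data)

    def test_rejects_empty_baseline_window(self):
        data = np.full((4, 6, 2, 2), 5.0)
        with pytest.raises(ConfigError):
            absorbance_change(_stack(data), (3, 3))


class TestUnmix:
    def test_zero_absorbance_gives_zero_concentrations(self, cfg):
        hemo = unmix(np.zeros((4, 5, 3, 3)), cfg)
        assert np.allclose(hemo.dhbo, 0) and np.allclose(hemo.dhbr, 0)
        assert np.allclose(hemo.dhbt, 0)

    def test_noise_free_round_trip(self, cfg):
        """Forward-rendered (2, -1) uM recovers to better than 1e-8 uM."""
        dhbo = np.full((5, 4, 4), 2.0)
        dhbr = np.full((5, 4, 4), -1.0)
        stack = render_reflectance(dhbo, dhbr, cfg, noise_sigma=0.0)
        dA = -np.log(stack.data / 1000.0)
        hemo = unmix(dA, cfg)
        assert np.abs(hemo.dhbo - 2.0).max() < 1e-8
        assert np.abs(hemo.dhbr + 1.0).max() < 1e-8

    def test_recovery_error_shrinks_with_noise_and_is_unbiased(self, cfg):
        """Monte-Carlo: RMSE decreases monotonically as sigma drops; mean
        error is within 3 SEM of zero at sigma = 0.5%."""
        dhbo = np.full((4, 6, 6), 2.0)
        dhbr = np.full((4, 6, 6), -1.0)
        rmses = []
        for sigma in (0.02, 0.005, 0.001):
            errs = []
            for seed in range(100):
                stack = render_reflectance(
                    dhbo, dhbr, cfg, noise_sigma=sigma, seed=seed
                )
                dA = -np.log(stack.data / 1000.0)
                hemo = unmix(dA, cfg)
                errs.append(hemo.dhbo - 2.0)
            errs = np.asarray(errs)
            rmses.append(np.sqrt((errs**2).mean()))
            if sigma == 0.005:
                mean_err = errs.mean()
                sem = errs.std() / np.sqrt(errs.size)
                assert abs(mean_err) < 3 * sem
        assert rmses[0] > rmses[1] > rmses[2]

    def test_linearity(self, cfg):
        rng = np.random.default_rng(3)
        dA = rng.normal(0, 0.01, size=(4, 5, 3, 3))
        h1 = unmix(dA, cfg)
        h2 = unmix(2.5 * dA, cfg)
        assert np.allclose(h2.dhbo, 2.5 * h1.dhbo, atol=1e-12)
        assert np.allclose(h2.dhbr, 2.5 * h1.dhbr, atol=1e-12)

    def test_matches_normal_equations_oracle(self, cfg):
        rng = np.random.default_rng(11)
        dA = rng.normal(0, 0.01, size=(4, 3, 2, 2))
        hemo = unmix(dA, cfg)
        M = cfg.design_matrix("tissue")
        MtM_inv = np.linalg.inv(M.T @ M)
        for t in range(3):
            for x in range(2):
                for y in range(2):
                    c = MtM_inv @ M.T @ dA[:, t, x, y]
                    assert hemo.dhbo[t, x, y] == pytest.approx(c[0], abs=1e-12)
                    assert hemo.dhbr[t, x, y] == pytest.approx(c[1], abs=1e-12)

    def test_conservation_dhbt(self, cfg):
        rng = np.random.default_rng(5)
        hemo = unmix(rng.normal(0, 0.01, size=(4, 5, 3, 3)), cfg)
        assert np.allclose(hemo.dhbt, hemo.dhbo + hemo.dhbr, atol=1e-12)

    def test_ill_conditioned_design_raises(self):
        eps = np.column_stack([np.ones(4), np.ones(4) * (1 + 1e-12)]) * 0.02
        cfg = SpectroConfig(epsilon=eps)
        with pytest.raises(NumericalError):
            unmix(np.zeros((4, 2, 2, 2)), cfg)

    def test_wavelength_mismatch_raises(self, cfg):
        with pytest.raises(ConfigError):
            unmix(np.zeros((3, 2, 2, 2)), cfg)


class TestSpatialResponseMap:
    def _hemo(self, dhbt, fr=16.0):
        return HemoMaps(
            dhbo=dhbt, dhbr=np.zeros_like(dhbt), dhbt=dhbt, frame_rate_hz=fr
        )

    def test_planted_blob_peaks_at_center(self, small_scene):
        hemo = self._hemo(small_scene["dhbt"])
        z = spatial_response_map(hemo, small_scene["trigger_times_s"], (0, 5), (-5, 0))
        peak = np.unravel_index(np.argmax(z), z.shape)
        assert abs(peak[0] - 16) <= 1 and abs(peak[1] - 16) <= 1

    def test_constant_response_yields_zero_map(self):
        dhbt = np.ones((160, 8, 8))
        z = spatial_response_map(self._hemo(dhbt), [5.0], (0, 2), (-2, 0))
        assert np.all(z == 0)

    def test_scale_invariance(self, small_scene):
        hemo1 = self._hemo(small_scene["dhbt"])
        hemo2 = self._hemo(2.0 * small_scene["dhbt"])
        z1 = spatial_response_map(hemo1, small_scene["trigger_times_s"], (0, 5), (-5, 0))
        z2 = spatial_response_map(hemo2, small_scene["trigger_times_s"], (0, 5), (-5, 0))
        assert np.allclose(z1, z2, atol=1e-9)

    def test_no_usable_trigger_raises(self):
        dhbt = np.random.default_rng(0).normal(size=(32, 4, 4))
        with pytest.raises(InputError):
            spatial_response_map(self._hemo(dhbt), [0.5], (0, 5), (-5, 0))


def test_hemomaps_rejects_broken_conservation():
    a = np.ones((3, 2, 2))
    with pytest.raises(InputError):
        HemoMaps(dhbo=a, dhbr=a, dhbt=a, frame_rate_hz=32.0)
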