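"""Centered FFT pair, keyhole geometry, Tukey taper, normalization, fusion."""

import numpy as np
import pytest
from scipy.signal.windows import tukey as scipy_tukey

import hybridflair as hf
from hybridflair.exceptions import DegenerateInputError, InputError


class TestFourierPair:
    def test_round_trip(self):
        x = np.random.default_rng(0).normal(size=(16, 24))
        back = hf.kspace_to_image(hf.image_to_kspace(x))
        np.testing.assert_allclose(back, x, rtol=0, atol=1e-12 * np.abs(x).max())

    def test_constant_image_concentrates_at_dc(self):
        # direct DFT summation oracle: constant c on n x n -> DC = c * n
        n, c = 12, 3.5
        k = hf.image_to_kspace(np.full((n, n), c))
        assert k[n // 2, n // 2] == pytest.approx(c * n, rel=1e-12)
        off = k.copy()
        off[n // 2, n // 2] = 0
        assert np.abs(off).max() < 1e-12 * c * n

    def test_parseval(self):
        x = np.random.default_rng(1).normal(size=(10, 14))
        k = hf.image_to_kspace(x)
        assert np.sum(np.abs(k) ** 2) == pytest.approx(np.sum(x**2), rel=1e-12)

    def test_non_2d_rejected(self):
        with pytest.raises(InputError):
            hf.image_to_kspace(np.zeros(8))


class TestKeyholeSpec:
    def test_r8_on_224_lines(self):
        spec = hf.make_keyhole_spec(224, 8)
        assert spec.n_keep == 28
        assert spec.acquired_lines[0] == 98 and spec.acquired_lines[-1] == 125
        assert spec.fraction == pytest.approx(0.125)
        assert 112 in spec.acquired_lines  # DC line

    def test_no_acceleration_keeps_all_lines(self):
        spec = hf.make_keyhole_spec(64, 1)
        assert np.array_equal(spec.acquired_lines, np.arange(64))

    def test_non_divisible_band_is_centered(self):
        spec = hf.make_keyhole_spec(10, 3)
        assert np.array_equal(spec.acquired_lines, [3, 4, 5, 6])
        assert 5 in spec.acquired_lines

    @pytest.mark.parametrize("bad", [0, -2])
    def test_invalid_acceleration_rejected(self, bad):
        with pytest.raises(InputError):
            hf.make_keyhole_spec(64, bad)


class TestTukeyWindow:
    def test_plateau_endpoints_and_support(self):
        spec = hf.make_keyhole_spec(224, 8, taper_ratio=0.25)
        w = hf.tukey_window(spec)
        band = w[spec.acquired_lines]
        y = np.arange(spec.n_keep) / (spec.n_keep - 1)
        assert np.all(band[(y >= 0.125) & (y <= 0.875)] == 1.0)
        assert band[0] == pytest.approx(0.0, abs=1e-15)
        assert band[-1] == pytest.approx(0.0, abs=1e-15)
        outside = np.ones(224, bool)
        outside[spec.acquired_lines] = False
        assert np.all(w[outside] == 0.0)
        assert np.all((w >= 0) & (w <= 1))
        np.testing.assert_allclose(band, band[::-1], atol=1e-15)

    def test_limits_hann_and_boxcar(self):
        n = 64
        hann_band = hf.tukey_window(hf.make_keyhole_spec(n, 1, 1.0))
        y = np.arange(n) / (n - 1)
        np.testing.assert_allclose(hann_band, np.sin(np.pi * y) ** 2, atol=1e-12)
        box_band = hf.tukey_window(hf.make_keyhole_spec(n, 1, 0.0))
        np.testing.assert_allclose(box_band, np.ones(n))

    @pytest.mark.parametrize("r", [0.0, 0.25, 0.5, 1.0])
    def test_matches_scipy_reference(self, r):
        spec = hf.make_keyhole_spec(224, 8, taper_ratio=r)
        band = hf.tukey_window(spec)[spec.acquired_lines]
        np.testing.assert_allclose(band, scipy_tukey(spec.n_keep, alpha=r,
                                                     sym=True), atol=1e-12)

    def test_single_line_band_clamped_with_warning(self):
        spec = hf.make_keyhole_spec(4, 4, taper_ratio=0.25)
        with pytest.warns(UserWarning, match="single-line"):
            w = hf.tukey_window(spec)
        assert w[spec.acquired_lines[0]] == 1.0


class TestUndersampling:
    def test_full_sampling_is_identity(self):
        k = np.random.default_rng(2).normal(size=(8, 8)) + 0j
        spec = hf.make_keyhole_spec(8, 1)
        assert np.array_equal(hf.retrospective_undersample(k, spec), k)

    def test_masked_lines_are_exactly_zero_and_band_bitwise_kept(self):
        rng = np.random.default_rng(3)
        k = rng.normal(size=(32, 16)) + 1j * rng.normal(size=(32, 16))
        spec = hf.make_keyhole_spec(32, 4)
        ku = hf.retrospective_undersample(k, spec)
        assert np.array_equal(ku[spec.acquired_lines], k[spec.acquired_lines])
        outside = np.setdiff1d(np.arange(32), spec.acquired_lines)
        assert np.all(ku[outside] == 0)


class TestNormalizationFactor:
    def test_identical_inputs_give_unity(self):
        rng = np.random.default_rng(4)
        k = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        w = hf.tukey_window(hf.make_keyhole_spec(16, 2))
        assert hf.normalization_factor(k, k, w) == pytest.approx(1.0)

    def test_hand_rms_toy_case(self):
        # conv moduli [3, 4], phys moduli [1, 2], unit window:
        # sqrt(12.5) / sqrt(2.5) = sqrt 5
        k_conv = np.array([[3.0, 4.0]], dtype=complex)
        k_phys = np.array([[1.0, 2.0]], dtype=complex)
        n = hf.normalization_factor(k_conv, k_phys, np.array([1.0]))
        assert n == pytest.approx(np.sqrt(5.0), rel=1e-12)

    def test_homogeneity_in_conventional_scale(self):
        rng = np.random.default_rng(5)
        kc = rng.normal(size=(16, 8)) + 1j * rng.normal(size=(16, 8))
        kp = rng.normal(size=(16, 8)) + 1j * rng.normal(size=(16, 8))
        w = hf.tukey_window(hf.make_keyhole_spec(16, 2))
        n1 = hf.normalization_factor(kc, kp, w)
        assert hf.normalization_factor(3.7 * kc, kp, w) == pytest.approx(3.7 * n1)

    def test_zero_windowed_physics_energy_rejected(self):
        w = hf.tukey_window(hf.make_keyhole_spec(16, 2))
        kc = np.ones((16, 8), complex)
        with pytest.raises(DegenerateInputError):
            hf.normalization_factor(kc, np.zeros((16, 8), complex), w)


class TestCombine:
    def test_consistent_inputs_pass_through(self):
        rng = np.random.default_rng(6)
        k = rng.normal(size=(16, 8)) + 1j * rng.normal(size=(16, 8))
        w = hf.tukey_window(hf.make_keyhole_spec(16, 4))
        np.testing.assert_allclose(hf.combine_kspace(k, k, w, 1.0), k,
                                   rtol=1e-15)

    def test_unit_window_returns_conventional(self):
        rng = np.random.default_rng(7)
        kc = rng.normal(size=(4, 4)) + 0j
        kp = rng.normal(size=(4, 4)) + 0j
        assert np.array_equal(hf.combine_kspace(kc, kp, np.ones(4), 2.0), kc)

    def test_keyhole_locality(self):
        """w = 1 lines come from the conventional data, w = 0 lines from
        the scaled physics data, exactly."""
        rng = np.random.default_rng(8)
        kc = rng.normal(size=(32, 8)) + 1j * rng.normal(size=(32, 8))
        kp = rng.normal(size=(32, 8)) + 1j * rng.normal(size=(32, 8))
        spec = hf.make_keyhole_spec(32, 4, taper_ratio=0.25)
        w = hf.tukey_window(spec)
        n = 1.7
        out = hf.combine_kspace(kc, kp, w, n)
        assert np.array_equal(out[w == 1.0], kc[w == 1.0])
        assert np.array_equal(out[w == 0.0], n * kp[w == 0.0])


class TestHybridReconstruct:
    def test_identity_chain(self, small_phantom):
        """Fully consistent data reproduces the physics image."""
        _, _, _, phys = small_phantom
        mask = hf.extract_brain_mask(np.abs(phys), 0.5)
        spec = hf.make_keyhole_spec(128, 8)
        hyb = hf.hybrid_reconstruct(phys, phys, spec, mask)
        rel = np.sqrt(np.mean((hyb - phys) ** 2) / np.mean(phys**2))
        assert rel < 1e-9

    def test_skull_region_copied_bit_exactly(self, mismatch_phantom):
        spec, labels, phys, conv, mask = mismatch_phantom
        samp = hf.make_keyhole_spec(224, 8)
        hyb = hf.hybrid_reconstruct(conv, phys, samp, mask)
        assert np.array_equal(hyb[~mask], phys[~mask])

    def test_homogeneity_in_conventional(self, small_phantom):
        _, labels, _, phys = small_phantom
        mask = hf.extract_brain_mask(np.abs(phys), 0.5)
        conv = phys * 1.3
        conv[labels == hf.LABELS["lesion"]] *= 1.5
        spec = hf.make_keyhole_spec(128, 8)
        h1 = hf.hybrid_reconstruct(conv, phys, spec, mask)
        h2 = hf.hybrid_reconstruct(2.5 * conv, phys, spec, mask)
        np.testing.assert_allclose(h2[mask], 2.5 * h1[mask], rtol=1e-9)

    def test_invariance_to_physics_rescale(self, small_phantom):
        """Scaling S_P cancels against the recomputed normalization."""
        _, labels, _, phys = small_phantom
        mask = hf.extract_brain_mask(np.abs(phys), 0.5)
        conv = phys.copy()
        conv[labels == hf.LABELS["lesion"]] *= 1.8
        spec = hf.make_keyhole_spec(128, 8)
        h1 = hf.hybrid_reconstruct(conv, phys, spec, mask)
        h2 = hf.hybrid_reconstruct(conv, 3.0 * phys, spec, mask)
        np.testing.assert_allclose(h2[mask], h1[mask], rtol=1e-9, atol=1e-12)

    def test_hybrid_lesion_tracks_conventional(self, mismatch_phantom):
        """The keyhole band transplants the lesion hyperintensity: the
        hybrid lesion mean sits closer to the conventional one than the
        physics-based lesion mean does."""
        spec, labels, phys, conv, mask = mismatch_phantom
        samp = hf.make_keyhole_spec(224, 8, taper_ratio=0.25)
        hyb = hf.hybrid_reconstruct(conv, phys, samp, mask)
        les = labels == hf.LABELS["lesion"]
        dev_hyb = abs(hyb[les].mean() - conv[les].mean())
        dev_phys = abs(phys[les].mean() - conv[les].mean())
        assert dev_hyb < dev_phys

    def test_empty_mask_rejected(self, small_phantom):
        _, _, _, phys = small_phantom
        spec = hf.make_keyhole_spec(128, 8)
        with pytest.raises(DegenerateInputError):
            hf.hybrid_reconstruct(phys, phys, spec, np.zeros_like(phys, bool))

    def test_grid_mismatch_rejected(self, small_phantom):
        _, _, _, phys = small_phantom
        spec = hf.make_keyhole_spec(128, 8)
        with pytest.raises(InputError):
            hf.hybrid_reconstruct(phys[:, :64, :], phys, spec,
                                  np.ones_like(phys, bool))
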