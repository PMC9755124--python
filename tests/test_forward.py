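import numpy as np
import pytest

from bsidt.forward import (
    IntensityStack,
    born_oracle_contrast,
    born_oracle_intensity,
    predict_contrast,
    predict_intensity,
    simulate_frames,
)
from bsidt.optics import ComplexVolume, ri_to_permittivity
from bsidt.synthetic import Bead, make_bead_phantom


class TestLinearForwardModel:
    def test_empty_volume_gives_uniform_background(self, small_config, small_tfs):
        vol = np.zeros(small_config.volume_shape, complex)
        img = predict_intensity(vol, small_tfs, 0, background=200.0)
        assert np.allclose(img, 200.0)

    def test_exactly_linear_in_contrast(self, small_config, small_tfs, rng):
        vol = rng.normal(size=small_config.volume_shape) * 1e-3 + 0j
        one = predict_intensity(vol, small_tfs, 3) - 1.0
        two = predict_intensity(2 * vol, small_tfs, 3) - 1.0
        assert np.allclose(two, 2 * one, atol=1e-15)

    def test_real_point_at_focus_invisible_on_axis(self, small_config):
        """End-to-end version of the on-axis in-focus identity."""
        from bsidt.transfer import IlluminationSet, compute_tfs

        tfs = compute_tfs(small_config, IlluminationSet(nu=np.array([[0.0, 0.0]]), amplitudes=np.array([1.0])))
        vol = np.zeros(small_config.volume_shape, complex)
        vol[16, 16, 2] = 2e-3  # purely real contrast at the m=0 slice
        g = predict_contrast(vol, tfs, 0)
        assert np.abs(g).max() < 1e-14

    def test_predicted_images_are_real_valued(self, small_config, small_tfs, rng):
        """Hermitian pairing: the pre-projection imaginary residual is
        negligible against the real part."""
        vol = (rng.normal(size=small_config.volume_shape) + 1j * rng.normal(size=small_config.volume_shape)) * 1e-3
        spec = np.zeros((small_config.ny, small_config.nx), complex)
        for mi in range(small_config.nz):
            spec += small_tfs.H_re[0, mi] * np.fft.fft2(vol[:, :, mi].real)
            spec += small_tfs.H_im[0, mi] * np.fft.fft2(vol[:, :, mi].imag)
        img = np.fft.ifft2(spec)
        assert np.linalg.norm(img.imag) < 1e-6 * np.linalg.norm(img.real)


class TestBornOracleEquivalence:
    def test_zero_volume_uniform_intensity(self, small_config, small_ring):
        vol = np.zeros(small_config.volume_shape, complex)
        I = born_oracle_intensity(vol, small_config, small_ring.nu[0])
        assert np.allclose(I, I.mean(), rtol=1e-9)

    def test_tf_model_matches_oracle_within_five_percent(self, small_config, small_ring, small_tfs):
        """The central correctness gate for the spectral forward model:
        background-normalised contrast agrees with the direct Green's
        function summation on a weak bead."""
        ph = make_bead_phantom(small_config, [Bead(center=(0, 0, 0), radius=0.2, delta_n=5e-4)])
        eps = ph.delta_eps(small_config)
        errs = []
        for i in range(small_ring.count):
            g_tf = predict_contrast(eps, small_tfs, i)
            g_or = born_oracle_contrast(eps, small_config, small_ring.nu[i])
            errs.append(np.linalg.norm(g_tf - g_or) / np.linalg.norm(g_or))
        assert max(errs) <= 0.05

    def test_contrast_doubles_with_contrast_to_first_order(self, small_config, small_ring):
        ph = make_bead_phantom(small_config, [Bead(center=(0, 0, 0), radius=0.2, delta_n=5e-4)])
        eps1 = ph.delta_eps(small_config).values
        g1 = born_oracle_contrast(eps1, small_config, small_ring.nu[0])
        g2 = born_oracle_contrast(2 * eps1, small_config, small_ring.nu[0])
        # second-order Born residual is O(dn^2), far below 1% here
        assert np.linalg.norm(g2 - 2 * g1) / np.linalg.norm(g2) < 0.01

    def test_grid_guard_rejects_large_volumes(self, bead_config):
        big = np.zeros(bead_config.volume_shape, complex)  # 64x64x9 voxels
        with pytest.raises(ValueError, match="guard"):
            born_oracle_intensity(big, bead_config, np.array([0.0, 0.0]))


class TestCameraNoise:
    def test_infinite_budget_returns_exact_copies(self, rng):
        clean = 1.0 + 0.1 * rng.random((8, 8))
        frames = simulate_frames(clean, np.inf, n_repeats=3, seed=7)
        assert np.array_equal(frames[0], clean)
        assert np.array_equal(frames[2], clean)

    def test_poisson_variance_matches_mean(self):
        clean = np.full((16, 16), 1.0)
        budget = 500.0
        frames = simulate_frames(clean, budget, n_repeats=1000, seed=11)
        counts = frames * budget
        ratio = counts.var(axis=0).mean() / counts.mean(axis=0).mean()
        assert ratio == pytest.approx(1.0, rel=0.05)

    def test_frame_averaging_reduces_noise_sqrt_n(self):
        clean = np.full((16, 16), 1.0)
        frames = simulate_frames(clean, 1000.0, n_repeats=60, seed=3)
        single_std = frames[0].std()
        avg_std = frames.mean(axis=0).std()
        assert single_std / avg_std == pytest.approx(np.sqrt(60), rel=0.25)

    def test_deterministic_per_frame_index(self):
        clean = np.full((4, 4), 1.0)
        a = simulate_frames(clean, 100.0, n_repeats=2, seed=5)
        b = simulate_frames(clean, 100.0, n_repeats=2, seed=5)
        assert np.array_equal(a, b)

    def test_rejects_non_positive_budget(self):
        with pytest.raises(ValueError, match="budget"):
            simulate_frames(np.ones((4, 4)), 0.0)


class TestIntensityStack:
    def test_shape_and_state_validation(self):
        frames = np.ones((2, 2, 1, 4, 4))
        bgs = np.ones((2, 2, 1))
        stack = IntensityStack(frames=frames, backgrounds=bgs)
        assert stack.n_sources == 2
        with pytest.raises(ValueError, match="state"):
            stack.normalized_contrast("warm")
        with pytest.raises(ValueError, match="non-negative"):
            IntensityStack(frames=-frames, backgrounds=bgs)

    def test_normalized_contrast_uses_background(self):
        frames = np.full((1, 2, 2, 4, 4), 150.0)
        bgs = np.full((1, 2, 2), 100.0)
        stack = IntensityStack(frames=frames, backgrounds=bgs)
        assert np.allclose(stack.normalized_contrast("hot"), 0.5)
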