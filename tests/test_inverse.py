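import numpy as np
import pytest

from bsidt.forward import predict_contrast
from bsidt.inverse import (
    ReconstructionSettings,
    band_limit_to_support,
    hot_cold_subtract,
    reconstruct_from_contrast,
    to_ri_volume,
)
from bsidt.optics import ComplexVolume, ri_to_permittivity
from bsidt.synthetic import Bead, make_bead_phantom


def forward_all(eps, tfs):
    return np.stack([predict_contrast(eps, tfs, i) for i in range(tfs.n_sources)])


class TestBasicContracts:
    def test_zero_input_zero_volume(self, small_config, small_tfs):
        g = np.zeros((small_tfs.n_sources, small_config.ny, small_config.nx))
        rec = reconstruct_from_contrast(g, small_tfs)
        assert np.abs(rec.values).max() == 0.0

    def test_linearity_in_contrast(self, small_config, small_tfs, rng):
        g = rng.normal(size=(small_tfs.n_sources, small_config.ny, small_config.nx)) * 1e-3
        a = reconstruct_from_contrast(g, small_tfs).values
        b = reconstruct_from_contrast(2 * g, small_tfs).values
        assert np.allclose(b, 2 * a, atol=1e-18)

    def test_regularization_monotonicity(self, small_config, small_tfs, rng):
        """Total reconstruction energy is non-increasing in the Tikhonov weights."""
        g = rng.normal(size=(small_tfs.n_sources, small_config.ny, small_config.nx)) * 1e-3
        energies = []
        for frac in (1e-4, 1e-3, 1e-2, 1e-1):
            rec = reconstruct_from_contrast(g, small_tfs, ReconstructionSettings(beta_fraction=frac))
            energies.append(np.sum(np.abs(rec.values) ** 2))
        assert np.all(np.diff(energies) <= 0)

    def test_hermitian_input_gives_real_channels(self, small_config, small_tfs):
        """With real (Hermitian-paired) contrast images the pre-projection
        imaginary residual of both recovered channels is negligible."""
        ph = make_bead_phantom(small_config, [Bead(center=(0, 0, 0), radius=0.2, delta_n=5e-4)])
        g = forward_all(ph.delta_eps(small_config), small_tfs)
        raw = reconstruct_from_contrast(g, small_tfs, ReconstructionSettings(enforce_real_output=False)).values
        proj = reconstruct_from_contrast(g, small_tfs, ReconstructionSettings(enforce_real_output=True)).values
        assert np.linalg.norm(raw - proj) <= 1e-6 * np.linalg.norm(proj)


class TestClosedLoopRecovery:
    def test_bead_centroid_within_one_voxel(self, bead_config, bead_tfs):
        bead = Bead(center=(0.65, -0.49, 0.3), radius=0.5, delta_n=1e-3)
        ph = make_bead_phantom(bead_config, [bead])
        g = forward_all(ph.delta_eps(bead_config), bead_tfs)
        rec = reconstruct_from_contrast(g, bead_tfs, ReconstructionSettings(beta_fraction=1e-3))
        vol = rec.values.real
        iy, ix, iz = np.unravel_index(np.argmax(vol), vol.shape)
        x, y = bead_config.lateral_coords()
        z = bead_config.z_positions
        ty = np.argmin(np.abs(y - bead.center[1]))
        tx = np.argmin(np.abs(x - bead.center[0]))
        tz = np.argmin(np.abs(z - bead.center[2]))
        assert abs(iy - ty) <= 1 and abs(ix - tx) <= 1 and abs(iz - tz) <= 1

    def test_correlation_with_band_limited_truth(self, bead_config, bead_tfs):
        """Noise-free joint inversion is a faithful band-limited image of the
        ground truth within the synthetic-aperture support."""
        ph = make_bead_phantom(bead_config, [Bead(center=(0.65, -0.49, 0.3), radius=0.5, delta_n=1e-3)])
        g = forward_all(ph.delta_eps(bead_config), bead_tfs)
        rec = reconstruct_from_contrast(
            g, bead_tfs, ReconstructionSettings(beta_fraction=1e-4, joint_slices=True)
        ).values.real
        truth_bl = band_limit_to_support(ph.delta_n_cold, bead_tfs)
        corr = np.corrcoef(rec.ravel(), truth_bl.ravel())[0, 1]
        assert corr >= 0.95

    def test_forward_consistency_residual_decreases_with_beta(self, small_config, small_tfs):
        """Re-applying the forward model to the joint-solve reconstruction
        reproduces the input spectra, with residual monotone in the
        regularisation weight (the joint solve minimises exactly this
        residual; the slice-decoupled closed form does not)."""
        ph = make_bead_phantom(small_config, [Bead(center=(0, 0, 0), radius=0.2, delta_n=5e-4)])
        g = forward_all(ph.delta_eps(small_config), small_tfs)
        residuals = []
        for frac in (1e-1, 1e-2, 1e-3, 1e-4):
            rec = reconstruct_from_contrast(
                g, small_tfs, ReconstructionSettings(beta_fraction=frac, joint_slices=True))
            g_replay = forward_all(rec, small_tfs)
            residuals.append(np.linalg.norm(g_replay - g) / np.linalg.norm(g))
        assert np.all(np.diff(residuals) <= 1e-12)


class TestRiConversionAndSubtraction:
    def test_zero_permittivity_gives_medium_index(self, small_config):
        vol = ComplexVolume(values=np.zeros(small_config.volume_shape, complex))
        ri = to_ri_volume(vol, small_config)
        assert np.allclose(ri, small_config.medium_ri)

    def test_known_slab(self, small_config):
        eps = np.full(small_config.volume_shape, 0.004, complex)
        ri = to_ri_volume(eps, small_config)
        assert np.allclose(ri, np.sqrt(small_config.medium_ri**2 + 0.004))

    def test_hot_equals_cold_gives_identically_zero(self):
        vol = np.random.default_rng(0).normal(size=(8, 8, 3))
        rec = hot_cold_subtract(vol, vol, wavenumber=1745.0)
        assert np.all(rec.delta_ri == 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share a shape"):
            hot_cold_subtract(np.zeros((4, 4, 2)), np.zeros((4, 4, 3)))

    def test_delta_consistency_enforced(self):
        from bsidt.inverse import ChemicalRecord

        with pytest.raises(ValueError, match="delta_ri"):
            ChemicalRecord(cold_ri=np.zeros((2, 2, 2)), hot_ri=np.ones((2, 2, 2)),
                           delta_ri=np.zeros((2, 2, 2)))
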