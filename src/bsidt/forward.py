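"""Forward simulation of camera intensities.

Two independent routes predict the intensity recorded under one oblique
illumination:

* :func:`predict_intensity` — the fast linear route: slice-wise 2D FFTs of
  the permittivity contrast multiplied by the transfer functions and summed
  over slices, then returned to the camera plane.
* :func:`born_oracle_intensity` — a brute-force first-Born field oracle
  that sums ``u_i(r') V(r') G(r - r')`` over every voxel in the spatial
  domain, low-pass filters the total field by the pupil and squares it.
  It shares no code with the transfer-function route and serves as the
  physics cross-check on small grids.

:func:`simulate_frames` adds Poisson shot noise (plus optional Gaussian
read noise) at a stated photon budget, reproducibly per frame index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .optics import ComplexVolume, FrequencyGrid, OpticalConfig, axial_frequency, axial_frequency_at, pupil
from .transfer import TransferFunctionSet

__all__ = [
    "STATES",
    "IntensityStack",
    "predict_intensity",
    "predict_contrast",
    "born_oracle_intensity",
    "born_oracle_contrast",
    "simulate_frames",
    "BORN_MAX_VOXELS",
]

STATES = ("hot", "cold")

#: Guard for the brute-force oracle: direct voxel summation is O(N^4 nz)
#: and is only intended for small cross-validation grids.
BORN_MAX_VOXELS = 48 * 48 * 7


def _hermitian_symmetrize(spec: np.ndarray) -> np.ndarray:
    """Project a 2D spectrum onto the Hermitian subspace (real image)."""
    ny, nx = spec.shape
    rev = spec[(-np.arange(ny)) % ny][:, (-np.arange(nx)) % nx]
    return 0.5 * (spec + np.conj(rev))


def predict_contrast(
    volume: ComplexVolume | np.ndarray,
    tfs: TransferFunctionSet,
    source: int,
) -> np.ndarray:
    """Normalised intensity contrast ``(I - I_bg)/I_bg`` for one source.

    Implements the linear spectral model: the contrast spectrum is the sum
    over slices of ``H_re * FT(delta_eps_re) + H_im * FT(delta_eps_im)``.
    The Hermitian pairing of each source with its own conjugate cross-term
    is built into the transfer functions, so the spectrum is symmetrised
    and the real part taken only to scrub floating-point leakage.
    """
    values = volume.values if isinstance(volume, ComplexVolume) else np.asarray(volume, dtype=complex)
    cfg = tfs.config
    if values.shape != cfg.volume_shape:
        raise ValueError(f"volume shape {values.shape} does not match config {cfg.volume_shape}")
    if not 0 <= source < tfs.n_sources:
        raise IndexError("source index out of range")

    spec = np.zeros((cfg.ny, cfg.nx), dtype=complex)
    for mi in range(cfg.nz):
        eps_re_hat = np.fft.fft2(values[:, :, mi].real)
        eps_im_hat = np.fft.fft2(values[:, :, mi].imag)
        spec += tfs.H_re[source, mi] * eps_re_hat + tfs.H_im[source, mi] * eps_im_hat
    spec = _hermitian_symmetrize(spec)
    return np.fft.ifft2(spec).real


def predict_intensity(
    volume: ComplexVolume | np.ndarray,
    tfs: TransferFunctionSet,
    source: int,
    background: float = 1.0,
) -> np.ndarray:
    """Camera intensity ``background * (1 + contrast)`` for one source."""
    if background <= 0:
        raise ValueError("background level must be positive")
    return background * (1.0 + predict_contrast(volume, tfs, source))


# ---------------------------------------------------------------------------
# Brute-force first-Born oracle
# ---------------------------------------------------------------------------


def born_oracle_intensity(
    volume: ComplexVolume | np.ndarray,
    config: OpticalConfig,
    nu_i: np.ndarray,
    amplitude: float = 1.0,
    detector_offset_slices: int = 1,
    periodic_copies: int = 2,
    max_voxels: int = BORN_MAX_VOXELS,
) -> np.ndarray:
    """Direct spatial-domain first-Born intensity for one plane-wave source.

    The scattered field is evaluated on a detector plane just above the
    volume by summing ``u_i(r') V(r') G(r - r')`` over every voxel, with
    ``V = k0^2 delta_eps / (4 pi)`` and ``G(r) = exp(j k_m |r|)/|r|``.
    The total field is then band-limited by the pupil and numerically
    refocused to the focal plane, and the squared modulus is returned.

    The simulation window is laterally periodic, so the free-space
    Green's function is periodized by additionally summing
    ``periodic_copies`` rings of laterally shifted object copies (each
    carrying the incident carrier phase of its shifted position); the
    slowly decaying 1/R tails otherwise leave a few-percent windowing
    mismatch against any periodic forward model.

    ``nu_i`` should lie on the DFT frequency grid of ``config`` (use
    ``IlluminationSet.ring(..., snap_to_grid=True)``) so the plane-wave
    carrier is itself periodic on the window.
    """
    values = volume.values if isinstance(volume, ComplexVolume) else np.asarray(volume, dtype=complex)
    if values.shape != config.volume_shape:
        raise ValueError("volume shape does not match config")
    n_vox = int(np.prod(values.shape))
    if n_vox > max_voxels:
        raise ValueError(
            f"{n_vox} voxels exceeds the direct-summation guard ({max_voxels}); "
            "use a smaller cross-validation grid"
        )

    nu_i = np.asarray(nu_i, dtype=float)
    eta_i = axial_frequency_at(nu_i, config)
    if eta_i <= 0:
        raise ValueError("source frequency is evanescent")
    kz_i = 2.0 * np.pi * eta_i
    k0 = config.k_vacuum
    k_m = config.k_medium

    x, y = config.lateral_coords()
    X, Y = np.meshgrid(x, y)
    z_slices = config.z_positions
    z_det = float(z_slices.max()) + detector_offset_slices * config.slice_thickness
    period_x = config.nx * config.pixel_size
    period_y = config.ny * config.pixel_size

    carrier = np.exp(2j * np.pi * (nu_i[0] * X + nu_i[1] * Y))
    voxel_volume = config.pixel_size**2 * config.slice_thickness

    # Scattered field on the detector plane: direct sum over voxels and
    # lateral image copies, chunked per slice/row.
    u_s = np.zeros((config.ny, config.nx), dtype=complex)
    pts_x = X.ravel()
    pts_y = Y.ravel()
    copies = range(-periodic_copies, periodic_copies + 1)
    for mi, z_m in enumerate(z_slices):
        src = (
            amplitude
            * carrier
            * np.exp(1j * kz_i * z_m)
            * (k0**2 / (4.0 * np.pi))
            * values[:, :, mi]
        ).ravel()
        nonzero = np.abs(src) > 0
        if not np.any(nonzero):
            continue
        sx = pts_x[nonzero]
        sy = pts_y[nonzero]
        sw = src[nonzero]
        dz = z_det - z_m
        for cx in copies:
            for cy in copies:
                copy_phase = np.exp(
                    2j * np.pi * (nu_i[0] * cx * period_x + nu_i[1] * cy * period_y)
                )
                sw_c = sw * copy_phase
                off_x = sx + cx * period_x
                off_y = sy + cy * period_y
                for row in range(config.ny):
                    dx = X[row][:, None] - off_x[None, :]
                    dy = Y[row][:, None] - off_y[None, :]
                    R = np.sqrt(dx * dx + dy * dy + dz * dz)
                    u_s[row] += (np.exp(1j * k_m * R) / R) @ sw_c
    u_s *= voxel_volume

    u_inc_det = amplitude * carrier * np.exp(1j * kz_i * z_det)
    u_tot = u_inc_det + u_s

    # Pupil filter and numerical refocus from the detector plane to focus.
    grid = FrequencyGrid.from_config(config)
    P = pupil(grid, config)
    kz = 2.0 * np.pi * axial_frequency(grid, config)
    spec = np.fft.fft2(u_tot) * P * np.exp(-1j * kz * z_det)
    u_focus = np.fft.ifft2(spec)
    return np.abs(u_focus) ** 2


def born_oracle_contrast(
    volume: ComplexVolume | np.ndarray,
    config: OpticalConfig,
    nu_i: np.ndarray,
    amplitude: float = 1.0,
    **kwargs: Any,
) -> np.ndarray:
    """Background-normalised oracle contrast ``(I - I0)/mean(I0)``."""
    values = volume.values if isinstance(volume, ComplexVolume) else np.asarray(volume, dtype=complex)
    I = born_oracle_intensity(values, config, nu_i, amplitude=amplitude, **kwargs)
    I0 = born_oracle_intensity(np.zeros_like(values), config, nu_i, amplitude=amplitude, **kwargs)
    return (I - I0) / I0.mean()


# ---------------------------------------------------------------------------
# Camera model
# ---------------------------------------------------------------------------


def simulate_frames(
    clean_image: np.ndarray,
    photon_budget: float,
    n_repeats: int = 1,
    seed: int | np.random.SeedSequence = 0,
    read_noise_std: float = 0.0,
    frame_offset: int = 0,
) -> np.ndarray:
    """Noisy camera frames from a clean intensity image.

    ``photon_budget`` is the expected photon count for a pixel at the mean
    image level; shot noise is Poisson at that budget and an optional
    Gaussian read noise (in the same normalised intensity units) is added.
    ``photon_budget=inf`` returns exact copies.  Each frame uses a
    deterministic substream derived from ``(seed, frame_offset + index)``,
    so identical indices reproduce identical frames.
    """
    clean = np.asarray(clean_image, dtype=float)
    if np.any(clean < 0):
        raise ValueError("clean image must be non-negative")
    if not photon_budget > 0:
        raise ValueError("photon budget must be positive (or inf)")
    frames = np.empty((n_repeats,) + clean.shape, dtype=float)
    base = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    mean_level = clean.mean() if clean.mean() > 0 else 1.0
    for r in range(n_repeats):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=base.entropy, spawn_key=(frame_offset + r,))
        )
        if np.isinf(photon_budget):
            frame = clean.copy()
        else:
            expected = clean / mean_level * photon_budget
            frame = rng.poisson(expected).astype(float) / photon_budget * mean_level
        if read_noise_std > 0:
            frame = frame + rng.normal(0.0, read_noise_std, size=clean.shape)
        frames[r] = frame
    return frames


@dataclass
class IntensityStack:
    """Raw frames indexed by (source, state, repetition).

    ``frames`` has shape ``(n_sources, 2, n_repeats, ny, nx)`` with the
    state axis ordered as :data:`STATES` (hot, cold).  ``backgrounds``
    carries the per-frame background level used for normalisation.
    """

    frames: np.ndarray
    backgrounds: np.ndarray
    wavenumber: float | None = None
    pump_power: float = 0.0
    timing: Any = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 5 or self.frames.shape[1] != len(STATES):
            raise ValueError("frames must have shape (n_sources, 2, n_repeats, ny, nx)")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")
        self.backgrounds = np.asarray(self.backgrounds, dtype=float)
        if self.backgrounds.shape != self.frames.shape[:3]:
            raise ValueError("backgrounds must have shape (n_sources, 2, n_repeats)")

    @property
    def n_sources(self) -> int:
        return self.frames.shape[0]

    @property
    def n_repeats(self) -> int:
        return self.frames.shape[2]

    def _state_index(self, state: str) -> int:
        if state not in STATES:
            raise ValueError(f"state must be one of {STATES}")
        return STATES.index(state)

    def mean_frames(self, state: str) -> np.ndarray:
        """Repetition-averaged frames for one state, shape (n_sources, ny, nx)."""
        return self.frames[:, self._state_index(state)].mean(axis=1)

    def normalized_contrast(self, state: str) -> np.ndarray:
        """``(mean(I) - bg)/bg`` per source; averaging precedes normalisation."""
        s = self._state_index(state)
        mean_img = self.frames[:, s].mean(axis=1)
        bg = self.backgrounds[:, s].mean(axis=1)
        return (mean_img - bg[:, None, None]) / bg[:, None, None]
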