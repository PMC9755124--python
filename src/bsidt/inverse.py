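"""Slice-wise Tikhonov deconvolution of multi-angle intensity stacks.

For every lateral frequency ``nu`` and slice ``m`` the real and imaginary
permittivity-contrast spectra are recovered from the per-source contrast
spectra ``g_i`` by solving the regularised 2x2 normal equations
accumulated over sources::

    [ sum|H_re|^2 + beta_re      sum H_re* H_im      ] [eps_re^]   [sum H_re* g^]
    [ conj(.)                    sum|H_im|^2 + beta_im] [eps_im^] = [sum H_im* g^]

This closed form decouples slices (each slice is estimated as if it alone
produced the data), which is the established annular-IDT inversion; a
joint solve over all slices is available behind a flag for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .forward import IntensityStack
from .optics import ComplexVolume, OpticalConfig, permittivity_to_ri
from .transfer import TransferFunctionSet

__all__ = [
    "ReconstructionSettings",
    "ChemicalRecord",
    "reconstruct",
    "reconstruct_from_contrast",
    "to_ri_volume",
    "hot_cold_subtract",
    "aperture_support_mask",
    "band_limit_to_support",
]


@dataclass(frozen=True)
class ReconstructionSettings:
    """Tikhonov weights and output options.

    If ``beta_re``/``beta_im`` are None they default to ``beta_fraction``
    times the maximum of the corresponding accumulated TF energy
    ``max over (nu, m) of sum_i |H|^2`` — a scale-free heuristic; no
    L-curve automation is attempted.
    """

    beta_re: float | None = None
    beta_im: float | None = None
    beta_fraction: float = 1e-2
    enforce_real_output: bool = True
    joint_slices: bool = False

    def __post_init__(self) -> None:
        for name in ("beta_re", "beta_im"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.beta_fraction <= 0:
            raise ValueError("beta_fraction must be positive")


@dataclass
class ChemicalRecord:
    """Hot/cold RI volumes, their photothermal difference, and metadata."""

    cold_ri: np.ndarray
    hot_ri: np.ndarray
    delta_ri: np.ndarray
    wavenumber: float | None = None
    pump_power: float = 0.0
    delay_time: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cold_ri = np.asarray(self.cold_ri, dtype=float)
        self.hot_ri = np.asarray(self.hot_ri, dtype=float)
        self.delta_ri = np.asarray(self.delta_ri, dtype=float)
        if not (self.cold_ri.shape == self.hot_ri.shape == self.delta_ri.shape):
            raise ValueError("cold, hot and delta volumes must share a shape")
        if not np.allclose(self.delta_ri, self.hot_ri - self.cold_ri, atol=1e-10):
            raise ValueError("delta_ri must equal hot_ri - cold_ri")


def _resolve_betas(tfs: TransferFunctionSet, settings: ReconstructionSettings) -> tuple[float, float]:
    A = np.sum(np.abs(tfs.H_re) ** 2, axis=0)
    B = np.sum(np.abs(tfs.H_im) ** 2, axis=0)
    beta_re = settings.beta_re if settings.beta_re is not None else settings.beta_fraction * float(A.max())
    beta_im = settings.beta_im if settings.beta_im is not None else settings.beta_fraction * float(B.max())
    return beta_re, beta_im


def reconstruct_from_contrast(
    contrast: np.ndarray,
    tfs: TransferFunctionSet,
    settings: ReconstructionSettings | None = None,
) -> ComplexVolume:
    """Recover ``delta_eps`` from per-source normalised contrast images.

    ``contrast`` has shape ``(n_sources, ny, nx)`` and holds
    ``(I - I_bg)/I_bg`` for each source (repetitions already averaged).
    """
    settings = settings or ReconstructionSettings()
    cfg = tfs.config
    contrast = np.asarray(contrast, dtype=float)
    if contrast.shape != (tfs.n_sources, cfg.ny, cfg.nx):
        raise ValueError(
            f"expected contrast of shape {(tfs.n_sources, cfg.ny, cfg.nx)}, got {contrast.shape}"
        )

    g_hat = np.fft.fft2(contrast, axes=(1, 2))  # (n_src, ny, nx)
    beta_re, beta_im = _resolve_betas(tfs, settings)

    if settings.joint_slices:
        eps_hat = _solve_joint(g_hat, tfs, beta_re, beta_im)
    else:
        eps_hat = _solve_decoupled(g_hat, tfs, beta_re, beta_im)

    eps_re = np.fft.ifft2(eps_hat[0], axes=(1, 2))
    eps_im = np.fft.ifft2(eps_hat[1], axes=(1, 2))
    if settings.enforce_real_output:
        eps_re = eps_re.real
        eps_im = eps_im.real
    values = np.moveaxis(eps_re + 1j * eps_im, 0, -1)  # (ny, nx, nz)
    return ComplexVolume(values=values, role="permittivity")


def _solve_decoupled(
    g_hat: np.ndarray, tfs: TransferFunctionSet, beta_re: float, beta_im: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(nu, m) 2x2 normal equations accumulated over sources."""
    Hre = tfs.H_re  # (n_src, nz, ny, nx)
    Him = tfs.H_im
    A = np.sum(np.abs(Hre) ** 2, axis=0) + beta_re  # (nz, ny, nx)
    B = np.sum(np.abs(Him) ** 2, axis=0) + beta_im
    C = np.sum(np.conj(Hre) * Him, axis=0)
    b1 = np.einsum("smyx,syx->myx", np.conj(Hre), g_hat)
    b2 = np.einsum("smyx,syx->myx", np.conj(Him), g_hat)
    det = A * B - np.abs(C) ** 2
    # beta > 0 makes det >= beta_re*beta_im > 0; guard anyway.
    if np.any(det <= 0):
        raise RuntimeError("singular normal equations despite positive regularization")
    x_re = (B * b1 - C * b2) / det
    x_im = (A * b2 - np.conj(C) * b1) / det
    return x_re, x_im


def _solve_joint(
    g_hat: np.ndarray, tfs: TransferFunctionSet, beta_re: float, beta_im: float
) -> tuple[np.ndarray, np.ndarray]:
    """Joint (2 nz) x (2 nz) Tikhonov solve per lateral frequency.

    Offered for comparison with the slice-decoupled closed form; O(nz)
    more expensive and rarely worth it for the weakly scattering volumes
    this model targets.
    """
    n_src, nz, ny, nx = tfs.H_re.shape
    # Design matrix per frequency: (n_src, 2 nz)
    H = np.concatenate([tfs.H_re, tfs.H_im], axis=1)  # (n_src, 2nz, ny, nx)
    Hc = np.conj(H)
    normal = np.einsum("sayx,sbyx->yxab", Hc, H)  # (ny, nx, 2nz, 2nz)
    reg = np.concatenate([np.full(nz, beta_re), np.full(nz, beta_im)])
    normal += np.diag(reg)[None, None]
    rhs = np.einsum("sayx,syx->yxa", Hc, g_hat)
    sol = np.linalg.solve(normal, rhs[..., None])[..., 0]  # (ny, nx, 2nz)
    x_re = np.moveaxis(sol[..., :nz], -1, 0)
    x_im = np.moveaxis(sol[..., nz:], -1, 0)
    return x_re, x_im


def reconstruct(
    stack: IntensityStack,
    tfs: TransferFunctionSet,
    settings: ReconstructionSettings | None = None,
    state: str = "cold",
) -> ComplexVolume:
    """Reconstruct one state of an acquisition (repetitions are averaged
    before normalisation, matching multi-frame camera averaging)."""
    contrast = stack.normalized_contrast(state)
    return reconstruct_from_contrast(contrast, tfs, settings)


def to_ri_volume(delta_eps: ComplexVolume | np.ndarray, config: OpticalConfig) -> np.ndarray:
    """Absolute real RI volume ``n_m + Re(delta_n)`` from ``delta_eps``."""
    delta_n = permittivity_to_ri(delta_eps, config.medium_ri)
    values = delta_n.values if isinstance(delta_n, ComplexVolume) else delta_n
    return config.medium_ri + values.real


def hot_cold_subtract(
    hot_ri: np.ndarray,
    cold_ri: np.ndarray,
    wavenumber: float | None = None,
    pump_power: float = 0.0,
    delay_time: float | None = None,
    metadata: dict | None = None,
) -> ChemicalRecord:
    """Photothermal difference volume ``hot - cold`` with its metadata."""
    hot_ri = np.asarray(hot_ri, dtype=float)
    cold_ri = np.asarray(cold_ri, dtype=float)
    if hot_ri.shape != cold_ri.shape:
        raise ValueError("hot and cold volumes must share a shape")
    return ChemicalRecord(
        cold_ri=cold_ri,
        hot_ri=hot_ri,
        delta_ri=hot_ri - cold_ri,
        wavenumber=wavenumber,
        pump_power=pump_power,
        delay_time=delay_time,
        metadata=metadata or {},
    )


# ---------------------------------------------------------------------------
# Synthetic-aperture support
# ---------------------------------------------------------------------------


def aperture_support_mask(tfs: TransferFunctionSet, threshold: float = 1e-2) -> np.ndarray:
    """3D frequency support of the measurement operator.

    The slice transfer functions depend on the slice index only through
    axial phase ramps, so their DFT along the slice axis concentrates on
    the Ewald-arc axial frequencies reachable by the illumination.  The
    mask keeps the 3D bins whose accumulated TF energy exceeds
    ``threshold`` times the maximum — the synthetic-aperture support.
    The default 1% cut excludes bins that carry so little transfer
    energy that a regularised inversion cannot recover them.  Requires
    contiguous ascending slice offsets.
    """
    offsets = np.asarray(tfs.config.slice_offsets)
    if not np.all(np.diff(offsets) == 1):
        raise ValueError("aperture support requires contiguous slice offsets")
    # FFT over the slice axis (axis=1 of (n_src, nz, ny, nx)).
    Hre_z = np.fft.fft(tfs.H_re, axis=1)
    Him_z = np.fft.fft(tfs.H_im, axis=1)
    energy = np.sum(np.abs(Hre_z) ** 2 + np.abs(Him_z) ** 2, axis=0)  # (nz, ny, nx)
    return energy > threshold * energy.max()


def band_limit_to_support(volume: np.ndarray, tfs: TransferFunctionSet, threshold: float = 1e-2) -> np.ndarray:
    """Filter a real volume ``(ny, nx, nz)`` to the synthetic-aperture
    support of ``tfs`` (for comparing ground truth with reconstructions)."""
    vol = np.asarray(volume, dtype=float)
    if vol.shape != tfs.config.volume_shape:
        raise ValueError("volume shape does not match config")
    mask = aperture_support_mask(tfs, threshold)  # (nz, ny, nx)
    spec = np.fft.fftn(np.moveaxis(vol, -1, 0))  # (nz, ny, nx)
    return np.moveaxis(np.fft.ifftn(spec * mask).real, 0, -1)
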