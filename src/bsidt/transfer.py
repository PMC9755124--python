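"""Weak-object transfer functions for the slice-based scattering model.

For every oblique source ``nu_i`` and axial slice ``m`` the model maps the
slice's real and imaginary permittivity-contrast spectra into the
background-normalised intensity spectrum through a pair of transfer
functions::

    H_re(nu, m | nu_i) =  (j k0^2 dz / 2) A(nu_i) P(nu_i)
        [ P(nu+nu_i) exp(-j (kz(nu+nu_i)-kz(nu_i)) m dz) / kz(nu+nu_i)
        - P(nu-nu_i) exp(+j (kz(nu-nu_i)-kz(nu_i)) m dz) / kz(nu-nu_i) ]

    H_im(nu, m | nu_i) = -(k0^2 dz / 2) A(nu_i) P(nu_i)
        [ same bracket with a plus sign between the terms ]

with ``k0`` the vacuum angular wavenumber, ``kz = 2 pi eta`` the angular
axial wavenumber at the in-medium wavelength, ``P`` the binary pupil and
``A`` the source amplitude.  The vacuum ``k0^2`` in the prefactor scales
the scattering potential; propagation (``kz``) happens in the medium.
Writing the axial wavenumber in angular units keeps the transfer functions
quantitatively consistent with the first-Born Green's-function field model
(see :mod:`bsidt.forward`), and reduces to the familiar thin-object phase
contrast in the in-focus limit.

Sign convention: the analysis Fourier transform is ``exp(-j 2 pi nu x)``
(numpy's forward FFT) and the incident plane wave of source ``i`` is
``exp(+j 2 pi (nu_i . rho + eta_i z))``.  Mirroring every ``nu_i`` yields
the same family of transfer functions with the bracket terms exchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import (
    FrequencyGrid,
    OpticalConfig,
    axial_frequency,
    axial_frequency_at,
    pupil,
    pupil_contains,
)

__all__ = [
    "IlluminationSet",
    "TransferFunctionSet",
    "compute_tfs",
    "synthetic_bandwidth",
    "ETA_FLOOR_FACTOR",
]

#: The band-edge regularisation floor: 1/kz diverges where a shifted pupil
#: touches the propagation band edge, so eta is clamped from below at
#: ``ETA_FLOOR_FACTOR / lambda_medium`` inside pupil supports.  This only
#: ever affects the outermost frequency ring.
ETA_FLOOR_FACTOR = 1e-3


@dataclass(frozen=True)
class IlluminationSet:
    """Oblique plane-wave sources: lateral frequencies and amplitudes."""

    nu: np.ndarray  # (n_sources, 2) lateral frequency vectors, cycles/µm
    amplitudes: np.ndarray  # (n_sources,) strictly positive

    def __post_init__(self) -> None:
        nu = np.atleast_2d(np.asarray(self.nu, dtype=float))
        amp = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if nu.ndim != 2 or nu.shape[1] != 2:
            raise ValueError("nu must be an (n, 2) array")
        if amp.shape[0] != nu.shape[0]:
            raise ValueError("amplitudes must match the number of sources")
        if nu.shape[0] == 0:
            raise ValueError("illumination set must contain at least one source")
        if np.any(amp <= 0):
            raise ValueError("source amplitudes must be strictly positive")
        object.__setattr__(self, "nu", nu)
        object.__setattr__(self, "amplitudes", amp)

    @property
    def count(self) -> int:
        return self.nu.shape[0]

    @classmethod
    def ring(
        cls,
        config: OpticalConfig,
        n_sources: int = 16,
        na_fraction: float = 1.0,
        phase: float = 0.0,
        snap_to_grid: bool = False,
    ) -> "IlluminationSet":
        """NA-matched annular illumination: ``n_sources`` plane waves at
        ``|nu_i| = na_fraction * NA / lambda_vac``, equally spaced in angle.

        With ``snap_to_grid`` every source frequency is rounded to the
        nearest DFT bin of the configured grid (staying inside the pupil),
        which makes the plane-wave carriers exactly periodic on the
        simulation window — required when comparing against the
        spatial-domain Born oracle on a finite grid.
        """
        if n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        radius = na_fraction * config.pupil_cutoff
        angles = phase + 2.0 * np.pi * np.arange(n_sources) / n_sources
        nu = np.stack([radius * np.cos(angles), radius * np.sin(angles)], axis=1)
        if snap_to_grid:
            nu = np.stack([_snap_inside_pupil(v, config) for v in nu], axis=0)
        return cls(nu=nu, amplitudes=np.ones(n_sources))


def _snap_inside_pupil(nu_vec: np.ndarray, config: OpticalConfig) -> np.ndarray:
    """Round a frequency vector to the DFT grid without leaving the pupil."""
    dvx = 1.0 / (config.nx * config.pixel_size)
    dvy = 1.0 / (config.ny * config.pixel_size)
    cx = nu_vec[0] / dvx
    cy = nu_vec[1] / dvy
    candidates = []
    for fx in (np.floor(cx), np.ceil(cx)):
        for fy in (np.floor(cy), np.ceil(cy)):
            cand = np.array([fx * dvx, fy * dvy])
            if pupil_contains(cand, config):
                candidates.append(cand)
    if not candidates:
        raise ValueError("cannot snap source frequency onto the grid inside the pupil")
    dists = [np.hypot(*(c - nu_vec)) for c in candidates]
    return candidates[int(np.argmin(dists))]


@dataclass
class TransferFunctionSet:
    """``H_re``/``H_im`` stacks indexed by (source, slice, ny, nx)."""

    H_re: np.ndarray
    H_im: np.ndarray
    config: OpticalConfig
    illumination: IlluminationSet

    def __post_init__(self) -> None:
        expected = (self.illumination.count, self.config.nz, self.config.ny, self.config.nx)
        if self.H_re.shape != expected or self.H_im.shape != expected:
            raise ValueError(f"transfer function arrays must have shape {expected}")
        if not (np.all(np.isfinite(self.H_re)) and np.all(np.isfinite(self.H_im))):
            raise ValueError("transfer functions must be finite everywhere")

    @property
    def n_sources(self) -> int:
        return self.H_re.shape[0]

    def support(self) -> np.ndarray:
        """Boolean (ny, nx) union of the shifted-pupil supports."""
        return (np.abs(self.H_re).sum(axis=(0, 1)) + np.abs(self.H_im).sum(axis=(0, 1))) > 0


def compute_tfs(config: OpticalConfig, illum: IlluminationSet) -> TransferFunctionSet:
    """Evaluate the slice transfer functions for every source and slice."""
    grid = FrequencyGrid.from_config(config)
    dz = config.slice_thickness
    k0 = config.k_vacuum
    kz_floor = 2.0 * np.pi * ETA_FLOOR_FACTOR / config.wavelength_medium

    n_src = illum.count
    nz = config.nz
    H_re = np.zeros((n_src, nz, config.ny, config.nx), dtype=complex)
    H_im = np.zeros_like(H_re)

    for i in range(n_src):
        nu_i = illum.nu[i]
        if not pupil_contains(nu_i, config):
            raise ValueError(
                f"source {i} at nu={tuple(nu_i)} lies outside the pupil "
                f"(cutoff {config.pupil_cutoff:.4f} cycles/µm)"
            )
        amp = illum.amplitudes[i]
        eta_i = axial_frequency_at(nu_i, config)
        if eta_i <= 0:
            raise ValueError(f"source {i} is evanescent, which contradicts NA < n_m")
        kz_i = 2.0 * np.pi * eta_i

        P_plus = pupil(grid, config, shift=(-nu_i[0], -nu_i[1]))  # P(nu + nu_i)
        P_minus = pupil(grid, config, shift=(nu_i[0], nu_i[1]))  # P(nu - nu_i)
        eta_plus = axial_frequency(grid, config, shift=(-nu_i[0], -nu_i[1]))
        eta_minus = axial_frequency(grid, config, shift=(nu_i[0], nu_i[1]))

        for sign, P_sh, eta_sh in ((+1, P_plus, eta_plus), (-1, P_minus, eta_minus)):
            if np.any((P_sh > 0) & (eta_sh <= 0)):
                raise RuntimeError(
                    "internal contradiction: evanescent frequency inside a shifted pupil "
                    "(requires 2*NA >= medium RI)"
                )

        kz_plus = np.maximum(2.0 * np.pi * eta_plus, kz_floor)
        kz_minus = np.maximum(2.0 * np.pi * eta_minus, kz_floor)

        prefac = amp  # P(nu_i) == 1 was just checked
        for mi, m in enumerate(config.slice_offsets):
            z_m = m * dz
            term_plus = P_plus * np.exp(-1j * (kz_plus - kz_i) * z_m) / kz_plus
            term_minus = P_minus * np.exp(+1j * (kz_minus - kz_i) * z_m) / kz_minus
            H_re[i, mi] = (1j * k0**2 * dz / 2.0) * prefac * (term_plus - term_minus)
            H_im[i, mi] = (-(k0**2) * dz / 2.0) * prefac * (term_plus + term_minus)

    return TransferFunctionSet(H_re=H_re, H_im=H_im, config=config, illumination=illum)


def synthetic_bandwidth(illum: IlluminationSet, config: OpticalConfig) -> float:
    """Largest accessible lateral frequency ``max_i |nu_i| + NA/lambda``.

    For the NA-matched ring this is the incoherent limit
    ``2 NA / lambda_vac``.
    """
    radii = np.hypot(illum.nu[:, 0], illum.nu[:, 1])
    return float(np.max(radii) + config.pupil_cutoff)
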