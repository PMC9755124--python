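"""Shared optical primitives.

Coordinate and unit conventions used throughout the package:

* lengths in micrometres (µm), spatial frequencies in cycles/µm,
  wavenumbers of the mid-IR pump in cm^-1;
* images are ``(ny, nx)`` arrays, volumes are ``(ny, nx, nz)`` with the
  axial index running over the configured slice offsets;
* the lateral frequency grid follows the standard DFT layout
  (``numpy.fft.fftfreq``), and every complex exponential written in
  cycles carries an explicit 2*pi;
* angular wavenumbers (rad/µm) are used inside the scattering model:
  ``k_vacuum = 2*pi/lambda_vac`` scales the scattering potential while
  propagation happens at the in-medium wavelength ``lambda_vac/n_m``.

The object is described by its complex permittivity contrast
``delta_eps = eps_object - n_m**2`` against the immersion medium; the
exact conversion to refractive-index contrast is
``delta_n = sqrt(n_m**2 + delta_eps) - n_m`` (principal branch), which
linearises to ``delta_eps ~ 2 n_m delta_n`` for weak objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

__all__ = [
    "OpticalConfig",
    "FrequencyGrid",
    "ComplexVolume",
    "EVANESCENT_SENTINEL",
    "axial_frequency",
    "evanescent_mask",
    "pupil",
    "permittivity_to_ri",
    "ri_to_permittivity",
]

#: Value stored in the axial-frequency grid wherever the lateral frequency
#: exceeds 1/lambda_medium (evanescent waves, excluded from all transfer
#: function supports).  Zero is safe because every consumer masks by the
#: pupil first and the in-band axial frequency is clamped away from zero.
EVANESCENT_SENTINEL = 0.0

#: Relative tolerance for the inclusive pupil boundary.  Sources placed
#: exactly on the NA-matched ring must pass the pupil test despite
#: floating-point rounding of hypot().
_PUPIL_RTOL = 1e-9


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry and wavelength of the probe arm.

    Parameters
    ----------
    probe_wavelength_vacuum:
        Vacuum wavelength of the visible probe, µm (0.450 for the blue
        diode ring).
    medium_ri:
        Refractive index of the immersion medium (D2O-based PBS ~ water).
    objective_na:
        Numerical aperture of the collection objective.
    pixel_size:
        Object-space pixel pitch, µm (camera pixel / magnification).
    nx, ny:
        Lateral grid size of the camera frames and of every slice.
    slice_thickness:
        Axial sampling step ``dz`` of the slice stack, µm.
    slice_offsets:
        Signed integer slice indices ``m``; slice ``m`` sits at
        ``z = m * slice_thickness`` relative to the focal plane.
    """

    probe_wavelength_vacuum: float = 0.450
    medium_ri: float = 1.333
    objective_na: float = 0.65
    pixel_size: float = 0.1625
    nx: int = 64
    ny: int = 64
    slice_thickness: float = 0.30
    slice_offsets: tuple[int, ...] = tuple(range(-7, 8))

    def __post_init__(self) -> None:
        object.__setattr__(self, "slice_offsets", tuple(int(m) for m in self.slice_offsets))
        if self.probe_wavelength_vacuum <= 0:
            raise ValueError("probe_wavelength_vacuum must be positive")
        if self.medium_ri <= 0:
            raise ValueError("medium_ri must be positive")
        if not 0 < self.objective_na < self.medium_ri:
            raise ValueError(
                f"objective_na must satisfy 0 < NA < medium_ri, got NA={self.objective_na}, "
                f"n_m={self.medium_ri}"
            )
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")
        if len(self.slice_offsets) == 0:
            raise ValueError("slice_offsets must be non-empty")
        # Nyquist for the synthetic-aperture band 2 NA / lambda.
        nyquist = 1.0 / (2.0 * self.synthetic_cutoff)
        if self.pixel_size > nyquist * (1 + 1e-12):
            raise ValueError(
                f"pixel_size {self.pixel_size} µm undersamples the synthetic aperture; "
                f"need <= {nyquist:.4f} µm"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def nz(self) -> int:
        return len(self.slice_offsets)

    @property
    def wavelength_medium(self) -> float:
        """Probe wavelength inside the immersion medium, µm."""
        return self.probe_wavelength_vacuum / self.medium_ri

    @property
    def k_vacuum(self) -> float:
        """Vacuum angular wavenumber 2*pi/lambda_vac, rad/µm."""
        return 2.0 * np.pi / self.probe_wavelength_vacuum

    @property
    def k_medium(self) -> float:
        """In-medium angular wavenumber 2*pi*n_m/lambda_vac, rad/µm."""
        return 2.0 * np.pi * self.medium_ri / self.probe_wavelength_vacuum

    @property
    def pupil_cutoff(self) -> float:
        """Lateral frequency radius of the pupil NA/lambda_vac, cycles/µm."""
        return self.objective_na / self.probe_wavelength_vacuum

    @property
    def synthetic_cutoff(self) -> float:
        """Synthetic-aperture band limit 2 NA / lambda_vac, cycles/µm."""
        return 2.0 * self.objective_na / self.probe_wavelength_vacuum

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return (self.ny, self.nx, self.nz)

    @property
    def z_positions(self) -> np.ndarray:
        """Axial slice positions ``m * dz`` in µm."""
        return np.asarray(self.slice_offsets, dtype=float) * self.slice_thickness

    def lateral_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Centered physical pixel coordinates ``(x, y)`` in µm (1D each)."""
        x = (np.arange(self.nx) - self.nx // 2) * self.pixel_size
        y = (np.arange(self.ny) - self.ny // 2) * self.pixel_size
        return x, y

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["slice_offsets"] = list(self.slice_offsets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        d = dict(d)
        d["slice_offsets"] = tuple(d["slice_offsets"])
        return cls(**d)


@dataclass(frozen=True)
class FrequencyGrid:
    """Lateral spatial-frequency grid (cycles/µm) in DFT order."""

    nu_x: np.ndarray
    nu_y: np.ndarray

    def __post_init__(self) -> None:
        if self.nu_x.shape != self.nu_y.shape:
            raise ValueError("nu_x and nu_y must share a shape")

    @classmethod
    def from_config(cls, config: OpticalConfig) -> "FrequencyGrid":
        fx = np.fft.fftfreq(config.nx, d=config.pixel_size)
        fy = np.fft.fftfreq(config.ny, d=config.pixel_size)
        nu_x, nu_y = np.meshgrid(fx, fy)
        return cls(nu_x=nu_x, nu_y=nu_y)

    @property
    def shape(self) -> tuple[int, int]:
        return self.nu_x.shape

    def radius(self, shift: tuple[float, float] | None = None) -> np.ndarray:
        """``|nu - shift|`` on the grid (shift given as ``(nu_x, nu_y)``)."""
        if shift is None:
            return np.hypot(self.nu_x, self.nu_y)
        return np.hypot(self.nu_x - shift[0], self.nu_y - shift[1])


@dataclass
class ComplexVolume:
    """A complex 3D field on the slice grid, tagged by physical meaning.

    ``role`` is either ``"permittivity"`` (values are ``delta_eps``) or
    ``"ri"`` (values are complex refractive-index contrast ``delta_n``).
    """

    values: np.ndarray
    role: str = "permittivity"

    _ROLES = ("permittivity", "ri")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 3:
            raise ValueError("ComplexVolume expects a 3D (ny, nx, nz) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ComplexVolume values must be finite")
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {self._ROLES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def _eta_from_radius_sq(r_sq: np.ndarray | float, config: OpticalConfig) -> np.ndarray:
    inv_lam_sq = (1.0 / config.wavelength_medium) ** 2
    arg = inv_lam_sq - np.asarray(r_sq, dtype=float)
    eta = np.sqrt(np.clip(arg, 0.0, None))
    return np.where(arg > 0.0, eta, EVANESCENT_SENTINEL)


def axial_frequency(
    nu: FrequencyGrid,
    config: OpticalConfig,
    shift: tuple[float, float] | None = None,
) -> np.ndarray:
    """Axial spatial frequency ``eta(nu) = sqrt(lambda_med**-2 - |nu|**2)``.

    ``lambda_med`` is the in-medium probe wavelength.  Entries with
    ``|nu| >= 1/lambda_med`` are evanescent and are set to
    :data:`EVANESCENT_SENTINEL`; they never propagate into a transfer
    function because they lie outside every pupil support for NA < n_m.

    ``shift`` evaluates ``eta(nu - shift)`` on the same grid, which is how
    the shifted-pupil terms of the transfer functions are sampled.
    """
    r = nu.radius(shift)
    return _eta_from_radius_sq(r * r, config)


def axial_frequency_at(nu_vec: Iterable[float], config: OpticalConfig) -> float:
    """``eta`` for a single lateral frequency vector (cycles/µm)."""
    vx, vy = nu_vec
    val = _eta_from_radius_sq(np.asarray(vx * vx + vy * vy), config)
    return float(val)


def evanescent_mask(
    nu: FrequencyGrid,
    config: OpticalConfig,
    shift: tuple[float, float] | None = None,
) -> np.ndarray:
    """Boolean grid, True where the (shifted) frequency is evanescent."""
    r = nu.radius(shift)
    return r >= 1.0 / config.wavelength_medium


def pupil(
    nu: FrequencyGrid,
    config: OpticalConfig,
    shift: tuple[float, float] | None = None,
) -> np.ndarray:
    """Binary circular pupil ``P(nu - shift)``, inclusive at the NA cutoff.

    The boundary is kept (ties at exactly NA/lambda count as inside, with a
    1e-9 relative tolerance) so that NA-matched ring sources pass their own
    pupil test.
    """
    r = nu.radius(shift)
    cutoff = config.pupil_cutoff
    return (r <= cutoff * (1.0 + _PUPIL_RTOL)).astype(float)


def pupil_contains(nu_vec: Iterable[float], config: OpticalConfig) -> bool:
    vx, vy = nu_vec
    return bool(np.hypot(vx, vy) <= config.pupil_cutoff * (1.0 + _PUPIL_RTOL))


def permittivity_to_ri(delta_eps: ComplexVolume | np.ndarray, medium_ri: float) -> ComplexVolume:
    """Exact conversion of permittivity contrast to complex RI contrast.

    ``n = sqrt(n_m**2 + delta_eps)`` (principal branch), returned as the
    contrast ``delta_n = n - n_m``.  Raises on non-physical input where
    ``n_m**2 + Re(delta_eps) <= 0``.
    """
    values = delta_eps.values if isinstance(delta_eps, ComplexVolume) else np.asarray(delta_eps, dtype=complex)
    radicand = medium_ri**2 + values
    bad = np.count_nonzero(radicand.real <= 0.0)
    if bad:
        raise ValueError(
            f"non-physical permittivity contrast: n_m^2 + Re(delta_eps) <= 0 at {bad} voxel(s)"
        )
    delta_n = np.sqrt(radicand) - medium_ri
    if isinstance(delta_eps, ComplexVolume):
        return ComplexVolume(values=delta_n, role="ri")
    return delta_n  # type: ignore[return-value]


def ri_to_permittivity(delta_n: ComplexVolume | np.ndarray, medium_ri: float) -> ComplexVolume:
    """Exact inverse of :func:`permittivity_to_ri`:
    ``delta_eps = (n_m + delta_n)**2 - n_m**2``."""
    values = delta_n.values if isinstance(delta_n, ComplexVolume) else np.asarray(delta_n, dtype=complex)
    delta_eps = (medium_ri + values) ** 2 - medium_ri**2
    if isinstance(delta_n, ComplexVolume):
        return ComplexVolume(values=delta_eps, role="permittivity")
    return delta_eps  # type: ignore[return-value]
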