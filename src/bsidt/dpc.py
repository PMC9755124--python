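"""2D differential-phase-contrast (DPC) reconstruction from ring subsets.

The comparison method: instead of the 3D slice model, the object is
treated as a single thin complex transmittance and its phase recovered
from a handful of asymmetric illumination groups.  For a weak thin object
under one oblique coherent plane wave the normalised intensity spectrum is

    g^(nu) = -j [P(nu - nu_i) - P(nu + nu_i)] phi^(nu)  -  [P- + P+] mu^(nu)

so a source group's phase transfer function is the antisymmetric pupil
difference summed over its members (scaled by -j, the documented
constant).  An optional oblique-path factor ``k_m / kz(nu_i)`` accounts
for the longer geometric path of a tilted beam through the slab, which
calibrates the recovered phase against the volumetric model for the
NA-matched ring.

Phase is recovered by Tikhonov least squares over the groups; absorption
recovery is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .optics import FrequencyGrid, OpticalConfig, axial_frequency_at, pupil
from .transfer import IlluminationSet

__all__ = [
    "DpcPatternSet",
    "dpc_phase_tf",
    "dpc_reconstruct",
    "dpc_hot_cold",
    "pattern_contrast_images",
]


@dataclass(frozen=True)
class DpcPatternSet:
    """Groups of source indices used as DPC illumination patterns."""

    patterns: tuple[tuple[int, ...], ...]
    regularization: float = 1e-2

    def __post_init__(self) -> None:
        if len(self.patterns) == 0:
            raise ValueError("need at least one pattern")
        pats = tuple(tuple(int(i) for i in p) for p in self.patterns)
        if any(len(p) == 0 for p in pats):
            raise ValueError("patterns must be non-empty")
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")
        object.__setattr__(self, "patterns", pats)

    @classmethod
    def cardinal(cls, illum: IlluminationSet, regularization: float = 1e-2) -> "DpcPatternSet":
        """Four 90-degree arcs of the ring (right, top, left, bottom)."""
        angles = np.mod(np.arctan2(illum.nu[:, 1], illum.nu[:, 0]), 2 * np.pi)
        patterns: list[list[int]] = [[], [], [], []]
        for i, a in enumerate(angles):
            quadrant = int(np.floor(((a + np.pi / 4) % (2 * np.pi)) / (np.pi / 2)))
            patterns[quadrant].append(i)
        if any(len(p) == 0 for p in patterns):
            raise ValueError("ring does not cover all four cardinal arcs")
        return cls(patterns=tuple(tuple(p) for p in patterns), regularization=regularization)


def dpc_phase_tf(
    pattern: Sequence[int],
    illum: IlluminationSet,
    config: OpticalConfig,
    oblique_path_correction: bool = True,
) -> np.ndarray:
    """Phase transfer function of one source group (complex 2D grid).

    Antisymmetric under ``nu -> -nu`` and zero at DC (DPC is blind to the
    mean phase).  The group's member contrasts are averaged, so the TF is
    the mean over member sources.
    """
    if len(pattern) == 0:
        raise ValueError("empty pattern")
    grid = FrequencyGrid.from_config(config)
    tf = np.zeros(grid.shape, dtype=complex)
    for i in pattern:
        nu_i = illum.nu[i]
        amp = illum.amplitudes[i]
        P_minus = pupil(grid, config, shift=(nu_i[0], nu_i[1]))  # P(nu - nu_i)
        P_plus = pupil(grid, config, shift=(-nu_i[0], -nu_i[1]))  # P(nu + nu_i)
        obliquity = 1.0
        if oblique_path_correction:
            eta_i = axial_frequency_at(nu_i, config)
            obliquity = (1.0 / config.wavelength_medium) / eta_i
        tf += -1j * amp * obliquity * (P_minus - P_plus)
    return tf / len(pattern)


def pattern_contrast_images(contrast: np.ndarray, patterns: DpcPatternSet) -> np.ndarray:
    """Average per-source normalised contrasts into per-pattern images."""
    contrast = np.asarray(contrast, dtype=float)
    return np.stack([contrast[list(p)].mean(axis=0) for p in patterns.patterns], axis=0)


def dpc_reconstruct(
    images: np.ndarray,
    patterns: DpcPatternSet,
    illum: IlluminationSet,
    config: OpticalConfig,
    oblique_path_correction: bool = True,
) -> np.ndarray:
    """Tikhonov phase retrieval (radians) from per-pattern contrast images.

    ``images`` has shape ``(n_patterns, ny, nx)`` and holds normalised
    contrast ``(I - I_bg)/I_bg`` averaged within each group.  A single
    shared regularisation weight (relative to the peak TF energy) is used
    across patterns.
    """
    images = np.asarray(images, dtype=float)
    if images.shape[0] != len(patterns.patterns):
        raise ValueError("one image per pattern required")
    tfs = np.stack(
        [dpc_phase_tf(p, illum, config, oblique_path_correction) for p in patterns.patterns],
        axis=0,
    )
    g_hat = np.fft.fft2(images, axes=(1, 2))
    denom = np.sum(np.abs(tfs) ** 2, axis=0)
    reg = patterns.regularization * float(denom.max())
    phi_hat = np.sum(np.conj(tfs) * g_hat, axis=0) / (denom + reg)
    return np.fft.ifft2(phi_hat).real


def dpc_hot_cold(hot_phase: np.ndarray, cold_phase: np.ndarray) -> np.ndarray:
    """Chemical phase difference map (radians)."""
    hot_phase = np.asarray(hot_phase, dtype=float)
    cold_phase = np.asarray(cold_phase, dtype=float)
    if hot_phase.shape != cold_phase.shape:
        raise ValueError("phase maps must share a shape")
    return hot_phase - cold_phase
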