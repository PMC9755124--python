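"""Gaussian blending of chemical volumes acquired at scanned IR positions.

The probe FOV is fixed; only the focused mid-IR pump spot (a Gaussian of
~63 µm FWHM) moves between acquisitions, so each per-position chemical
volume carries the pump's Gaussian dose profile.  A red guide-star image
taken along the pump path marks each spot centre.  Stitching weights each
tile by a unity-peak Gaussian mask at its guide-star centroid, sums the
weighted tiles and normalises by the summed masks.  Because the tiles are
themselves Gaussian-weighted by the physical pump dose, the normalised
blend is trustworthy only where the combined mask coverage is close to
its peak — the result carries an explicit reliability mask.

Spectra should always be extracted from individual tiles, never from a
blended volume, to keep the quantitative dRI scale intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_IR_FWHM",
    "Tile",
    "BlendResult",
    "guide_star_centroid",
    "gaussian_mask",
    "blend",
    "stitch_tiles",
]

#: Default FWHM of the focused mid-IR pump spot, µm.
DEFAULT_IR_FWHM = 63.0

#: Floor for the mask-sum denominator (masks are unity-peak).
MASK_SUM_FLOOR = 1e-3

#: A voxel counts as well-covered when the residual dose bias of the
#: blend is above this value.  Tiles are physically weighted by the pump
#: Gaussian, and the mask-weighted normalised sum recovers the local
#: signal times ``sum(m^2)/sum(m)`` (<= 1); that factor is computable
#: from the masks alone and is the reliability criterion.
COVERAGE_FRACTION = 0.9


@dataclass
class Tile:
    """One scanned-IR acquisition: chemical volume + guide-star image."""

    delta_ri: np.ndarray  # (ny, nx, nz)
    guide_star: np.ndarray  # (ny, nx)
    ir_fwhm: float = DEFAULT_IR_FWHM

    def __post_init__(self) -> None:
        self.delta_ri = np.asarray(self.delta_ri, dtype=float)
        self.guide_star = np.asarray(self.guide_star, dtype=float)
        if self.delta_ri.ndim != 3:
            raise ValueError("delta_ri must be a 3D volume")
        if self.guide_star.shape != self.delta_ri.shape[:2]:
            raise ValueError("guide star image must match the lateral volume shape")
        if self.ir_fwhm <= 0:
            raise ValueError("ir_fwhm must be positive")


def guide_star_centroid(image: np.ndarray, rel_threshold: float = 0.2) -> tuple[float, float]:
    """Sub-pixel ``(x, y)`` centroid of the guide-star spot, in pixels.

    The median is subtracted as background; pixels above
    ``rel_threshold * max`` of the residual are intensity-weighted.
    """
    image = np.asarray(image, dtype=float)
    signal = image - np.median(image)
    peak = signal.max()
    if peak <= 0:
        raise ValueError("guide star image has no signal above background")
    weights = np.where(signal >= rel_threshold * peak, signal, 0.0)
    total = weights.sum()
    ys, xs = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
    return float((xs * weights).sum() / total), float((ys * weights).sum() / total)


def gaussian_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    fwhm: float,
    pixel_size: float = 1.0,
) -> np.ndarray:
    """Unity-peak 2D Gaussian ``exp(-r^2 / (2 sigma^2))``.

    ``center`` is ``(x, y)`` in pixels, ``fwhm`` in the same physical
    units as ``pixel_size``; ``sigma = fwhm / (2 sqrt(2 ln 2))``.  The
    analytic peak value is exactly 1 at the (possibly sub-pixel) centre.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    r_sq = ((xs - center[0]) * pixel_size) ** 2 + ((ys - center[1]) * pixel_size) ** 2
    return np.exp(-r_sq / (2.0 * sigma**2))


@dataclass
class BlendResult:
    stitched: np.ndarray  # (ny, nx, nz)
    coverage: np.ndarray  # (ny, nx) summed masks
    reliable: np.ndarray  # (ny, nx) boolean well-covered flag


def blend(
    volumes: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    floor: float = MASK_SUM_FLOOR,
    coverage_fraction: float = COVERAGE_FRACTION,
) -> BlendResult:
    """Mask-weighted sum of tiles normalised by the summed masks.

    Each 2D mask applies laterally across all slices of its tile.  The
    result is invariant to rescaling all masks by a common positive
    constant.  Because each tile's chemical signal is physically weighted
    by the same Gaussian pump dose that the mask models, the blend
    recovers the local signal times ``sum(m_i^2)/sum(m_i)``; voxels where
    that dose-fidelity factor falls below ``coverage_fraction`` (or where
    the summed masks vanish) are flagged unreliable.
    """
    if len(volumes) == 0:
        raise ValueError("empty tile set")
    if len(volumes) != len(masks):
        raise ValueError("need one mask per volume")
    shape = np.asarray(volumes[0]).shape
    num = np.zeros(shape, dtype=float)
    den = np.zeros(shape[:2], dtype=float)
    den_sq = np.zeros(shape[:2], dtype=float)
    for vol, mask in zip(volumes, masks):
        vol = np.asarray(vol, dtype=float)
        mask = np.asarray(mask, dtype=float)
        if vol.shape != shape:
            raise ValueError("all tiles must share a grid")
        if mask.shape != shape[:2]:
            raise ValueError("masks must match the lateral grid")
        num += vol * mask[:, :, None]
        den += mask
        den_sq += mask**2
    scale = den.max()
    stitched = num / np.maximum(den, floor * scale)[:, :, None]
    # normalise to unity-peak masks so the flag is invariant to a common
    # rescaling of all masks
    peak = max(float(np.max(m)) for m in masks)
    dose_fidelity = den_sq / np.maximum(den, floor * scale) / peak
    reliable = (dose_fidelity >= coverage_fraction) & (den >= floor * scale)
    return BlendResult(stitched=stitched, coverage=den, reliable=reliable)


def stitch_tiles(
    tiles: Sequence[Tile],
    pixel_size: float = 1.0,
    floor: float = MASK_SUM_FLOOR,
    coverage_fraction: float = COVERAGE_FRACTION,
) -> BlendResult:
    """Full pipeline: centroid each guide star, build the unity-peak
    Gaussian masks at the measured IR FWHM, and blend."""
    if len(tiles) == 0:
        raise ValueError("empty tile set")
    masks = []
    for tile in tiles:
        center = guide_star_centroid(tile.guide_star)
        masks.append(
            gaussian_mask(tile.guide_star.shape, center, tile.ir_fwhm, pixel_size=pixel_size)
        )
    return blend([t.delta_ri for t in tiles], masks, floor=floor, coverage_fraction=coverage_fraction)
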