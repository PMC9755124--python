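"""Ground-truth phantoms and the full synthetic acquisition pipeline.

Everything the imaging pipeline consumes can be generated here from
first principles: weakly scattering RI phantoms with per-species
concentration maps, the pump-probe frame schedule with its strict
hot/cold alternation, and complete simulated acquisitions (per source,
state, repetition, wavenumber and scanned-IR tile) with reproducible
noise.  Every synthetic dataset keeps its ground truth alongside so
parameter recovery can be scored automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .forward import STATES, IntensityStack, predict_intensity, simulate_frames
from .inverse import ChemicalRecord, ReconstructionSettings, reconstruct, to_ri_volume, hot_cold_subtract
from .optics import ComplexVolume, OpticalConfig, ri_to_permittivity
from .photothermal import PumpProbeTiming, SpeciesLibrary, mip_delta_n
from .stitching import DEFAULT_IR_FWHM, Tile, gaussian_mask
from .transfer import IlluminationSet, TransferFunctionSet, compute_tfs

__all__ = [
    "Bead",
    "Phantom",
    "FrameSlot",
    "make_bead_phantom",
    "make_cell_phantom",
    "timing_schedule",
    "simulate_stack",
    "acquire_chemical_record",
    "simulate_tiles",
]

#: Weak-scattering guard for default phantoms.
MAX_WEAK_DELTA_N = 5e-3


class Bead(NamedTuple):
    """A spherical inclusion: centre (x, y, z) in µm relative to the
    volume centre/focal plane, radius in µm, RI contrast, species tag."""

    center: tuple[float, float, float]
    radius: float
    delta_n: float
    species: str = "lipid"


@dataclass
class Phantom:
    """Ground truth: cold RI contrast plus per-species concentration maps."""

    delta_n_cold: np.ndarray  # real (ny, nx, nz)
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delta_n_cold = np.asarray(self.delta_n_cold, dtype=float)
        if self.delta_n_cold.ndim != 3:
            raise ValueError("delta_n_cold must be a 3D volume")
        for name, c in self.concentrations.items():
            c = np.asarray(c, dtype=float)
            if c.shape != self.delta_n_cold.shape:
                raise ValueError(f"concentration map {name!r} must match the volume shape")
            if np.any(c < 0):
                raise ValueError(f"concentration map {name!r} must be non-negative")
            self.concentrations[name] = c

    def delta_eps(self, config: OpticalConfig, extra_delta_n: np.ndarray | None = None) -> ComplexVolume:
        """Exact permittivity contrast of the cold (or perturbed) phantom."""
        dn = self.delta_n_cold if extra_delta_n is None else self.delta_n_cold + extra_delta_n
        return ri_to_permittivity(ComplexVolume(values=dn.astype(complex), role="ri"), config.medium_ri)


def _voxel_center_grids(config: OpticalConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x, y = config.lateral_coords()
    z = config.z_positions
    X, Y, Z = np.meshgrid(x, y, z, indexing="xy")  # shapes (ny, nx, nz)
    return X, Y, Z


def make_bead_phantom(
    config: OpticalConfig,
    beads: Sequence[Bead],
    anti_alias: bool = True,
) -> Phantom:
    """Rasterised spheres on the slice grid; deterministic.

    With ``anti_alias`` the bead edge is linearly feathered over one
    lateral pixel; overlapping beads take the maximum contrast (rule:
    inclusions do not add).
    """
    X, Y, Z = _voxel_center_grids(config)
    dn = np.zeros(config.volume_shape, dtype=float)
    conc: dict[str, np.ndarray] = {}
    half_x = config.nx * config.pixel_size / 2
    half_y = config.ny * config.pixel_size / 2
    tol = 1e-9 * config.slice_thickness
    z_lo, z_hi = config.z_positions.min() - tol, config.z_positions.max() + tol
    for bead in beads:
        cx, cy, cz = bead.center
        if abs(cx) > half_x or abs(cy) > half_y or not z_lo <= cz <= z_hi:
            raise ValueError(f"bead at {bead.center} lies outside the grid")
        r = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
        if anti_alias:
            occupancy = np.clip(0.5 + (bead.radius - r) / config.pixel_size, 0.0, 1.0)
        else:
            occupancy = (r <= bead.radius).astype(float)
        dn = np.maximum(dn, bead.delta_n * occupancy) if bead.delta_n >= 0 else np.minimum(dn, bead.delta_n * occupancy)
        cmap = conc.setdefault(bead.species, np.zeros_like(dn))
        np.maximum(cmap, occupancy, out=cmap)
    return Phantom(delta_n_cold=dn, concentrations=conc, metadata={"beads": [b._asdict() for b in beads]})


def make_cell_phantom(
    config: OpticalConfig,
    seed: int,
    cytosol_delta_n: float = 1.0e-3,
    droplet_delta_n: float = 2.0e-3,
    n_droplets: tuple[int, int] = (6, 12),
    droplet_radius: tuple[float, float] = (0.3, 0.6),
) -> Phantom:
    """A single-cell phantom: an ellipsoidal cytosol with a uniform
    protein concentration and lipid droplets scattered inside it.

    Protein fills the cytosol except where droplets sit, so the two
    species maps are spatially mostly disjoint.  Reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    X, Y, Z = _voxel_center_grids(config)
    half_x = config.nx * config.pixel_size / 2
    half_y = config.ny * config.pixel_size / 2
    z_span = max(config.z_positions.max(), config.slice_thickness)

    ax = rng.uniform(0.5, 0.75) * half_x
    ay = rng.uniform(0.5, 0.75) * half_y
    az = rng.uniform(0.6, 0.9) * z_span
    cell = (X / ax) ** 2 + (Y / ay) ** 2 + (Z / az) ** 2 <= 1.0

    protein = cell.astype(float)
    lipid = np.zeros_like(protein)
    count = int(rng.integers(n_droplets[0], n_droplets[1] + 1))
    placed = 0
    for _ in range(200):
        if placed >= count:
            break
        r = rng.uniform(*droplet_radius)
        cx = rng.uniform(-0.8 * ax, 0.8 * ax)
        cy = rng.uniform(-0.8 * ay, 0.8 * ay)
        cz = rng.uniform(-0.6 * az, 0.6 * az)
        if (cx / ax) ** 2 + (cy / ay) ** 2 + (cz / az) ** 2 > 0.8:
            continue
        d = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
        inside = d <= r
        lipid[inside] = 1.0
        placed += 1
    protein[lipid > 0] = 0.0

    dn = cytosol_delta_n * protein + droplet_delta_n * lipid
    if np.max(np.abs(dn)) > MAX_WEAK_DELTA_N:
        raise ValueError("cell phantom exceeds the weak-scattering regime")
    return Phantom(
        delta_n_cold=dn,
        concentrations={"protein": protein, "lipid": lipid},
        metadata={"seed": seed, "n_droplets": placed},
    )


class FrameSlot(NamedTuple):
    index: int
    source: int
    state: str
    repetition: int


def timing_schedule(
    timing: PumpProbeTiming,
    n_sources: int,
    n_repeats: int = 1,
) -> list[FrameSlot]:
    """Ordered acquisition plan with strict hot/cold alternation.

    The camera must run at twice the pump duty-modulation rate so that
    consecutive frames sample opposite pump states; each (source,
    repetition) contributes one hot and one cold frame, giving a plan of
    ``2 * n_sources * n_repeats`` frames (32 for the canonical 16-source
    single-repeat volumetric acquisition).
    """
    if not np.isclose(timing.camera_rate, 2.0 * timing.duty_mod_rate):
        raise ValueError(
            "camera_rate must equal 2 * duty_mod_rate for strict hot/cold alternation"
        )
    plan: list[FrameSlot] = []
    idx = 0
    for source in range(n_sources):
        for rep in range(n_repeats):
            for state in STATES:  # hot then cold within each pair
                plan.append(FrameSlot(index=idx, source=source, state=state, repetition=rep))
                idx += 1
    return plan


def simulate_stack(
    phantom: Phantom,
    config: OpticalConfig,
    tfs: TransferFunctionSet,
    library: SpeciesLibrary | None = None,
    wavenumber: float | None = None,
    pump_power: float = 0.0,
    timing: PumpProbeTiming | None = None,
    photon_budget: float = np.inf,
    n_repeats: int = 1,
    seed: int = 0,
    background: float = 1.0,
    ir_profile: np.ndarray | None = None,
) -> IntensityStack:
    """Simulate one hot/cold acquisition of a phantom at one wavenumber.

    The hot volume adds the photothermal ``delta_n`` computed from the
    species concentration maps; with zero pump power (or no library) hot
    and cold coincide.  Noise follows the frame plan ordering so the
    dataset is byte-reproducible given (seed, config).
    """
    timing = timing or PumpProbeTiming()
    plan = timing_schedule(timing, tfs.n_sources, n_repeats)

    eps_cold = phantom.delta_eps(config)
    if library is not None and wavenumber is not None and pump_power > 0:
        dn_hot = mip_delta_n(
            phantom.concentrations, library, wavenumber, pump_power, timing, ir_profile=ir_profile
        )
    else:
        dn_hot = np.zeros(config.volume_shape)
    eps_hot = phantom.delta_eps(config, extra_delta_n=dn_hot)

    clean = {
        "cold": [predict_intensity(eps_cold, tfs, i, background) for i in range(tfs.n_sources)],
        "hot": [predict_intensity(eps_hot, tfs, i, background) for i in range(tfs.n_sources)],
    }

    frames = np.zeros((tfs.n_sources, len(STATES), n_repeats, config.ny, config.nx))
    backgrounds = np.full((tfs.n_sources, len(STATES), n_repeats), float(background))
    base = np.random.SeedSequence(seed)
    for slot in plan:
        img = clean[slot.state][slot.source]
        frames[slot.source, STATES.index(slot.state), slot.repetition] = simulate_frames(
            img, photon_budget, n_repeats=1, seed=base, frame_offset=slot.index
        )[0]
    return IntensityStack(
        frames=frames,
        backgrounds=backgrounds,
        wavenumber=wavenumber,
        pump_power=pump_power,
        timing=timing,
        metadata={"seed": seed, "photon_budget": photon_budget, "n_frames": len(plan)},
    )


def acquire_chemical_record(
    phantom: Phantom,
    config: OpticalConfig,
    tfs: TransferFunctionSet,
    library: SpeciesLibrary,
    wavenumber: float,
    pump_power: float,
    timing: PumpProbeTiming | None = None,
    settings: ReconstructionSettings | None = None,
    photon_budget: float = np.inf,
    n_repeats: int = 1,
    seed: int = 0,
    ir_profile: np.ndarray | None = None,
) -> ChemicalRecord:
    """Closed loop for one wavenumber: simulate, reconstruct both states,
    convert to RI and subtract."""
    timing = timing or PumpProbeTiming()
    stack = simulate_stack(
        phantom,
        config,
        tfs,
        library,
        wavenumber,
        pump_power,
        timing,
        photon_budget,
        n_repeats,
        seed,
        ir_profile=ir_profile,
    )
    cold = to_ri_volume(reconstruct(stack, tfs, settings, state="cold"), config)
    hot = to_ri_volume(reconstruct(stack, tfs, settings, state="hot"), config)
    return hot_cold_subtract(
        hot,
        cold,
        wavenumber=wavenumber,
        pump_power=pump_power,
        delay_time=timing.probe_delay,
        metadata={"seed": seed},
    )


def simulate_tiles(
    phantom: Phantom,
    config: OpticalConfig,
    tfs: TransferFunctionSet,
    library: SpeciesLibrary,
    wavenumber: float,
    pump_power: float,
    ir_centers: Sequence[tuple[float, float]],
    ir_fwhm: float = DEFAULT_IR_FWHM,
    timing: PumpProbeTiming | None = None,
    settings: ReconstructionSettings | None = None,
    photon_budget: float = np.inf,
    seed: int = 0,
    guide_star_fwhm: float = 2.0,
) -> list[Tile]:
    """Scanned-IR acquisition: one closed-loop chemical volume per pump
    position (centres given as ``(x, y)`` pixels), each weighted by the
    physical Gaussian pump dose, plus its synthetic guide-star image."""
    tiles = []
    shape = (config.ny, config.nx)
    for t, center in enumerate(ir_centers):
        profile = gaussian_mask(shape, center, ir_fwhm, pixel_size=config.pixel_size)
        record = acquire_chemical_record(
            phantom,
            config,
            tfs,
            library,
            wavenumber,
            pump_power,
            timing=timing,
            settings=settings,
            photon_budget=photon_budget,
            seed=seed + 1000 * (t + 1),
            ir_profile=profile,
        )
        guide = gaussian_mask(shape, center, guide_star_fwhm, pixel_size=config.pixel_size)
        tiles.append(Tile(delta_ri=record.delta_ri, guide_star=guide, ir_fwhm=ir_fwhm))
    return tiles
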