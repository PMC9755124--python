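# bsidt — bond-selective intensity diffraction tomography

`bsidt` is a computational implementation of mid-infrared photothermal
volumetric chemical imaging on a plain brightfield microscope.  It is
aimed at computational-imaging and label-free-microscopy researchers who
want to study, extend or benchmark the method without the instrument:
every stage — from raw oblique-illumination camera frames to 3D
chemical maps and fingerprint spectra — can be simulated from ground
truth phantoms and inverted back.

## What it computes

**Intensity diffraction tomography (IDT).**  Sixteen oblique plane-wave
sources on an NA-matched ring illuminate a weakly scattering object
(complex permittivity contrast Δε against the medium).  Under the
first-Born approximation each background-normalised intensity spectrum
is linear in the slice-wise object spectra,

    ĝ(ν|ν_i) = Σ_m H_re(ν,m|ν_i) Δε̂_re(ν,m) + H_im(ν,m|ν_i) Δε̂_im(ν,m),

where the transfer functions H_re/H_im combine shifted pupils
P(ν±ν_i), axial propagation phases and 1/kz obliquity factors.  The
inverse problem is a closed-form Tikhonov deconvolution (2×2 per
frequency–slice pair, or an optional joint solve over all slices), and
the synthetic aperture reaches the incoherent limit 2·NA/λ.  An
independent brute-force Green's-function oracle cross-validates the
forward model to a few percent.

**The photothermal (bond-selective) layer.**  A pulsed mid-IR pump tuned
to a vibrational band (Amide I at 1657 cm⁻¹, lipid C=O at 1745 cm⁻¹, …)
transiently heats whatever absorbs there, lowering the local refractive
index by ~10⁻⁴–10⁻³.  Interleaved "hot" and "cold" frames are
reconstructed separately and subtracted: the difference volume is a 3D
map of that chemical bond.  Scanning the pump wavenumber yields a
hyperspectral stack from which fingerprint spectra are extracted
(ROI average → IR-power normalisation → Savitzky–Golay smoothing).
The package also includes the 2D differential-phase-contrast (DPC)
comparison mode, Gaussian-blend stitching of scanned-pump tiles with
guide-star registration, and quantification tools (FWHM resolution
measurement, lipid-droplet volumetry, group statistics).

## Worked example

Two lipid droplets (radii 0.75 and 0.6 µm) in a 64×64×9 volume, imaged
at the lipid band and at the 1900 cm⁻¹ off-resonance control band, with
shot noise and 60-frame averaging per source:

```python
import numpy as np
from bsidt import *
from bsidt.photothermal import SpeciesLibrary, PumpProbeTiming
from bsidt.synthetic import Bead, make_bead_phantom, acquire_chemical_record
from bsidt.quantify import lipid_volume, default_lipid_threshold

config = OpticalConfig(nx=64, ny=64, slice_offsets=tuple(range(-4, 5)))
tfs = compute_tfs(config, IlluminationSet.ring(config, n_sources=16))
library = SpeciesLibrary.default()

phantom = make_bead_phantom(config, [
    Bead(center=(-1.0, 0.5, 0.0), radius=0.75, delta_n=1.5e-3, species="lipid"),
    Bead(center=(+1.3, -0.6, 0.3), radius=0.6,  delta_n=1.5e-3, species="lipid"),
])

common = dict(timing=PumpProbeTiming(),
              settings=ReconstructionSettings(beta_fraction=1e-3, joint_slices=True),
              photon_budget=1e6, n_repeats=60)
record  = acquire_chemical_record(phantom, config, tfs, library, 1745.0, 6.0, seed=42, **common)
control = acquire_chemical_record(phantom, config, tfs, library, 1900.0, 6.0, seed=43, **common)

peak = record.delta_ri.ravel()[np.argmax(np.abs(record.delta_ri))]
print(f"peak photothermal dRI at 1745 cm^-1 : {peak:+.2e}")
print(f"off-resonance (1900 cm^-1) max |dRI|: {np.abs(control.delta_ri).max():.2e}")
thr = default_lipid_threshold(control.delta_ri)
dims = (config.pixel_size, config.pixel_size, config.slice_thickness)
total, comps = lipid_volume(record.delta_ri, thr, dims, per_component=True)
print(f"lipid threshold (3x control noise)  : {thr:.2e}")
print(f"two largest droplets                : {np.round(np.sort(comps)[::-1][:2], 2)} um^3")
```

prints

```
peak photothermal dRI at 1745 cm^-1 : -4.58e-04
off-resonance (1900 cm^-1) max |dRI|: 2.06e-04
lipid threshold (3x control noise)  : 8.72e-05
two largest droplets                : [3.22 1.73] um^3
```

The injected photothermal amplitude at this pump power is
−7.7×10⁻⁵ × 6 = −4.62×10⁻⁴, so the chemical peak is recovered to within
~1% while the control band shows only the noise floor.  The thresholded droplet volumes exceed the
geometric truths (1.77 and 0.90 µm³) because the band-limited point
response spreads each droplet past the 3σ threshold — the usual caveat
of global-threshold volumetry at this resolution.

A command-line interface mirrors the library (`bsidt simulate`, `tf`,
`reconstruct`, `chemvol`, `spectrum`, `dpc`, `stitch`, `quantify`); each
subcommand reads/writes the documented TIFF + YAML / HDF5 / CSV formats
and drops a provenance log.

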