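# Methods

`bsidt` implements bond-selective intensity diffraction tomography: the
recovery of 3D refractive-index (RI) maps from intensity-only images under
oblique laser illumination, combined with mid-infrared photothermal
pump–probe detection that converts vibrational absorption into small,
chemically specific RI changes.  Everything runs on synthetic phantoms;
no instrument or downloads are needed.

## Imaging model

The object is a complex permittivity contrast `Δε(r) = Δε_re + jΔε_im`
against the immersion medium (refractive index `n_m`, default 1.333 for
heavy-water buffer).  Under the first-Born approximation the scattered
field is

    u_s(r) = ∫ u_i(r′) V(r′) G(r − r′) d³r′ ,
    V = k₀² Δε / 4π ,     G(r) = e^{j k_m |r|} / |r| ,

with `k₀ = 2π/λ_vac` the vacuum wavenumber (the scattering potential
derives from the Helmholtz equation, so the vacuum wavenumber appears
there) and `k_m = 2π n_m/λ_vac` governing propagation.  The volume is
discretised into `nz` axial slices of thickness `Δz` at offsets `m·Δz`
around focus.  For each plane-wave source with lateral frequency `ν_i`
the background-normalised intensity spectrum is linear in the slice
spectra:

    ĝ(ν | ν_i) = Σ_m  H_re(ν, m | ν_i) Δε̂_re(ν, m) + H_im(ν, m | ν_i) Δε̂_im(ν, m)

with transfer functions built from the binary pupil `P` (radius `NA/λ_vac`,
boundary inclusive) and the angular axial wavenumber
`kz(ν) = 2π √(λ_med⁻² − |ν|²)`:

    H_re = (j k₀² Δz / 2) A(ν_i) P(ν_i) [ P₊ e^{−j(kz₊−kz_i) mΔz}/kz₊ − P₋ e^{+j(kz₋−kz_i) mΔz}/kz₋ ]
    H_im = −(k₀² Δz / 2) A(ν_i) P(ν_i) [ same bracket, plus sign ]

where `P±, kz±` are evaluated at `ν ± ν_i`.  Spatial frequencies are in
cycles/µm and every complex exponential carries an explicit 2π; the
denominators are angular so that the transfer-function route and the
Green's-function route agree in absolute units.  That agreement is
enforced by a test: an independent brute-force oracle sums
`u_i·V·G` voxel-by-voxel in the spatial domain (on a laterally periodised
window matching the FFT model's boundary conditions), and the two
routes agree to ~3–4% relative L2 on weak beads — the central
correctness gate of the package.

Evanescent frequencies (`|ν| ≥ 1/λ_med`) are excluded by a sentinel and
can never enter a pupil support while `2·NA < n_m`.  The `1/kz`
band-edge divergence is clamped at `10⁻³·(2π/λ_med)`; the clamp touches
only the outermost frequency ring.

## Inversion

Per lateral frequency and slice, the real/imaginary contrast pair is
recovered by closed-form Tikhonov normal equations accumulated over the
16 sources (a 2×2 complex solve per frequency–slice pair).  This
slice-decoupled form is the fast default.  Its axial behaviour should be
understood before quantitative use: because each slice is estimated as
if it alone produced the data, the axial point response is the
unit-peak correlation of transfer functions across slices (~1.9 µm FWHM
under the default geometry), and axially extended features are inflated
by the kernel's sum.  The package therefore also provides a joint solve
over all slices (`joint_slices=True`, a (2·nz)×(2·nz) system per lateral
frequency) which genuinely deconvolves the inter-slice coupling; it is
used for every quantitative fidelity check in this package (resolution
characterisation, band-limited ground-truth correlation, photothermal
amplitude recovery) and costs roughly nz× more time.  Spectrum
extraction depends only on the wavenumber-to-wavenumber *shape* of the
reconstruction, which is unaffected by this choice, so the pipeline
default remains the decoupled form.

Regularisation weights default to `10⁻²` of the peak accumulated
transfer energy (separately for the real and imaginary channels), with
`10⁻³`–`10⁻⁴` used in noise-free closed loops ("small" regularisation).
Hot and cold states share the same weights.  With Hermitian-paired
(real) input images the pre-projection imaginary residual is below 10⁻⁶
of the real part and is discarded.

The "synthetic-aperture support" used when comparing reconstructions to
ground truth is derived from the transfer functions themselves: their
DFT along the slice axis concentrates on the reachable Ewald-arc axial
frequencies, and 3D bins holding more than 1% of the peak transfer
energy form the support indicator.  Bins below that cut carry too
little energy for a regularised inversion to recover.

## Photothermal layer

The mid-IR pump is modelled linearly: for species k with absorption
cross-section σ_k(ν̃) and concentration c_k(r),

    Δn(r) = − Σ_k s_k σ_k(ν̃) c_k(r) · P_pump · d(timing)

with the sign negative because heating lowers the RI of aqueous media.
The response scale `s_k` defaults to the measured oil-film calibration
constant 7.7×10⁻⁵ per pump-power unit (shipped, with its R² = 0.96 and
the ~20 µs thermal decay constant, as named calibration constants — they
are instrument measurements, not desk-recomputable quantities).  Heat
dissipation is a single-exponential surrogate
`d = exp(−max(0, delay−pulse)/τ)`, capped at 1 while the probe overlaps
the pump pulse; the full heat-diffusion problem is out of scope.
The default species library spans the 900–1900 cm⁻¹ fingerprint region
with Lorentzian bands (protein: Amide I at 1657 cm⁻¹ and a
deuterium-shifted Amide II doublet; lipid: ester C=O at 1745 cm⁻¹).
Tails below 1% of each band's peak are clipped to zero so the
1900 cm⁻¹ control band is exactly dark — convenient for control tests
and a fair approximation of the near-flat off-resonance response.

Timing defaults: 10 kHz pulse trains, ~1 µs pulses, 0.5 µs probe delay,
50 Hz pump duty modulation with a 100 Hz camera, so frames alternate
strictly hot/cold and one volumetric acquisition at one wavenumber is
exactly 32 raw frames (16 sources × hot/cold).

Spectrum extraction is three inspectable stages: mean of the chemical
volume over the chosen ROI per wavenumber; division by the mid-IR source
power spectrum; Savitzky–Golay smoothing (default window 7, order 2 —
the filter parameters are not dictated by any physics and are exposed).

## DPC comparison mode

The 2D differential-phase-contrast reconstructor groups the ring into
four cardinal arcs and uses the thin-object weak-phase transfer function
`−j Σ A_i [P(ν−ν_i) − P(ν+ν_i)]` per group, optionally multiplied by the
oblique-path factor `k_m/kz(ν_i)` that accounts for the longer slab path
of a tilted beam (on by default; it calibrates the recovered phase
against the volumetric model for the NA-matched ring).  Phase is
recovered by shared-weight Tikhonov least squares over the groups.
DPC is DC-blind and integrates through depth — both demonstrated in the
test suite by direct comparison against the 3D reconstruction of the
same synthetic raw data.

## Stitching

Scanned-IR acquisitions share the probe FOV; only the Gaussian pump spot
(63 µm FWHM at full scale) moves.  Tiles are blended as
`Σ m_i·tile_i / Σ m_i` with unity-peak Gaussian masks centred on
guide-star centroids (intensity-weighted centroid above 20% of peak
after median background subtraction).  Because each tile's chemical
signal already carries the physical Gaussian dose, the blend recovers
the local signal times `Σm²/Σm ≤ 1`; that dose-fidelity factor is
computed from the masks and voxels below 0.9 are flagged unreliable
(default; at the real spot-to-step ratio of ~6 the whole FOV is
reliable).  Spectra are always extracted from individual tiles, never
from a blended volume.

## Synthetic data

Phantoms stay in the weak-scattering regime (|Δn| ≤ 5×10⁻³): rasterised
spheres with one-pixel anti-aliased edges (overlaps take the maximum
contrast), and a seeded single-cell phantom with a uniform-protein
ellipsoidal cytosol and lipid droplets that displace protein (the two
concentration maps are spatially disjoint by construction).  Acquisition
simulation follows the frame plan (source-major, hot/cold pairs),
applies Poisson shot noise at a stated photon budget plus optional
Gaussian read noise, and derives a per-frame RNG substream from the
global seed so datasets are byte-reproducible.  What the generator does
not emulate: partial coherence of the diffuser-broadened sources,
aberrations, fixed-pattern noise, multiple scattering — so passing tests
demonstrate the correctness of the algorithms under the stated model,
not robustness to those instrument effects.

## Problem sizes

The shipped checks run on desk-scale grids chosen to exercise every code
path: 32×32×5 (px 0.1 µm) for the brute-force oracle, 64×64×9
(px 0.1625 µm) for closed-loop recovery, 48×48×5 for the 26-wavenumber
spectral loop, and 64×64×15 for the resolution characterisation.  The
stitching scene scales the pump spot to 6 µm FWHM with 1 µm steps,
preserving the real scan's step-to-spot ratio on the ~10 µm synthetic
FOV.

## Resolution characterisation and known limitations

The resolution figures are measured on a reconstructed sub-voxel weak
point scatterer (0.1625 µm pixels — the camera pixel over the 40×
magnification — 0.3 µm slices over ±2.1 µm), with FWHM taken by linear
interpolation of half-maximum crossings on Fourier-upsampled profiles.
With the joint solver this gives ≈268 nm laterally and ≈1.22 µm axially.
The axial figure sits within the instrument's measured ~1.1 µm.  The
lateral figure is *sharper* than the measured ~350 nm: an ideal filled
synthetic aperture of radius 2NA/λ has PSF FWHM ≈ 0.705·λ/(2NA) ≈ 244 nm,
whereas measured widths on real data include the finite test feature,
residual aberrations and the partial coherence of diffuser-broadened
sources, none of which this coherent plane-wave model includes.  We
report the model's honest value rather than degrading the simulation to
match.

Other known limitations: single scattering only (strongly scattering
samples violate the model); the decoupled inversion's axial inflation
described above; guide-star centroiding assumes a single dominant spot;
the camera model has no fixed-pattern noise or rolling shutter.
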