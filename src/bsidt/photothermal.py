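"""Mid-infrared photothermal physics, calibration fits and spectroscopy.

A pulsed mid-IR pump tuned to a vibrational band deposits heat where the
matching species absorbs; the transient temperature rise perturbs the
local refractive index, which the visible probe reads out.  The model
here is deliberately linear: the photothermal RI change is proportional
to pump power, species concentration and the species' absorption
cross-section at the pump wavenumber, attenuated by a single-exponential
thermal decay between the pump pulse and the delayed probe pulse.  Water
(D2O buffer) heating, heat diffusion between voxels and per-particle-size
decay constants are out of scope.

The module also carries the instrument-style calibration fits (linear
power response, exponential temporal decay) and the three-stage spectrum
extraction used on hyperspectral stacks: ROI averaging, division by the
mid-IR source power spectrum, Savitzky-Golay smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.signal import savgol_filter

from .inverse import ChemicalRecord

__all__ = [
    "CALIBRATION_SLOPE",
    "CALIBRATION_R_SQUARED",
    "CALIBRATION_DECAY_US",
    "SpeciesLibrary",
    "PumpProbeTiming",
    "Spectrum",
    "PowerFit",
    "DecayFit",
    "mip_delta_n",
    "decay_factor",
    "fit_power_response",
    "fit_exponential_decay",
    "extract_spectrum",
]

#: Measured photothermal power response of the soybean-oil reference film:
#: |dRI| per unit pump power.  Shipped as a calibration constant — it is an
#: instrument measurement, not a desk-recomputable quantity.
CALIBRATION_SLOPE = 7.7e-5
#: Goodness of fit of that linear power response.
CALIBRATION_R_SQUARED = 0.96
#: Thermal decay constant of the oil-film reference, µs.
CALIBRATION_DECAY_US = 20.0


@dataclass(frozen=True)
class SpeciesLibrary:
    """Absorption spectra and photothermal slopes per chemical species.

    ``cross_sections[name]`` is a non-negative weight per wavenumber on the
    shared ``wavenumbers`` axis (cm^-1, strictly increasing);
    ``slopes[name]`` is the magnitude of the RI change per unit pump power
    at unit concentration and unit cross-section.  Heating lowers the RI
    (negative thermo-optic coefficient of aqueous media), so the model
    applies the slope with a negative sign by default.
    """

    wavenumbers: np.ndarray
    cross_sections: Mapping[str, np.ndarray]
    slopes: Mapping[str, float]

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        if wn.ndim != 1 or wn.size < 1 or np.any(np.diff(wn) <= 0):
            raise ValueError("wavenumbers must be a strictly increasing 1D axis")
        object.__setattr__(self, "wavenumbers", wn)
        for name, sigma in self.cross_sections.items():
            sigma = np.asarray(sigma, dtype=float)
            if sigma.shape != wn.shape:
                raise ValueError(f"cross-section of {name!r} must match the wavenumber axis")
            if np.any(sigma < 0):
                raise ValueError(f"cross-section of {name!r} must be non-negative")
            if name not in self.slopes:
                raise ValueError(f"missing photothermal slope for species {name!r}")

    def index_of(self, wavenumber: float) -> int:
        idx = np.flatnonzero(np.isclose(self.wavenumbers, wavenumber, rtol=0, atol=1e-6))
        if idx.size == 0:
            raise ValueError(
                f"wavenumber {wavenumber} cm^-1 is not on the library axis "
                f"[{self.wavenumbers[0]}, {self.wavenumbers[-1]}]; no silent extrapolation"
            )
        return int(idx[0])

    @classmethod
    def default(
        cls,
        wavenumbers: np.ndarray | None = None,
    ) -> "SpeciesLibrary":
        """A two-species fingerprint-region library.

        Protein: Amide I band at 1657 cm^-1 plus the deuterium-shifted
        Amide II doublet (~1550 and ~1450 cm^-1).  Lipid: the ester C=O
        stretch at 1745 cm^-1 with a weak CH2 scissoring shoulder.  Peaks
        are Lorentzian with far tails (below 1% of peak) clipped to zero,
        a compact-support approximation that keeps the off-resonance
        control band at 1900 cm^-1 exactly dark.  Both species share the
        measured oil-film slope magnitude as their photothermal response
        scale.
        """
        wn = np.arange(900.0, 1901.0, 1.0) if wavenumbers is None else np.asarray(wavenumbers, float)

        def lorentz(center: float, fwhm: float, amp: float = 1.0) -> np.ndarray:
            hw = fwhm / 2.0
            line = amp * hw**2 / ((wn - center) ** 2 + hw**2)
            return np.where(line >= 0.01 * amp, line, 0.0)

        protein = lorentz(1657.0, 30.0, 1.0) + lorentz(1550.0, 35.0, 0.45) + lorentz(1450.0, 35.0, 0.35)
        lipid = lorentz(1745.0, 24.0, 1.0) + lorentz(1460.0, 30.0, 0.2)
        return cls(
            wavenumbers=wn,
            cross_sections={"protein": protein, "lipid": lipid},
            slopes={"protein": CALIBRATION_SLOPE, "lipid": CALIBRATION_SLOPE},
        )


@dataclass(frozen=True)
class PumpProbeTiming:
    """Pump/probe pulse timing, all times in µs and rates in Hz.

    Defaults follow the standard acquisition scheme: 10 kHz pulse trains
    of ~1 µs pulses, probe delayed 0.5 µs behind the pump, a 50 Hz on/off
    duty modulation of the pump generating the hot/cold alternation, and
    a 100 Hz camera so that consecutive frames sample opposite states.
    """

    rep_rate: float = 10_000.0
    pulse_duration: float = 1.0
    probe_delay: float = 0.5
    duty_mod_rate: float = 50.0
    camera_rate: float = 100.0
    decay_constant: float = CALIBRATION_DECAY_US

    def __post_init__(self) -> None:
        if self.rep_rate <= 0 or self.camera_rate <= 0 or self.duty_mod_rate <= 0:
            raise ValueError("rates must be positive")
        pulse_spacing_us = 1e6 / self.rep_rate
        if not self.probe_delay < pulse_spacing_us:
            raise ValueError("probe_delay must be shorter than the pump pulse spacing")
        if self.decay_constant <= 0:
            raise ValueError("decay_constant must be positive")

    @property
    def pulses_per_frame(self) -> float:
        return self.rep_rate / self.camera_rate

    def to_dict(self) -> dict:
        return {
            "rep_rate": self.rep_rate,
            "pulse_duration": self.pulse_duration,
            "probe_delay": self.probe_delay,
            "duty_mod_rate": self.duty_mod_rate,
            "camera_rate": self.camera_rate,
            "decay_constant": self.decay_constant,
        }


def decay_factor(timing: PumpProbeTiming) -> float:
    """Fraction of the peak photothermal signal seen by the delayed probe.

    Single-exponential surrogate for heat dissipation: unity while the
    probe overlaps the pump pulse, ``exp(-lag/tau)`` afterwards with
    ``lag = probe_delay - pulse_duration``.
    """
    lag = max(0.0, timing.probe_delay - timing.pulse_duration)
    return float(np.exp(-lag / timing.decay_constant))


def mip_delta_n(
    concentrations: Mapping[str, np.ndarray],
    library: SpeciesLibrary,
    wavenumber: float,
    pump_power: float,
    timing: PumpProbeTiming | None = None,
    sign: float = -1.0,
    ir_profile: np.ndarray | None = None,
) -> np.ndarray:
    """Photothermal RI change volume at one pump wavenumber.

    ``delta_n(r) = sign * sum_k slope_k sigma_k(wavenumber) c_k(r) * P * decay``,
    strictly linear in power and in every concentration.  ``ir_profile``
    optionally modulates the pump laterally (e.g. the focused Gaussian
    pump spot), broadcast over slices.
    """
    if pump_power < 0:
        raise ValueError("pump power must be non-negative")
    idx = library.index_of(wavenumber)
    decay = decay_factor(timing) if timing is not None else 1.0
    out: np.ndarray | None = None
    for name, conc in concentrations.items():
        conc = np.asarray(conc, dtype=float)
        if np.any(conc < 0):
            raise ValueError(f"concentration map of {name!r} must be non-negative")
        sigma = float(library.cross_sections[name][idx])
        slope = abs(float(library.slopes[name]))
        term = sign * slope * sigma * conc * pump_power * decay
        out = term if out is None else out + term
    if out is None:
        raise ValueError("no concentration maps supplied")
    if ir_profile is not None:
        profile = np.asarray(ir_profile, dtype=float)
        if profile.shape != out.shape[:2]:
            raise ValueError("ir_profile must match the lateral volume shape")
        out = out * profile[:, :, None]
    return out


# ---------------------------------------------------------------------------
# Calibration fits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerFit:
    slope: float
    intercept: float
    r_squared: float


def fit_power_response(powers: Sequence[float], delta_n_peaks: Sequence[float]) -> PowerFit:
    """Ordinary least squares of peak |dRI| against pump power."""
    x = np.asarray(powers, dtype=float)
    y = np.asarray(delta_n_peaks, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need at least 3 (power, response) pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate power values")
    if np.ptp(y) == 0:
        return PowerFit(slope=0.0, intercept=float(y[0]), r_squared=0.0)
    res = stats.linregress(x, y)
    return PowerFit(slope=float(res.slope), intercept=float(res.intercept), r_squared=float(res.rvalue**2))


@dataclass(frozen=True)
class DecayFit:
    tau: float
    amplitude: float
    residual_rms: float


def fit_exponential_decay(delays: Sequence[float], values: Sequence[float]) -> DecayFit:
    """Least-squares fit of ``a * exp(-t/tau)`` to a decay series.

    Raises ``ValueError`` for non-decaying data (log-linear slope >= 0).
    """
    t = np.asarray(delays, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4 or t.size != y.size:
        raise ValueError("need at least 4 (delay, value) pairs")
    if np.any(y <= 0):
        raise ValueError("values must be positive after baseline handling")
    log_slope, log_icpt = np.polyfit(t, np.log(y), 1)
    if log_slope >= 0:
        raise ValueError("non-decaying data: log-linear trend is not negative")
    p0 = (float(np.exp(log_icpt)), float(-1.0 / log_slope))
    popt, _ = optimize.curve_fit(
        lambda tt, a, tau: a * np.exp(-tt / tau), t, y, p0=p0, maxfev=10_000
    )
    a_hat, tau_hat = float(popt[0]), float(popt[1])
    resid = y - a_hat * np.exp(-t / tau_hat)
    return DecayFit(tau=tau_hat, amplitude=a_hat, residual_rms=float(np.sqrt(np.mean(resid**2))))


# ---------------------------------------------------------------------------
# Hyperspectral spectrum extraction
# ---------------------------------------------------------------------------


@dataclass
class Spectrum:
    """An extracted mid-IR spectrum with its intermediate stages."""

    wavenumbers: np.ndarray
    values: np.ndarray  # final (normalised + smoothed) dRI per wavenumber
    raw: np.ndarray  # ROI mean before normalisation
    normalized: np.ndarray  # after IR-power normalisation, before smoothing
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        if np.any(np.diff(wn) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        for name in ("values", "raw", "normalized"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != wn.shape:
                raise ValueError(f"{name} must match the wavenumber axis")
            setattr(self, name, arr)
        self.wavenumbers = wn


def extract_spectrum(
    records: Sequence[ChemicalRecord],
    roi: np.ndarray,
    ir_power: Mapping[float, float] | np.ndarray,
    sg_window: int = 7,
    sg_polyorder: int = 2,
) -> Spectrum:
    """ROI-averaged, power-normalised, Savitzky-Golay smoothed spectrum.

    ``records`` is one ChemicalRecord per wavenumber (any order; sorted
    internally).  ``roi`` is a boolean mask over the volume or an integer
    index tuple; ``ir_power`` maps wavenumber to the measured mid-IR power
    (or gives the powers as an array aligned with the sorted wavenumbers).
    All three stages are returned for inspection.
    """
    if len(records) == 0:
        raise ValueError("no chemical records supplied")
    order = np.argsort([r.wavenumber for r in records])
    records = [records[i] for i in order]
    wn = np.asarray([r.wavenumber for r in records], dtype=float)
    if np.any(np.diff(wn) <= 0):
        raise ValueError("records must have distinct wavenumbers")

    roi = np.asarray(roi)
    if roi.dtype == bool:
        if not roi.any():
            raise ValueError("empty ROI")
        raw = np.array([r.delta_ri[roi].mean() for r in records])
        n_voxels = int(roi.sum())
    else:
        if roi.size == 0:
            raise ValueError("empty ROI")
        idx = tuple(roi.T) if roi.ndim == 2 else tuple(roi)
        raw = np.array([r.delta_ri[idx].mean() for r in records])
        n_voxels = len(raw) and int(np.asarray(idx[0]).size)

    if isinstance(ir_power, Mapping):
        power = np.array([float(ir_power[w]) for w in wn])
    else:
        power = np.asarray(ir_power, dtype=float)
        if power.shape != wn.shape:
            raise ValueError("ir_power array must align with the wavenumber axis")
    if np.any(power <= 0):
        raise ValueError("IR power must be strictly positive at every wavenumber")

    if sg_window % 2 == 0 or sg_window <= sg_polyorder:
        raise ValueError("Savitzky-Golay window must be odd and larger than the polynomial order")

    normalized = raw / power
    if len(normalized) >= sg_window:
        smoothed = savgol_filter(normalized, sg_window, sg_polyorder)
    else:
        smoothed = normalized.copy()

    return Spectrum(
        wavenumbers=wn,
        values=smoothed,
        raw=raw,
        normalized=normalized,
        provenance={
            "n_roi_voxels": n_voxels,
            "sg_window": sg_window,
            "sg_polyorder": sg_polyorder,
            "normalization": "ir_power",
        },
    )
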