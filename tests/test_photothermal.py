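import numpy as np
import pytest

from bsidt.inverse import ChemicalRecord
from bsidt.photothermal import (
    CALIBRATION_SLOPE,
    PumpProbeTiming,
    SpeciesLibrary,
    decay_factor,
    extract_spectrum,
    fit_exponential_decay,
    fit_power_response,
    mip_delta_n,
)


@pytest.fixture(scope="module")
def library():
    return SpeciesLibrary.default()


class TestDecayFactor:
    def test_probe_inside_pump_pulse_sees_full_signal(self):
        t = PumpProbeTiming(probe_delay=0.5, pulse_duration=1.0)
        assert decay_factor(t) == 1.0

    @pytest.mark.parametrize(
        "lag,expected",
        [(20.0, np.exp(-1.0)), (10.0, np.exp(-0.5))],
    )
    def test_exponential_lag(self, lag, expected):
        t = PumpProbeTiming(probe_delay=1.0 + lag, pulse_duration=1.0, decay_constant=20.0)
        assert decay_factor(t) == pytest.approx(expected, rel=1e-12)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError, match="decay_constant"):
            PumpProbeTiming(decay_constant=-1.0)


class TestMipDeltaN:
    def test_zero_power_gives_zero(self, library):
        conc = {"lipid": np.ones((4, 4, 2))}
        dn = mip_delta_n(conc, library, 1745.0, pump_power=0.0)
        assert np.all(dn == 0)

    def test_off_resonance_control_band_is_dark(self, library):
        """At the 1900 cm^-1 control band no default species absorbs."""
        conc = {"lipid": np.ones((4, 4, 2)), "protein": np.ones((4, 4, 2))}
        dn = mip_delta_n(conc, library, 1900.0, pump_power=5.0)
        assert np.all(dn == 0)

    def test_bilinear_in_power_and_concentration(self, library, rng):
        conc = {"lipid": rng.random((4, 4, 2))}
        base = mip_delta_n(conc, library, 1745.0, 2.0)
        assert np.allclose(mip_delta_n(conc, library, 1745.0, 4.0), 2 * base)
        double_c = {"lipid": 2 * conc["lipid"]}
        assert np.allclose(mip_delta_n(double_c, library, 1745.0, 2.0), 2 * base)

    def test_heating_lowers_ri_by_default(self, library):
        dn = mip_delta_n({"lipid": np.ones((2, 2, 1))}, library, 1745.0, 1.0)
        assert dn.max() <= 0 and dn.min() < 0

    def test_off_axis_wavenumber_rejected(self, library):
        with pytest.raises(ValueError, match="not on the library axis"):
            mip_delta_n({"lipid": np.ones((2, 2, 1))}, library, 1745.37, 1.0)


class TestPowerResponseFit:
    def test_exact_calibration_line(self):
        powers = np.linspace(0, 40, 8)
        fit = fit_power_response(powers, CALIBRATION_SLOPE * powers)
        assert fit.slope == pytest.approx(7.7e-5, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noisy_slope_recovered_within_ten_percent(self):
        slope = 7.7e-5
        powers = np.linspace(1, 10, 10)
        rng = np.random.default_rng(42)
        slopes = []
        for _ in range(100):
            y = slope * powers
            y = y + rng.normal(0, 0.05 * np.abs(y).max(), size=y.shape)
            slopes.append(fit_power_response(powers, y).slope)
        assert np.median(slopes) == pytest.approx(slope, rel=0.10)

    def test_constant_response_has_zero_slope(self):
        fit = fit_power_response([1, 2, 3, 4], [5.0, 5.0, 5.0, 5.0])
        assert fit.slope == 0.0 and fit.r_squared == 0.0


class TestDecayFit:
    def test_noise_free_recovers_tau(self):
        t = np.linspace(0, 80, 12)
        fit = fit_exponential_decay(t, 3.0 * np.exp(-t / 20.0))
        assert fit.tau == pytest.approx(20.0, rel=1e-6)

    def test_noisy_tau_within_ten_percent(self):
        t = np.linspace(1, 80, 12)
        rng = np.random.default_rng(7)
        taus = []
        for _ in range(100):
            y = np.exp(-t / 20.0) * (1 + rng.normal(0, 0.05, size=t.shape))
            taus.append(fit_exponential_decay(t, np.clip(y, 1e-9, None)).tau)
        assert np.median(taus) == pytest.approx(20.0, rel=0.10)

    def test_constant_series_flagged_non_decaying(self):
        with pytest.raises(ValueError, match="non-decaying"):
            fit_exponential_decay([0, 1, 2, 3], [1.0, 1.0, 1.0, 1.0])


def _records(wavenumbers, volumes):
    out = []
    for w, v in zip(wavenumbers, volumes):
        zero = np.zeros_like(v)
        out.append(ChemicalRecord(cold_ri=zero, hot_ri=v, delta_ri=v, wavenumber=float(w)))
    return out


class TestExtractSpectrum:
    def test_flat_hyperstack_flat_power_gives_flat_spectrum(self):
        wn = np.arange(1500.0, 1600.0, 4.0)
        vols = [np.full((4, 4, 2), 2e-4) for _ in wn]
        spec = extract_spectrum(_records(wn, vols), np.ones((4, 4, 2), bool), np.ones(wn.size))
        assert np.allclose(spec.values, 2e-4)

    def test_doubling_power_halves_output_exactly(self):
        wn = np.arange(1500.0, 1600.0, 4.0)
        rng = np.random.default_rng(0)
        vols = [rng.normal(size=(4, 4, 2)) for _ in wn]
        recs = _records(wn, vols)
        roi = np.ones((4, 4, 2), bool)
        a = extract_spectrum(recs, roi, np.ones(wn.size))
        b = extract_spectrum(recs, roi, 2 * np.ones(wn.size))
        assert np.allclose(b.values, a.values / 2)

    def test_stages_commute_with_positive_rescale(self):
        wn = np.arange(1500.0, 1600.0, 4.0)
        rng = np.random.default_rng(1)
        vols = [rng.normal(size=(4, 4, 2)) for _ in wn]
        roi = np.ones((4, 4, 2), bool)
        a = extract_spectrum(_records(wn, vols), roi, np.ones(wn.size))
        b = extract_spectrum(_records(wn, [3.5 * v for v in vols]), roi, np.ones(wn.size))
        assert np.allclose(b.values, 3.5 * a.values)

    def test_empty_roi_and_bad_power_rejected(self):
        wn = np.arange(1500.0, 1540.0, 4.0)
        recs = _records(wn, [np.ones((4, 4, 2)) for _ in wn])
        with pytest.raises(ValueError, match="empty ROI"):
            extract_spectrum(recs, np.zeros((4, 4, 2), bool), np.ones(wn.size))
        with pytest.raises(ValueError, match="strictly positive"):
            extract_spectrum(recs, np.ones((4, 4, 2), bool), np.zeros(wn.size))

    def test_savitzky_golay_window_validation(self):
        wn = np.arange(1500.0, 1600.0, 4.0)
        recs = _records(wn, [np.ones((4, 4, 2)) for _ in wn])
        with pytest.raises(ValueError, match="odd"):
            extract_spectrum(recs, np.ones((4, 4, 2), bool), np.ones(wn.size), sg_window=6)


class TestSpeciesLibrary:
    def test_default_bands_sit_on_their_centers(self, library):
        protein = library.cross_sections["protein"]
        lipid = library.cross_sections["lipid"]
        assert library.wavenumbers[np.argmax(protein)] == 1657.0
        assert library.wavenumbers[np.argmax(lipid)] == 1745.0

    def test_negative_cross_section_rejected(self):
        wn = np.array([1000.0, 1100.0])
        with pytest.raises(ValueError, match="non-negative"):
            SpeciesLibrary(wavenumbers=wn, cross_sections={"x": np.array([-1.0, 0.0])}, slopes={"x": 1.0})
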