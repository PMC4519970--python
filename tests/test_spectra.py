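import numpy as np
import pytest

from lumifret import (
    Spectrum,
    inner_filter_correct,
    overlap_integral,
    read_spectrum,
    resample_common_grid,
    subtract_spectra,
    write_spectrum,
)
from lumifret.spectra import SpectrumParseError


def _boxcar(lo, hi, value, kind, step=1.0):
    wl = np.arange(lo, hi + step / 2, step)
    return Spectrum(wl, np.full(wl.size, float(value)), kind)


class TestSpectrumInvariants:
    def test_rejects_nonincreasing_grid(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Spectrum([500.0, 500.0, 600.0], [1.0, 2.0, 3.0], "emission")

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            Spectrum([500.0, 600.0], [1.0], "emission")

    def test_rejects_negative_absorbance(self):
        with pytest.raises(ValueError, match="nonnegative"):
            Spectrum([500.0, 600.0], [0.1, -0.1], "absorbance")

    def test_rejects_unknown_kind(self):
        with pytest.raises(ValueError, match="kind"):
            Spectrum([500.0], [1.0], "transmittance")


class TestReadSpectrum:
    def test_roundtrip(self, tmp_path):
        path = tmp_path / "em.txt"
        path.write_text("500,0.0\n545,1.0\n600,0.0\n")
        spec = read_spectrum(path, "emission")
        assert len(spec) == 3
        assert spec.kind == "emission"
        np.testing.assert_allclose(spec.wavelengths, [500, 545, 600])

    def test_out_of_order_rows_are_sorted(self, tmp_path):
        path = tmp_path / "em.txt"
        path.write_text("600 0.0\n500 1.0\n")
        spec = read_spectrum(path, "emission")
        np.testing.assert_allclose(spec.wavelengths, [500, 600])
        np.testing.assert_allclose(spec.values, [1.0, 0.0])

    def test_duplicate_wavelength_rejected(self, tmp_path):
        path = tmp_path / "em.txt"
        path.write_text("500 0.0\n545 1.0\n545 0.5\n")
        with pytest.raises(SpectrumParseError, match="duplicate wavelength 545"):
            read_spectrum(path, "emission")

    def test_non_numeric_row_names_line(self, tmp_path):
        path = tmp_path / "em.txt"
        path.write_text("500 0.0\nfoo bar\n")
        with pytest.raises(SpectrumParseError, match=":2:"):
            read_spectrum(path, "emission")

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "em.txt"
        path.write_text("# only a comment\n")
        with pytest.raises(SpectrumParseError, match="no data"):
            read_spectrum(path, "emission")

    def test_writer_emits_readable_dialect(self, tmp_path):
        spec = _boxcar(500, 510, 2.5, "extinction")
        path = tmp_path / "ext.txt"
        write_spectrum(spec, path)
        back = read_spectrum(path, "extinction")
        np.testing.assert_allclose(back.wavelengths, spec.wavelengths)
        np.testing.assert_allclose(back.values, spec.values)


class TestResampleCommonGrid:
    def test_identity_on_identical_grids(self):
        a = _boxcar(500, 510, 1.0, "emission")
        b = _boxcar(500, 510, 2.0, "emission")
        ra, rb = resample_common_grid(a, b, step=1.0)
        np.testing.assert_allclose(ra.wavelengths, a.wavelengths)
        np.testing.assert_allclose(ra.values, a.values)
        np.testing.assert_allclose(rb.values, b.values)

    def test_shared_grid_interval_arithmetic(self):
        a = _boxcar(400, 700, 1.0, "emission")
        b = _boxcar(500, 800, 1.0, "emission")
        ra, rb = resample_common_grid(a, b, step=1.0)
        assert len(ra) == len(rb) == 201
        assert ra.wl_min == 500 and ra.wl_max == 700

    def test_linear_interpolation_exact_on_linear_data(self):
        wl = np.arange(500.0, 521.0, 2.0)
        a = Spectrum(wl, wl.copy(), "emission")  # v(lambda) = lambda
        b = _boxcar(501, 519, 1.0, "emission")
        ra, _ = resample_common_grid(a, b, step=2.0)  # midpoints of a's grid
        np.testing.assert_allclose(ra.values, ra.wavelengths, rtol=1e-14)

    def test_disjoint_ranges_error(self):
        a = _boxcar(400, 450, 1.0, "emission")
        b = _boxcar(500, 550, 1.0, "emission")
        with pytest.raises(ValueError, match="overlap"):
            resample_common_grid(a, b)


class TestOverlapIntegral:
    def test_boxcar_matches_polynomial_oracle(self):
        # F const, eps = 1e5 on [540, 550]: J = 1e5 * int(l^4) / 10 exactly
        donor = _boxcar(540, 550, 3.0, "emission")
        acceptor = _boxcar(540, 550, 1.0e5, "extinction")
        oracle = 1.0e5 * (550.0**5 - 540.0**5) / 5.0 / 10.0
        res = overlap_integral(donor, acceptor, step=1.0)
        assert res.J == pytest.approx(oracle, rel=5e-3)
        assert res.J == pytest.approx(1.0e5 * 545.0**4, rel=2e-4)
        assert res.wavelength_range == (540.0, 550.0)

    def test_donor_normalization_and_acceptor_linearity(self):
        donor = _boxcar(540, 560, 1.0, "emission")
        acceptor = _boxcar(545, 555, 2.0e4, "extinction")
        j = overlap_integral(donor, acceptor).J
        assert overlap_integral(donor.scaled(2.0), acceptor).J == pytest.approx(j, rel=1e-12)
        assert overlap_integral(donor, acceptor.scaled(2.0)).J == pytest.approx(2 * j, rel=1e-12)

    def test_disjoint_support_errors(self):
        donor = _boxcar(500, 520, 1.0, "emission")
        acceptor = _boxcar(600, 620, 1.0e5, "extinction")
        with pytest.raises(ValueError, match="overlap"):
            overlap_integral(donor, acceptor)

    def test_zero_donor_area_errors(self):
        donor = _boxcar(540, 550, 0.0, "emission")
        acceptor = _boxcar(540, 550, 1.0e5, "extinction")
        with pytest.raises(ValueError, match="zero area"):
            overlap_integral(donor, acceptor)

    def test_quadrature_converges_under_step_halving(self):
        wl = np.arange(500.0, 601.0, 1.0)
        donor = Spectrum(wl, np.exp(-((wl - 550.0) ** 2) / (2 * 8.0**2)), "emission")
        acceptor = Spectrum(wl, 1e5 * np.exp(-((wl - 555.0) ** 2) / (2 * 10.0**2)), "extinction")
        j1 = overlap_integral(donor, acceptor, step=1.0).J
        j_half = overlap_integral(donor, acceptor, step=0.5).J
        assert abs(j1 - j_half) / j_half < 1e-3


class TestInnerFilterCorrect:
    def test_zero_absorbance_is_identity(self):
        em = _boxcar(550, 650, 100.0, "emission")
        d = _boxcar(550, 650, 0.0, "absorbance")
        out = inner_filter_correct(em, d)
        np.testing.assert_allclose(out.values, em.values)

    def test_known_correction_factors(self):
        # D=2 -> x10; D=0.30103 (=log10 2) -> x sqrt(2)
        em = Spectrum([600.0, 610.0], [100.0, 50.0], "emission")
        d = Spectrum([600.0, 610.0], [2.0, 0.30103], "absorbance")
        out = inner_filter_correct(em, d)
        assert out.values[0] == pytest.approx(1000.0)
        assert out.values[1] == pytest.approx(70.71, abs=0.01)

    def test_output_never_below_input(self):
        rng = np.random.default_rng(7)
        wl = np.arange(550.0, 650.0)
        em = Spectrum(wl, rng.uniform(0, 100, wl.size), "emission")
        d = Spectrum(wl, rng.uniform(0, 1.5, wl.size), "absorbance")
        out = inner_filter_correct(em, d)
        assert np.all(out.values >= em.values)

    def test_wrong_kinds_rejected(self):
        em = _boxcar(550, 650, 1.0, "emission")
        with pytest.raises(ValueError, match="absorbance"):
            inner_filter_correct(em, em)


class TestSubtractSpectra:
    def test_self_subtraction_is_zero(self):
        em = _boxcar(550, 650, 42.0, "emission")
        result = subtract_spectra(em, em)
        np.testing.assert_allclose(result.spectrum.values, 0.0)
        assert result.n_clamped == 0

    def test_recovers_injected_gaussian_band(self):
        wl = np.arange(500.0, 701.0)
        base = np.full(wl.size, 10.0)
        band = 25.0 * np.exp(-((wl - 606.0) ** 2) / (2 * 12.0**2))
        full = Spectrum(wl, base + band, "emission")
        bleached = Spectrum(wl, base, "emission")
        recovered = subtract_spectra(full, bleached).spectrum
        np.testing.assert_allclose(recovered.values, band, atol=1e-10)

    def test_negative_residuals_clamped_and_counted(self):
        wl = np.arange(550.0, 560.0)
        full = Spectrum(wl, np.full(wl.size, 1.0), "emission")
        bleached = Spectrum(wl, np.full(wl.size, 2.0), "emission")
        result = subtract_spectra(full, bleached)
        assert np.all(result.spectrum.values == 0.0)
        assert result.n_clamped == wl.size
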