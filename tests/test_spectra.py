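"""Spectrum I/O, λmax, violet contribution and bathochromic shift."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anthochrome.spectra import (
    Spectrum,
    bathochromic_shift,
    find_lambda_max,
    read_spectrum,
    resample,
    violet_contribution,
    write_spectrum,
)


class TestSpectrumModel:
    def test_direct_construction(self):
        s = Spectrum([500, 501, 502], [0.1, 0.2, 0.1])
        assert len(s) == 3
        assert s.resolution_nm == 1.0

    @pytest.mark.parametrize(
        "wl, ab, msg",
        [
            ([500, 500, 501], [1, 2, 3], "strictly increasing"),
            ([500, 501], [1, 2, 3], "length mismatch"),
            ([500], [1], "at least 2"),
            ([500, 501], [1, np.nan], "non-finite"),
        ],
    )
    def test_invariants_rejected(self, wl, ab, msg):
        with pytest.raises(ValueError, match=msg):
            Spectrum(wl, ab)


class TestIO:
    def test_roundtrip_with_header(self, tmp_path, gaussian_spectrum):
        s = gaussian_spectrum()
        path = tmp_path / "s.csv"
        write_spectrum(s, path)
        back = read_spectrum(path)
        assert np.allclose(back.wavelengths_nm, s.wavelengths_nm)
        # writer emits 6 significant digits; round-trip at that precision
        assert np.allclose(back.absorbance, s.absorbance, rtol=1e-5, atol=1e-9)

    def test_headerless_and_header_give_same_spectrum(self, tmp_path):
        (tmp_path / "a.csv").write_text("500,0.1\n501,0.2\n502,0.1\n")
        (tmp_path / "b.csv").write_text(
            "wavelength_nm,absorbance\n500,0.1\n501,0.2\n502,0.1\n"
        )
        a, b = read_spectrum(tmp_path / "a.csv"), read_spectrum(tmp_path / "b.csv")
        assert np.array_equal(a.wavelengths_nm, b.wavelengths_nm)
        assert np.array_equal(a.absorbance, b.absorbance)

    def test_shuffled_rows_sorted_on_read(self, tmp_path):
        (tmp_path / "shuf.csv").write_text("502,0.1\n500,0.3\n501,0.2\n")
        s = read_spectrum(tmp_path / "shuf.csv")
        assert np.array_equal(s.wavelengths_nm, [500, 501, 502])
        assert np.array_equal(s.absorbance, [0.3, 0.2, 0.1])

    def test_bad_row_reports_line_number(self, tmp_path):
        (tmp_path / "bad.csv").write_text("500,0.1\n501,oops\n")
        with pytest.raises(ValueError, match=":2:"):
            read_spectrum(tmp_path / "bad.csv")

    def test_duplicate_wavelengths_rejected(self, tmp_path):
        (tmp_path / "dup.csv").write_text("500,0.1\n500,0.2\n501,0.3\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_spectrum(tmp_path / "dup.csv")


class TestResample:
    def test_identity_on_own_grid(self, gaussian_spectrum):
        s = gaussian_spectrum()
        r = resample(s, s.wavelengths_nm)
        assert np.array_equal(r.absorbance, s.absorbance)

    def test_midpoint_of_line(self):
        s = Spectrum([500, 502], [0.0, 2.0])
        assert resample(s, [500, 501, 502]).absorbance[1] == pytest.approx(1.0)

    def test_matches_piecewise_linear_oracle(self, gaussian_spectrum, rng):
        s = gaussian_spectrum(step=2.0)
        grid = np.sort(rng.uniform(410, 690, size=50))
        r = resample(s, grid)
        # independent interpolation: manual segment-by-segment evaluation
        for g, v in zip(grid, r.absorbance):
            i = np.searchsorted(s.wavelengths_nm, g, side="right") - 1
            i = min(i, len(s) - 2)
            x0, x1 = s.wavelengths_nm[i], s.wavelengths_nm[i + 1]
            y0, y1 = s.absorbance[i], s.absorbance[i + 1]
            assert v == pytest.approx(y0 + (y1 - y0) * (g - x0) / (x1 - x0))

    def test_extrapolation_refused(self, gaussian_spectrum):
        with pytest.raises(ValueError, match="extrapolation"):
            resample(gaussian_spectrum(), [300, 500])


class TestLambdaMax:
    def test_symmetric_gaussian_peak(self, gaussian_spectrum):
        m = find_lambda_max(gaussian_spectrum(center=600.0))
        assert m.lambda_max_nm == 600.0
        assert m.a_max == pytest.approx(1.0)

    def test_equals_brute_force_argmax(self, rng):
        wl = np.arange(400.0, 701.0)
        # random smooth spectrum: sum of random Gaussians
        a = sum(
            h * np.exp(-0.5 * ((wl - c) / s) ** 2)
            for h, c, s in zip(
                rng.uniform(0.2, 1, 5), rng.uniform(420, 680, 5), rng.uniform(10, 60, 5)
            )
        )
        s = Spectrum(wl, a)
        best = max(zip(a, wl))  # exhaustive scan oracle
        assert find_lambda_max(s).lambda_max_nm == best[1]

    def test_plateau_tie_breaks_to_longer_wavelength(self):
        s = Spectrum([500, 501, 502, 503], [0.0, 1.0, 1.0, 0.5])
        assert find_lambda_max(s, (495, 505)).lambda_max_nm == 502.0

    def test_window_restriction_and_empty_overlap(self, gaussian_spectrum):
        s = gaussian_spectrum(center=600.0)
        assert find_lambda_max(s, (400, 550)).lambda_max_nm == 550.0
        with pytest.raises(ValueError, match="does not overlap"):
            find_lambda_max(s, (900, 950))


class TestVioletContribution:
    def test_constant_unit_absorbance(self):
        wl = np.arange(400.0, 701.0)
        assert violet_contribution(Spectrum(wl, np.ones_like(wl))) == pytest.approx(
            100.0
        )

    def test_zero_spectrum(self):
        wl = np.arange(400.0, 701.0)
        assert violet_contribution(Spectrum(wl, np.zeros_like(wl))) == 0.0

    def test_upper_edge_excluded(self):
        # only the 600-nm point differs: must not change the left sum
        wl = np.arange(400.0, 701.0)
        a = np.ones_like(wl)
        b = a.copy()
        b[wl == 600.0] = 50.0
        assert violet_contribution(Spectrum(wl, a)) == violet_contribution(
            Spectrum(wl, b)
        )

    def test_nonuniform_grid_resampled(self, rng):
        wl = np.sort(rng.choice(np.arange(400.0, 701.0, 0.25), 400, replace=False))
        wl = np.unique(np.concatenate([[400.0], wl, [700.0]]))
        a = np.exp(-0.5 * ((wl - 550) / 30) ** 2)
        vc = violet_contribution(Spectrum(wl, a))
        # closed-form Gaussian mass over [500, 600] nm
        from math import erf, sqrt

        oracle = 30 * np.sqrt(2 * np.pi) * erf((50 / 30) / sqrt(2))
        assert vc == pytest.approx(oracle, rel=0.02)

    def test_missing_coverage_named(self):
        s = Spectrum(np.arange(520.0, 701.0), np.ones(181))
        with pytest.raises(ValueError, match=r"\[500"):
            violet_contribution(s)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(alpha=st.floats(0.0, 10.0, allow_nan=False))
    def test_linear_in_absorbance(self, alpha):
        wl = np.arange(400.0, 701.0)
        a = np.exp(-0.5 * ((wl - 560) / 40) ** 2)
        vc1 = violet_contribution(Spectrum(wl, a))
        vc2 = violet_contribution(Spectrum(wl, alpha * a))
        assert vc2 == pytest.approx(alpha * vc1, abs=1e-9)

    def test_grid_refinement_converges_to_quadrature(self):
        # VC at decreasing spacing approaches the 0.1-nm trapezoid integral
        def gauss(wl):
            return np.exp(-0.5 * ((wl - 550.0) / 30.0) ** 2)

        fine = np.arange(500.0, 600.0 + 0.05, 0.1)
        oracle = np.trapezoid(gauss(fine), fine)
        errs = []
        for step in (4.0, 2.0, 1.0, 0.5):
            wl = np.arange(400.0, 700.0 + step / 2, step)
            errs.append(abs(violet_contribution(Spectrum(wl, gauss(wl))) - oracle))
        assert all(e1 >= e2 for e1, e2 in zip(errs, errs[1:]))
        assert errs[-1] / oracle < 0.01


class TestBathochromicShift:
    def test_by_construction_sign(self, gaussian_spectrum):
        ref = gaussian_spectrum(center=598.0)
        shifted = gaussian_spectrum(center=640.0)
        assert bathochromic_shift(ref, shifted) == 42.0
        assert bathochromic_shift(shifted, ref) == -42.0

    def test_identity(self, gaussian_spectrum):
        s = gaussian_spectrum()
        assert bathochromic_shift(s, s) == 0.0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        c1=st.floats(450, 650), c2=st.floats(450, 650),
        scale=st.floats(0.1, 10), offset=st.floats(0, 0.5),
    )
    def test_antisymmetry_and_affine_invariance(self, c1, c2, scale, offset):
        wl = np.arange(400.0, 701.0)
        a = Spectrum(wl, np.exp(-0.5 * ((wl - c1) / 30) ** 2))
        b = Spectrum(wl, np.exp(-0.5 * ((wl - c2) / 30) ** 2))
        assert bathochromic_shift(a, b) == -bathochromic_shift(b, a)
        a_scaled = Spectrum(wl, scale * a.absorbance + offset)
        assert (
            find_lambda_max(a_scaled).lambda_max_nm
            == find_lambda_max(a).lambda_max_nm
        )
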