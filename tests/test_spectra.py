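"""Spectrum container, overlap integral and Förster-radius arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretchar.spectra import (
    FretTheoryParams,
    Spectrum,
    efficiency_at_distance,
    forster_radius,
    overlap_integral,
    read_spectrum,
    resample,
    round_half_up,
    simulate_pair_spectrum,
)


class TestSpectrum:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            Spectrum([400, 400, 500], [0, 1, 0], "emission")  # non-increasing
        with pytest.raises(ValueError):
            Spectrum([400, 450], [1, -1], "emission")  # negative values
        with pytest.raises(ValueError):
            Spectrum([400], [1], "emission")  # degenerate

    def test_normalizations(self):
        s = Spectrum([400, 450, 500], [0.0, 2.0, 0.0], "emission")
        assert s.normalized("peak").values.max() == 1.0
        assert abs(s.normalized("area").area() - 1.0) < 1e-9


class TestReadSpectrum:
    def test_echoes_rows(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("400,0\n450,1\n500,0\n")
        s = read_spectrum(p, "emission")
        assert len(s) == 3 and s.normalization == "raw"
        assert s.peak_wavelength_nm == 450

    def test_duplicate_wavelength_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("400,0\n450,1\n450,2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_spectrum(p, "emission")

    def test_unsorted_equals_sorted(self, tmp_path):
        rows = [(500.0, 0.2), (400.0, 0.1), (450.0, 1.0)]
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        p1.write_text("".join(f"{w},{v}\n" for w, v in rows))
        p2.write_text("".join(f"{w},{v}\n" for w, v in sorted(rows)))
        s1, s2 = read_spectrum(p1, "emission"), read_spectrum(p2, "emission")
        np.testing.assert_array_equal(s1.wavelengths_nm, s2.wavelengths_nm)
        np.testing.assert_array_equal(s1.values, s2.values)

    def test_header_tolerated_and_bad_rows_named(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("wavelength_nm,value\n400,0\n450,1\n")
        assert len(read_spectrum(p, "absorbance")) == 2
        bad = tmp_path / "bad.csv"
        bad.write_text("400,0\n450,oops\n500,0\n")
        with pytest.raises(ValueError, match="line"):
            read_spectrum(bad, "absorbance")


class TestResample:
    def test_identity_on_own_grid(self):
        s = Spectrum([400.0, 450.0, 500.0], [0.0, 1.0, 0.5], "emission")
        r = resample(s, 400, 500, 50)
        np.testing.assert_allclose(r.values, s.values)

    def test_linear_midpoint(self):
        s = Spectrum([400.0, 500.0], [0.0, 1.0], "emission")
        r = resample(s, 450, 450.0 + 1, 1.0)
        assert abs(r.values[0] - 0.5) < 1e-12

    def test_outside_support_is_zero(self):
        s = Spectrum([450.0, 500.0], [1.0, 1.0], "emission")
        r = resample(s, 400, 600, 10)
        assert r.values[0] == 0.0 and r.values[-1] == 0.0

    def test_no_overlap_errors(self):
        s = Spectrum([450.0, 500.0], [1.0, 1.0], "emission")
        with pytest.raises(ValueError, match="overlap"):
            resample(s, 600, 700, 1.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_fine_resample_preserves_integral(self, seed):
        rng = np.random.default_rng(seed)
        wl = np.sort(rng.uniform(400, 600, 15))
        wl += np.arange(15) * 1e-6  # ensure strictly increasing
        vals = rng.uniform(0, 1, 15)
        s = Spectrum(wl, vals, "emission")
        fine = resample(s, wl[0], wl[-1], 0.1)
        assert fine.area() == pytest.approx(s.area(), rel=1e-3)


class TestOverlapIntegral:
    def test_disjoint_spectra_give_zero(self):
        grid = np.arange(400.0, 701.0)
        em = np.where(grid < 500, 1.0, 0.0)
        ab = np.where(grid > 600, 1.0, 0.0)
        j = overlap_integral(
            Spectrum(grid, em, "emission"), Spectrum(grid, ab, "absorbance"), 1e5
        )
        assert j == 0.0

    def test_narrow_emission_in_flat_extinction(self):
        # donor emission collapsing around λ0 inside ε(λ)=ε0 → J → ε0·λ0⁴
        lam0, eps0 = 520.0, 7.3e4
        grid = np.arange(400.0, 651.0, 0.25)
        ab = Spectrum(grid, np.ones_like(grid), "absorbance")
        for width, tol in ((5.0, 2e-3), (1.0, 1e-4)):
            em = Spectrum(grid, np.exp(-0.5 * ((grid - lam0) / width) ** 2), "emission")
            j = overlap_integral(em, ab, eps0)
            assert j == pytest.approx(eps0 * lam0**4, rel=4 * (width / lam0) ** 2 + tol)

    def test_amplitude_invariance(self):
        grid = np.arange(400.0, 701.0)
        em = np.exp(-0.5 * ((grid - 474) / 20) ** 2)
        ab = np.exp(-0.5 * ((grid - 515) / 25) ** 2)
        j1 = overlap_integral(
            Spectrum(grid, em, "emission"), Spectrum(grid, ab, "absorbance"), 1e5
        )
        j2 = overlap_integral(
            Spectrum(grid, 7.7 * em, "emission"),
            Spectrum(grid, 0.03 * ab, "absorbance"),
            1e5,
        )
        assert j1 == pytest.approx(j2, rel=1e-12)

    def test_grid_mismatch_rejected(self):
        a = Spectrum(np.arange(400.0, 500.0), np.ones(100), "emission")
        b = Spectrum(np.arange(401.0, 501.0), np.ones(100), "absorbance")
        with pytest.raises(ValueError, match="[Gg]rid"):
            overlap_integral(a, b, 1e5)


class TestForsterRadius:
    def test_zero_overlap_gives_zero(self):
        assert forster_radius(0.0) == 0.0

    def test_sixth_root_scaling(self):
        j = 2.5e15
        assert forster_radius(j * 2**6) == pytest.approx(2 * forster_radius(j), rel=1e-12)

    def test_monotone_in_parameters(self):
        j = 2.0e15
        base = forster_radius(j, FretTheoryParams(2 / 3, 1.33, 0.9))
        assert forster_radius(j, FretTheoryParams(1.0, 1.33, 0.9)) > base
        assert forster_radius(j, FretTheoryParams(2 / 3, 1.40, 0.9)) < base
        assert forster_radius(j, FretTheoryParams(2 / 3, 1.33, 0.95)) > base
        assert forster_radius(1.1 * j, FretTheoryParams(2 / 3, 1.33, 0.9)) > base

    def test_negative_overlap_rejected(self):
        with pytest.raises(ValueError):
            forster_radius(-1.0)


class TestEfficiencyAtDistance:
    @pytest.mark.parametrize(
        "r_over_r0,expected",
        [(1.0, 0.5), (0.0, 1.0), (2.0, 1.0 / 65.0)],
    )
    def test_closed_form(self, r_over_r0, expected):
        assert efficiency_at_distance(57.0, 57.0 * r_over_r0) == pytest.approx(expected)

    def test_strictly_decreasing(self):
        r = np.linspace(0, 150, 50)
        e = [efficiency_at_distance(60.0, x) for x in r]
        assert all(a > b for a, b in zip(e, e[1:]))


class TestSimulatePairSpectrum:
    def test_limits(self, donor, yellow_acceptor):
        s0 = simulate_pair_spectrum(donor, yellow_acceptor, 0.0)
        s1 = simulate_pair_spectrum(donor, yellow_acceptor, 1.0)
        # E=0 → pure donor shape; E=1 → pure acceptor shape
        d = donor.emission.normalized("area")
        a = yellow_acceptor.emission.normalized("area")
        interp_d = np.interp(s0.wavelengths_nm, d.wavelengths_nm, d.values)
        interp_a = np.interp(s1.wavelengths_nm, a.wavelengths_nm, a.values)
        np.testing.assert_allclose(s0.values, 0.93 * interp_d, atol=1e-12)
        np.testing.assert_allclose(s1.values, 0.68 * interp_a, atol=1e-12)

    def test_photon_bookkeeping(self):
        # disjoint bands so the donor/acceptor integrals separate cleanly
        from fretchar.synth import gen_spectra

        d = gen_spectra((400, 430), widths_nm=(8, 6), qy=0.93, name="d")
        a = gen_spectra((600, 640), widths_nm=(8, 6), qy=0.68, name="a")
        E = 0.4
        s = simulate_pair_spectrum(d, a, E)
        split = 520.0
        donor_band = np.trapezoid(
            s.values[s.wavelengths_nm < split], s.wavelengths_nm[s.wavelengths_nm < split]
        )
        total = s.area()
        expected = (1 - E) * 0.93 / ((1 - E) * 0.93 + E * 0.68)
        # 1e-6: the band split at 520 nm sits on a discrete trapezoid grid
        assert donor_band / total == pytest.approx(expected, rel=1e-6)

    def test_invalid_efficiency(self, donor, yellow_acceptor):
        with pytest.raises(ValueError):
            simulate_pair_spectrum(donor, yellow_acceptor, 1.2)


def test_round_half_up():
    assert round_half_up(58.5) == 59
    assert round_half_up(58.49) == 58
    assert round_half_up(-0.5) == 0
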