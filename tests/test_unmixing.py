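"""Spectral unmixing of sensitized emission and the E_D estimator."""

import numpy as np
import pytest
from dataclasses import replace

from fretchar.spectra import Spectrum
from fretchar.synth import gen_cell_spectra, make_reference_set
from fretchar.unmixing import (
    CellSpectra,
    ReferenceSet,
    align_and_normalize,
    apparent_efficiency,
    subtract_direct_excitation,
    unmix,
    unmix_pipeline,
)


@pytest.fixture
def refs(donor, yellow_acceptor):
    return make_reference_set(donor, yellow_acceptor, direct_excitation_fraction=0.2)


def _grid_spectrum(values):
    return Spectrum(np.arange(350.0, 801.0), values, "emission")


class TestAlignAndNormalize:
    def test_divides_by_acceptor_peak(self, donor, yellow_acceptor):
        f_a = yellow_acceptor.emission.normalized("area")
        cell = CellSpectra(
            donor_excitation=donor.emission,
            acceptor_excitation=_grid_spectrum(2.0 * f_a.values / f_a.values.max()),
            acceptor_class="green_yellow",
        )
        # window 0: test the scalar-division semantics against the raw peak
        out = align_and_normalize(cell, peak_smooth_window=0)
        np.testing.assert_allclose(
            out.donor_excitation.values, donor.emission.values / 2.0, atol=1e-12
        )

    def test_identity_on_aligned_grids(self, donor, yellow_acceptor):
        f_a = yellow_acceptor.emission.normalized("peak")
        cell = CellSpectra(donor.emission, f_a, "green_yellow")
        out = align_and_normalize(cell)
        np.testing.assert_array_equal(
            out.donor_excitation.wavelengths_nm, donor.emission.wavelengths_nm
        )

    def test_offset_grid_interpolates(self):
        grid = np.arange(400.0, 600.0)
        line = (grid - 400.0) / 200.0
        donor_exc = Spectrum(grid + 0.5, line, "emission")
        acc_exc = Spectrum(grid, np.ones_like(grid), "emission")
        out = align_and_normalize(CellSpectra(donor_exc, acc_exc, "green_yellow"))
        expected = (out.donor_excitation.wavelengths_nm - 400.5) / 200.0
        inside = (out.donor_excitation.wavelengths_nm >= 401) & (
            out.donor_excitation.wavelengths_nm <= 598
        )
        np.testing.assert_allclose(
            out.donor_excitation.values[inside], expected[inside], atol=1e-9
        )

    def test_zero_acceptor_peak_errors(self, donor):
        zeros = _grid_spectrum(np.zeros(451))
        with pytest.raises(ValueError, match="peak"):
            align_and_normalize(CellSpectra(donor.emission, zeros, "green_yellow"))


class TestSubtractDirectExcitation:
    def test_constructed_mixture_recovers_donor(self, donor, refs):
        f_d = donor.emission.normalized("area")
        shape = refs.donor_excited_acceptor_shape
        mixed = _grid_spectrum(f_d.values + shape.values)
        cell = CellSpectra(mixed, _grid_spectrum(np.ones(451)), "green_yellow")
        out = subtract_direct_excitation(cell, refs)
        np.testing.assert_allclose(out.values, f_d.values, atol=1e-12)

    def test_pure_direct_shape_zeroes_out(self, refs):
        shape = refs.donor_excited_acceptor_shape
        cell = CellSpectra(
            _grid_spectrum(shape.values.copy()),
            _grid_spectrum(np.ones(451)),
            "green_yellow",
        )
        out = subtract_direct_excitation(cell, refs)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)


class TestUnmix:
    def test_exact_two_component_coefficients(self, donor, yellow_acceptor, refs):
        f_d = refs.donor_ref.values
        f_a = refs.acceptor_ref.values
        corrected = _grid_spectrum(0.3 * f_d + 0.7 * f_a)
        result = unmix(corrected, refs, "green_yellow")
        assert result.coefficients["donor"] == pytest.approx(0.3, abs=1e-9)
        assert result.coefficients["acceptor"] == pytest.approx(0.7, abs=1e-9)

    def test_pure_donor_gives_zero_sensitized(self, refs):
        corrected = _grid_spectrum(0.8 * refs.donor_ref.values)
        result = unmix(corrected, refs, "green_yellow")
        np.testing.assert_allclose(result.F_S, 0.0, atol=1e-9)

    def test_three_component_red_mixture(self, donor, red_acceptor, green_contaminant):
        refs = make_reference_set(donor, red_acceptor, green=green_contaminant)
        f_d = refs.donor_ref.values
        f_g = refs.green_ref.values
        f_r = refs.acceptor_ref.values
        corrected = _grid_spectrum(0.5 * f_d + 0.2 * f_g + 0.3 * f_r)
        result = unmix(corrected, refs, "orange_red_with_green")
        np.testing.assert_allclose(result.F_D, 0.5 * f_d, atol=1e-9)
        np.testing.assert_allclose(result.F_G, 0.2 * f_g, atol=1e-9)
        np.testing.assert_allclose(result.F_S, 0.3 * f_r, atol=1e-8)

    def test_collinear_references_rejected(self, donor):
        refs = ReferenceSet(
            donor_ref=donor.emission,
            acceptor_ref=donor.emission,  # identical shape → singular design
            donor_excited_acceptor_shape=donor.emission,
            q_d=0.93,
            q_a=0.68,
        )
        corrected = _grid_spectrum(refs.donor_ref.values.copy())
        with pytest.raises(ValueError, match="collinear|conditioned"):
            unmix(corrected, refs, "green_yellow")


class TestApparentEfficiency:
    def test_algebraic_identity_and_flatness(self, refs):
        # F_D = N(1-E) Q_D f_D, F_S = N E Q_A f_A → E_D(λ) = E everywhere
        E, N = 0.4, 2.7
        f_d, f_a = refs.donor_ref.values, refs.acceptor_ref.values
        corrected = _grid_spectrum(
            N * (1 - E) * refs.q_d * f_d + N * E * refs.q_a * f_a
        )
        result = unmix(corrected, refs, "green_yellow")
        e_d, e_lambda, w = apparent_efficiency(result, refs)
        assert e_d == pytest.approx(E, abs=1e-9)
        np.testing.assert_allclose(e_lambda, E, atol=1e-9)  # flat in λ
        assert w.min() >= 0

    def test_no_sensitized_emission_gives_zero(self, refs):
        corrected = _grid_spectrum(refs.q_d * refs.donor_ref.values)
        result = unmix(corrected, refs, "green_yellow")
        e_d, _, _ = apparent_efficiency(result, refs)
        assert e_d == pytest.approx(0.0, abs=1e-9)

    def test_pure_sensitized_gives_one(self, refs):
        corrected = _grid_spectrum(0.5 * refs.acceptor_ref.values)
        result = unmix(corrected, refs, "green_yellow")
        e_d, _, _ = apparent_efficiency(result, refs)
        assert e_d == pytest.approx(1.0, abs=1e-6)

    def test_intensity_scale_invariance(self, donor, yellow_acceptor):
        cell, refs, _ = gen_cell_spectra(donor, yellow_acceptor, true_E=0.42)
        e1, _ = unmix_pipeline(cell, refs)
        scaled = CellSpectra(
            replace(cell.donor_excitation, values=cell.donor_excitation.values * 37.0),
            replace(
                cell.acceptor_excitation, values=cell.acceptor_excitation.values * 37.0
            ),
            cell.acceptor_class,
        )
        e2, _ = unmix_pipeline(scaled, refs)
        assert e1 == pytest.approx(e2, abs=1e-9)

    def test_weighted_mean_bounded_by_extremes(self, refs, rng):
        f_d, f_a = refs.donor_ref.values, refs.acceptor_ref.values
        noisy = 0.4 * refs.q_d * f_d + 0.3 * refs.q_a * f_a
        noisy = np.clip(noisy + rng.normal(0, 0.02 * noisy.max(), noisy.shape), 0, None)
        result = unmix(_grid_spectrum(noisy), refs, "green_yellow")
        e_d, e_lambda, _ = apparent_efficiency(result, refs)
        assert e_lambda.min() - 1e-12 <= e_d <= e_lambda.max() + 1e-12


class TestEndToEnd:
    @pytest.mark.parametrize("true_e", [0.2, 0.42, 0.59])
    def test_noiseless_identity(self, donor, yellow_acceptor, true_e):
        cell, refs, _ = gen_cell_spectra(
            donor, yellow_acceptor, true_E=true_e, direct_excitation_fraction=0.15
        )
        e_d, _ = unmix_pipeline(cell, refs)
        assert e_d == pytest.approx(true_e, abs=1e-6)

    def test_red_class_identity(self, donor, red_acceptor, green_contaminant):
        cell, refs, _ = gen_cell_spectra(
            donor,
            red_acceptor,
            true_E=0.34,
            green_fraction=0.05,
            green=green_contaminant,
            acceptor_class="orange_red_with_green",
        )
        e_d, _ = unmix_pipeline(cell, refs)
        assert e_d == pytest.approx(0.34, abs=1e-6)

    def test_noisy_recovery_unbiased(self, donor, yellow_acceptor):
        true_e = 0.42
        estimates = []
        for seed in range(100):
            cell, refs, _ = gen_cell_spectra(
                donor, yellow_acceptor, true_E=true_e,
                noise_model="gaussian", seed=seed,
            )
            e_d, _ = unmix_pipeline(cell, refs)
            estimates.append(e_d)
        estimates = np.asarray(estimates)
        sem = estimates.std(ddof=1) / np.sqrt(estimates.size)
        assert abs(estimates.mean() - true_e) < 1.96 * sem
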