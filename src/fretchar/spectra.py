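"""Spectrum handling and Förster theory.

The theoretical quality of a FRET pair is summarised by the Förster radius
R0, the donor-acceptor distance at which half of the donor excitations are
transferred.  R0 is computed from the spectral overlap integral J(λ) of the
area-normalized donor emission with the acceptor molar extinction, the donor
quantum yield Q_D, the orientation factor κ² and the refractive index n of
the medium:

    J      = ∫ f_D(λ) ε_A(λ) λ⁴ dλ          [M⁻¹ cm⁻¹ nm⁴]
    R0⁶    = 8.79e-5 · κ² · n⁻⁴ · Q_D · J   [Å⁶]
    E(r)   = 1 / (1 + (r/R0)⁶)

This module owns the :class:`Spectrum` container, the overlap/R0 arithmetic
and a forward model for the composite emission of a donor-acceptor pair at a
given transfer efficiency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "FluorophoreRecord",
    "FretTheoryParams",
    "FretPairTheory",
    "read_spectrum",
    "resample",
    "overlap_integral",
    "forster_radius",
    "efficiency_at_distance",
    "simulate_pair_spectrum",
    "round_half_up",
]

SPECTRUM_KINDS = ("absorbance", "emission", "excitation")


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves going up."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Spectrum:
    """A sampled wavelength/value curve.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelength grid in nanometres.
    values
        Non-negative intensities; arbitrary units, or M⁻¹cm⁻¹ once an
        absorbance spectrum has been scaled to its molar extinction.
    kind
        One of ``absorbance``, ``emission``, ``excitation``.
    normalization
        ``raw``, ``peak`` (max == 1) or ``area`` (trapezoid integral == 1).
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str
    normalization: str = "raw"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if wl.ndim != 1 or wl.shape != vals.shape:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError("degenerate spectrum: need at least 2 samples")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(vals < 0):
            raise ValueError("spectrum values must be non-negative")

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    @property
    def peak_wavelength_nm(self) -> float:
        return float(self.wavelengths_nm[int(np.argmax(self.values))])

    def area(self) -> float:
        """Trapezoidal integral over the sampled grid."""
        return float(np.trapezoid(self.values, self.wavelengths_nm))

    def normalized(self, how: str) -> "Spectrum":
        """Return a copy normalized to unit peak or unit area."""
        if how == "peak":
            m = float(self.values.max())
            if m <= 0:
                raise ValueError("cannot peak-normalize an all-zero spectrum")
            return replace(self, values=self.values / m, normalization="peak")
        if how == "area":
            a = self.area()
            if a <= 0:
                raise ValueError("cannot area-normalize a zero-area spectrum")
            return replace(self, values=self.values / a, normalization="area")
        raise ValueError(f"unknown normalization {how!r}")

    def scaled(self, factor: float) -> "Spectrum":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return replace(self, values=self.values * factor, normalization="raw")


@dataclass(frozen=True)
class FluorophoreRecord:
    """Named fluorophore: spectra plus the scalar photophysics used by FRET.

    ``epsilon_max`` is the molar extinction at the absorption peak
    (M⁻¹cm⁻¹); ``quantum_yield`` is photons out per photon absorbed.
    """

    name: str
    absorption_peak_nm: float
    epsilon_max: float
    quantum_yield: float
    absorbance: Spectrum
    emission: Spectrum

    def __post_init__(self) -> None:
        if not 0.0 <= self.quantum_yield <= 1.0:
            raise ValueError("quantum yield must lie in [0, 1]")
        if self.epsilon_max <= 0:
            raise ValueError("epsilon_max must be positive")
        step = float(np.median(np.diff(self.absorbance.wavelengths_nm)))
        if abs(self.absorbance.peak_wavelength_nm - self.absorption_peak_nm) > step:
            raise ValueError(
                f"{self.name}: absorbance peak "
                f"{self.absorbance.peak_wavelength_nm:g} nm disagrees with "
                f"declared {self.absorption_peak_nm:g} nm"
            )


@dataclass(frozen=True)
class FretTheoryParams:
    """Photophysical constants entering R0: κ², n and the donor QY."""

    kappa_sq: float = 2.0 / 3.0
    refractive_index: float = 1.33
    donor_qy: float = 0.93

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa_sq <= 4.0:
            raise ValueError("kappa^2 must lie in [0, 4]")
        if self.refractive_index < 1.0:
            raise ValueError("refractive index must be >= 1")
        if not 0.0 < self.donor_qy <= 1.0:
            raise ValueError("donor quantum yield must lie in (0, 1]")


@dataclass(frozen=True)
class FretPairTheory:
    """Overlap integral and Förster radius for a donor-acceptor pair."""

    donor: FluorophoreRecord
    acceptor: FluorophoreRecord
    overlap_J: float
    R0_angstrom: float
    params: FretTheoryParams = field(default_factory=FretTheoryParams)


def read_spectrum(path: str | Path, kind: str) -> Spectrum:
    """Read a two-column (wavelength_nm, value) CSV into a Spectrum.

    A single header row is tolerated; rows are sorted by wavelength and
    duplicate wavelengths are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: degenerate input, no rows") from None
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns, found {df.shape[1]}")
    df = df.iloc[:, :2]
    # drop an optional header row; everything after it must be numeric
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        line = int(numeric.index[bad][0]) + 1
        raise ValueError(f"{path}: non-numeric row at line {line}")
    if len(numeric) < 2:
        raise ValueError(f"{path}: degenerate input, fewer than 2 data rows")
    numeric = numeric.sort_values(numeric.columns[0])
    wl = numeric.iloc[:, 0].to_numpy(dtype=float)
    steps = np.diff(wl)
    if np.any(steps == 0):
        dup = wl[:-1][steps == 0][0]
        raise ValueError(f"{path}: duplicate wavelength {dup:g} nm")
    return Spectrum(wl, numeric.iloc[:, 1].to_numpy(dtype=float), kind=kind)


def resample(
    spec: Spectrum, grid_start_nm: float, grid_end_nm: float, step_nm: float
) -> Spectrum:
    """Linearly interpolate a spectrum onto a regular grid.

    Values outside the measured support are set to zero, never extrapolated.
    """
    if step_nm <= 0:
        raise ValueError("step_nm must be positive")
    if grid_end_nm < spec.wavelengths_nm[0] or grid_start_nm > spec.wavelengths_nm[-1]:
        raise ValueError("requested grid does not overlap the spectrum support")
    n = int(round((grid_end_nm - grid_start_nm) / step_nm)) + 1
    grid = grid_start_nm + step_nm * np.arange(n)
    vals = np.interp(grid, spec.wavelengths_nm, spec.values, left=0.0, right=0.0)
    return Spectrum(grid, vals, kind=spec.kind)


def overlap_integral(
    donor_emission: Spectrum, acceptor_absorbance: Spectrum, epsilon_max: float
) -> float:
    """Spectral overlap J = ∫ f_D(λ) ε_A(λ) λ⁴ dλ in M⁻¹cm⁻¹nm⁴.

    ``donor_emission`` is area-normalized and ``acceptor_absorbance``
    peak-normalized then scaled to ``epsilon_max`` internally, so the result
    is invariant to the arbitrary amplitudes of the inputs.  Both spectra
    must share the same wavelength grid.
    """
    if epsilon_max <= 0:
        raise ValueError("epsilon_max must be positive")
    wl_d = donor_emission.wavelengths_nm
    wl_a = acceptor_absorbance.wavelengths_nm
    if wl_d.shape != wl_a.shape or not np.allclose(wl_d, wl_a):
        raise ValueError("grid mismatch: resample both spectra to a common grid")
    f_d = donor_emission.normalized("area").values
    eps = acceptor_absorbance.normalized("peak").values * epsilon_max
    j = float(np.trapezoid(f_d * eps * wl_d**4, wl_d))
    if j < -1e-12:
        raise ValueError("overlap integral came out negative")
    return max(j, 0.0)


# R0^6 prefactor for J in M^-1 cm^-1 nm^4 and R0 in Angstrom
_R0_PREFACTOR = 8.79e-5


def forster_radius(J: float, params: FretTheoryParams | None = None) -> float:
    """Förster radius in Å from the overlap integral (M⁻¹cm⁻¹nm⁴)."""
    if J < 0:
        raise ValueError("overlap integral must be non-negative")
    p = params or FretTheoryParams()
    r0_sixth = (
        _R0_PREFACTOR * p.kappa_sq * p.refractive_index**-4 * p.donor_qy * J
    )
    return r0_sixth ** (1.0 / 6.0)


def efficiency_at_distance(R0: float, r: float) -> float:
    """Transfer efficiency E = 1 / (1 + (r/R0)⁶) at separation r."""
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    if r < 0:
        raise ValueError("distance must be non-negative")
    return 1.0 / (1.0 + (r / R0) ** 6)


def pair_theory(
    donor: FluorophoreRecord,
    acceptor: FluorophoreRecord,
    params: FretTheoryParams | None = None,
    step_nm: float = 1.0,
) -> FretPairTheory:
    """Compute J and R0 for a pair from their spectra on a common 1 nm grid."""
    p = params if params is not None else FretTheoryParams(donor_qy=donor.quantum_yield)
    lo = min(donor.emission.wavelengths_nm[0], acceptor.absorbance.wavelengths_nm[0])
    hi = max(donor.emission.wavelengths_nm[-1], acceptor.absorbance.wavelengths_nm[-1])
    em = resample(donor.emission, lo, hi, step_nm)
    ab = resample(acceptor.absorbance, lo, hi, step_nm)
    j = overlap_integral(em, ab, acceptor.epsilon_max)
    return FretPairTheory(donor, acceptor, j, forster_radius(j, p), p)


def simulate_pair_spectrum(
    donor: FluorophoreRecord,
    acceptor: FluorophoreRecord,
    E: float,
    direct_excitation_fraction: float = 0.0,
) -> Spectrum:
    """Composite emission of a pair transferring a fraction E of excitations.

    Photon bookkeeping: of each donor excitation, a fraction (1-E) is emitted
    through the donor with yield Q_D and a fraction E through the acceptor
    with yield Q_A; direct excitation of the acceptor adds a further
    acceptor-shaped term.
    """
    if not 0.0 <= E <= 1.0:
        raise ValueError("E must lie in [0, 1]")
    if direct_excitation_fraction < 0:
        raise ValueError("direct excitation fraction must be non-negative")
    lo = min(donor.emission.wavelengths_nm[0], acceptor.emission.wavelengths_nm[0])
    hi = max(donor.emission.wavelengths_nm[-1], acceptor.emission.wavelengths_nm[-1])
    f_d = resample(donor.emission, lo, hi, 1.0).normalized("area")
    f_a = resample(acceptor.emission, lo, hi, 1.0).normalized("area")
    vals = (
        (1.0 - E) * donor.quantum_yield * f_d.values
        + (E + direct_excitation_fraction) * acceptor.quantum_yield * f_a.values
    )
    return Spectrum(f_d.wavelengths_nm, vals, kind="emission")
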