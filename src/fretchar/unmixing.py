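"""Spectral unmixing of sensitized emission and the apparent efficiency E_D.

A cell co-expressing a donor-acceptor fusion is imaged spectrally twice:
once under donor excitation (which also directly excites some acceptor) and
once under acceptor excitation.  After normalizing the donor-excitation
spectrum to the peak of the acceptor-excitation spectrum and subtracting
the direct-excitation contribution (measured on acceptor-only cells), the
remaining spectrum is decomposed by non-negative linear regression into a
donor component F_D(λ), a sensitized-emission component F_S(λ) and — for
orange/red acceptors with immature green species — a green component
F_G(λ).  The apparent transfer efficiency then follows per wavelength from

    E_D(λ) = 1 − F_D / ( (Q_D f_D)/(Q_A f_A) · F_S + F_D )

with f_D, f_A the area-normalized reference emission shapes, and is averaged
over a flat spectral region with weights w(λ) = f_D(λ)·f_A(λ).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import nnls
from scipy.signal import savgol_filter

from .spectra import Spectrum, resample

__all__ = [
    "ReferenceSet",
    "CellSpectra",
    "UnmixResult",
    "ACCEPTOR_CLASSES",
    "FIT_RANGES_NM",
    "align_and_normalize",
    "subtract_direct_excitation",
    "unmix",
    "apparent_efficiency",
    "unmix_pipeline",
]

ACCEPTOR_CLASSES = ("green_yellow", "orange_red_with_green", "red_no_green")

#: Wavelength windows used for the per-class regressions (nm).
FIT_RANGES_NM = {
    "green_yellow": (450.0, 650.0),
    "orange_red_with_green": (450.0, 525.0),
    "red_no_green": (450.0, 500.0),
}

#: f_A below this fraction of its peak is excluded from E_D(λ).
F_A_FLOOR = 1e-6

#: default Savitzky-Golay window (samples) for noise-robust peak picking
PEAK_SMOOTH_WINDOW = 21


def estimate_peak(values: np.ndarray, window: int = PEAK_SMOOTH_WINDOW) -> float:
    """Peak intensity of a sampled curve, read off a quadratic
    Savitzky-Golay smooth when the curve is long enough.

    The raw maximum of a noisy curve is upward-biased; the smooth trades
    that for a small curvature bias which cancels whenever sample and
    control are normalized by the same rule.
    """
    values = np.asarray(values, dtype=float)
    if window and values.size > window:
        return float(savgol_filter(values, window, 2).max())
    return float(values.max())


@dataclass(frozen=True)
class ReferenceSet:
    """Reference shapes and quantum yields needed for unmixing.

    All reference spectra are area-normalized internally.  The
    ``donor_excited_acceptor_shape`` is the spectrum of an acceptor-only
    cell under donor excitation, normalized exactly like a sample cell
    (to the peak of its own acceptor-excitation spectrum), so it can be
    subtracted from a normalized sample directly.
    """

    donor_ref: Spectrum
    acceptor_ref: Spectrum
    donor_excited_acceptor_shape: Spectrum
    q_d: float
    q_a: float
    green_ref: Spectrum | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.q_d <= 1.0 or not 0.0 < self.q_a <= 1.0:
            raise ValueError("quantum yields must lie in (0, 1]")
        object.__setattr__(self, "donor_ref", self.donor_ref.normalized("area"))
        object.__setattr__(self, "acceptor_ref", self.acceptor_ref.normalized("area"))
        if self.green_ref is not None:
            object.__setattr__(self, "green_ref", self.green_ref.normalized("area"))


@dataclass(frozen=True)
class CellSpectra:
    """Donor- and acceptor-excitation emission spectra of one cell."""

    donor_excitation: Spectrum
    acceptor_excitation: Spectrum
    acceptor_class: str

    def __post_init__(self) -> None:
        if self.acceptor_class not in ACCEPTOR_CLASSES:
            raise ValueError(f"unknown acceptor class {self.acceptor_class!r}")


@dataclass(frozen=True)
class UnmixResult:
    """Decomposition of a corrected cell spectrum into components."""

    wavelengths_nm: np.ndarray
    F_D: np.ndarray
    F_S: np.ndarray
    F_G: np.ndarray
    F_A: np.ndarray  # the direct-excitation component that was subtracted
    coefficients: dict[str, float]
    residual_norm: float


def align_and_normalize(
    cell: CellSpectra, step_nm: float = 1.0, peak_smooth_window: int = PEAK_SMOOTH_WINDOW
) -> CellSpectra:
    """Put both spectra on a common grid and apply the peak normalization.

    The donor-excitation spectrum is divided by the peak intensity of the
    acceptor-excitation spectrum, which expresses everything per unit of
    acceptor and makes cells with different expression levels comparable.
    The peak is read off a Savitzky-Golay-smoothed copy (quadratic,
    ``peak_smooth_window`` samples): the raw maximum of a noisy spectrum is
    upward-biased, which would systematically over-subtract the
    direct-excitation component downstream.  Set the window to 0 to use the
    raw maximum.
    """
    don, acc = cell.donor_excitation, cell.acceptor_excitation
    lo = max(don.wavelengths_nm[0], acc.wavelengths_nm[0])
    hi = min(don.wavelengths_nm[-1], acc.wavelengths_nm[-1])
    if hi <= lo:
        raise ValueError("spectra do not overlap in wavelength")
    don = resample(don, lo, hi, step_nm)
    acc = resample(acc, lo, hi, step_nm)
    peak = estimate_peak(acc.values, peak_smooth_window)
    if peak <= 0:
        raise ValueError("acceptor-excitation spectrum has zero peak")
    don = replace(don, values=don.values / peak)
    return CellSpectra(don, acc, cell.acceptor_class)


def subtract_direct_excitation(cell: CellSpectra, refs: ReferenceSet) -> Spectrum:
    """Remove the directly excited acceptor contribution.

    The acceptor-only control shape is already expressed per unit of
    acceptor-excitation peak, so after :func:`align_and_normalize` the
    subtraction is a plain per-wavelength difference.  Negative residuals
    from noise are kept (the regressions tolerate them).
    """
    if refs.donor_excited_acceptor_shape is None:
        raise ValueError("acceptor-only control spectrum is required")
    f = cell.donor_excitation
    shape = resample(
        refs.donor_excited_acceptor_shape,
        f.wavelengths_nm[0],
        f.wavelengths_nm[-1],
        float(f.wavelengths_nm[1] - f.wavelengths_nm[0]),
    )
    corrected = f.values - shape.values
    # Spectrum forbids negative values by contract; carry the corrected
    # curve as plain arrays wrapped after clipping tiny negative noise.
    return Spectrum(
        f.wavelengths_nm, np.clip(corrected, 0.0, None), kind="emission"
    )


def _on_grid(spec: Spectrum, grid: np.ndarray) -> np.ndarray:
    return np.interp(grid, spec.wavelengths_nm, spec.values, left=0.0, right=0.0)


def unmix(
    corrected: Spectrum, refs: ReferenceSet, acceptor_class: str
) -> UnmixResult:
    """Non-negative least-squares decomposition of a corrected spectrum.

    green_yellow
        regress donor + acceptor shapes over 450-650 nm; the acceptor
        coefficient times its shape is the sensitized emission.
    orange_red_with_green
        regress donor + green (EGFP) shapes over 450-525 nm; sensitized
        emission is the remainder of the spectrum.
    red_no_green
        regress the donor shape alone over 450-500 nm; sensitized emission
        is the remainder.
    """
    if acceptor_class not in ACCEPTOR_CLASSES:
        raise ValueError(f"unknown acceptor class {acceptor_class!r}")
    grid = corrected.wavelengths_nm
    lo, hi = FIT_RANGES_NM[acceptor_class]
    window = (grid >= lo) & (grid <= hi)
    if not window.any():
        raise ValueError("fit range does not intersect the spectrum grid")
    f_d = _on_grid(refs.donor_ref, grid)
    f_a = _on_grid(refs.acceptor_ref, grid)

    columns = [f_d]
    names = ["donor"]
    if acceptor_class == "green_yellow":
        columns.append(f_a)
        names.append("acceptor")
    elif acceptor_class == "orange_red_with_green":
        if refs.green_ref is None:
            raise ValueError("orange_red_with_green requires a green reference")
        columns.append(_on_grid(refs.green_ref, grid))
        names.append("green")
    design = np.column_stack([c[window] for c in columns])
    cond = np.linalg.cond(design.T @ design)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("collinear reference spectra: unmixing is ill-conditioned")
    coef, rnorm = nnls(design, corrected.values[window])

    coefficients = dict(zip(names, (float(c) for c in coef)))
    F_D = coefficients["donor"] * f_d
    if acceptor_class == "green_yellow":
        F_G = np.zeros_like(grid)
        F_S = coefficients["acceptor"] * f_a
    elif acceptor_class == "orange_red_with_green":
        F_G = coefficients["green"] * _on_grid(refs.green_ref, grid)
        F_S = corrected.values - F_D - F_G
    else:
        F_G = np.zeros_like(grid)
        F_S = corrected.values - F_D
    return UnmixResult(
        wavelengths_nm=grid,
        F_D=F_D,
        F_S=F_S,
        F_G=F_G,
        F_A=np.zeros_like(grid),
        coefficients=coefficients,
        residual_norm=float(rnorm),
    )


def _default_flat_region(
    result: UnmixResult, refs: ReferenceSet, acceptor_class: str
) -> tuple[float, float]:
    """Wavelengths where both reference shapes exceed 1% of their maxima,
    intersected with the class fit window when that intersection exists.

    Red acceptors barely emit inside their (blue) regression window, so for
    them the flat region falls back to the unrestricted donor/acceptor
    overlap — E_D(λ) is defined wherever both shapes carry signal, not only
    where the donor was regressed.
    """
    grid = result.wavelengths_nm
    f_d = _on_grid(refs.donor_ref, grid)
    f_a = _on_grid(refs.acceptor_ref, grid)
    overlap = (f_d > 0.01 * f_d.max()) & (f_a > 0.01 * f_a.max())
    lo, hi = FIT_RANGES_NM[acceptor_class]
    ok = overlap & (grid >= lo) & (grid <= hi)
    if not ok.any():
        ok = overlap
    if not ok.any():
        raise ValueError("no flat region: reference shapes do not overlap")
    return float(grid[ok][0]), float(grid[ok][-1])


def apparent_efficiency(
    result: UnmixResult,
    refs: ReferenceSet,
    flat_region_nm: tuple[float, float] | None = None,
    acceptor_class: str = "green_yellow",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Weighted-average apparent FRET efficiency E_D (fraction).

    Returns ``(E_D, E_D_lambda, weights)``.  Wavelengths where the acceptor
    reference falls below :data:`F_A_FLOOR` of its peak are excluded before
    forming the Q_D f_D / (Q_A f_A) ratio.
    """
    if flat_region_nm is None:
        flat_region_nm = _default_flat_region(result, refs, acceptor_class)
    grid = result.wavelengths_nm
    f_d = _on_grid(refs.donor_ref, grid)
    f_a = _on_grid(refs.acceptor_ref, grid)
    lo, hi = flat_region_nm
    sel = (grid >= lo) & (grid <= hi) & (f_a > F_A_FLOOR * f_a.max())
    if not sel.any():
        raise ValueError("flat region is empty after the acceptor floor filter")
    f_d, f_a = f_d[sel], f_a[sel]
    F_D, F_S = result.F_D[sel], result.F_S[sel]
    ratio = (refs.q_d * f_d) / (refs.q_a * f_a)
    denom = ratio * F_S + F_D
    with np.errstate(divide="ignore", invalid="ignore"):
        e_lambda = np.where(denom > 0, 1.0 - F_D / denom, 0.0)
    w = f_d * f_a
    e_d = float(np.sum(w * e_lambda) / np.sum(w))
    return e_d, e_lambda, w


def unmix_pipeline(
    cell: CellSpectra,
    refs: ReferenceSet,
    flat_region_nm: tuple[float, float] | None = None,
) -> tuple[float, UnmixResult]:
    """Full chain: align/normalize, subtract direct excitation, unmix, E_D."""
    aligned = align_and_normalize(cell)
    corrected = subtract_direct_excitation(aligned, refs)
    result = unmix(corrected, refs, cell.acceptor_class)
    e_d, _, _ = apparent_efficiency(
        result, refs, flat_region_nm, acceptor_class=cell.acceptor_class
    )
    return e_d, result
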