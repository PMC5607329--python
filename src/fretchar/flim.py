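"""Frequency-domain FLIM: phasor fits, calibration and lifetimes.

In homodyne frequency-domain FLIM the sample is excited with light modulated
at an RF frequency f (here typically 75.1 or 40 MHz) and a stack of K images
is recorded at detector phase steps θ_k.  Each pixel traces

    I_k = DC + AC·cos(θ_k − φ)

and the fluorescence lifetime enters through the phase shift φ and the
demodulation M = AC/DC relative to the excitation:

    τφ = tan(φ) / ω          τM = sqrt(1/M² − 1) / ω          ω = 2πf

For a mono-exponential decay τφ == τM; for mixtures τφ < τM.  A reference
measurement with known lifetime removes the instrument's phase offset and
modulation factor.  FRET quenches the donor, so the transfer efficiency
follows from the donor lifetime with (DA) and without (D) acceptor:
E = 1 − τ_DA/τ_D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "PhaseStack",
    "PhasorEstimate",
    "CalibrationReference",
    "LifetimePair",
    "EfficiencyResult",
    "fit_phasor",
    "calibrate",
    "lifetimes_from_phasor",
    "fret_efficiency_from_lifetime",
    "roi_lifetime_timecourse",
    "phasor_coordinates",
    "mix_phasors",
]

TWO_PI = 2.0 * math.pi

#: AC/DC below this is treated as an undefined phase (constant signal).
UNDEFINED_PHASE_FLOOR = 1e-3


@dataclass(frozen=True)
class PhaseStack:
    """K phase-modulated intensity frames plus their acquisition metadata."""

    frames: np.ndarray  # (K, ...) photon counts or intensities
    phase_steps_rad: np.ndarray  # (K,) detector phase angles
    modulation_frequency_hz: float
    acquisition_order: np.ndarray | None = None  # permutation of 0..K-1

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        steps = np.mod(np.asarray(self.phase_steps_rad, dtype=float), TWO_PI)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "phase_steps_rad", steps)
        if steps.ndim != 1 or frames.shape[0] != steps.size:
            raise ValueError("one phase step per frame required")
        if steps.size < 3:
            raise ValueError("need at least 3 phase steps")
        if np.unique(steps).size != steps.size:
            raise ValueError("phase steps must be distinct")
        if np.any(frames < 0):
            raise ValueError("frames must be non-negative")
        if self.acquisition_order is not None:
            order = np.asarray(self.acquisition_order)
            object.__setattr__(self, "acquisition_order", order)
            if sorted(order.tolist()) != list(range(steps.size)):
                raise ValueError("acquisition_order must be a permutation of 0..K-1")

    @property
    def omega(self) -> float:
        return TWO_PI * self.modulation_frequency_hz


@dataclass(frozen=True)
class PhasorEstimate:
    """First-harmonic summary of a phase stack: DC, AC, phase.

    Fields may be scalars or per-pixel arrays; ``undefined`` flags pixels
    whose AC/DC fell below :data:`UNDEFINED_PHASE_FLOOR`.
    """

    dc: np.ndarray | float
    ac: np.ndarray | float
    phase_rad: np.ndarray | float
    undefined: np.ndarray | bool = False

    @property
    def modulation_depth(self) -> np.ndarray | float:
        return self.ac / np.where(np.asarray(self.dc) > 0, self.dc, np.nan)

    @property
    def g(self) -> np.ndarray | float:
        """Phasor abscissa G = M·cos(φ)."""
        return self.modulation_depth * np.cos(self.phase_rad)

    @property
    def s(self) -> np.ndarray | float:
        """Phasor ordinate S = M·sin(φ)."""
        return self.modulation_depth * np.sin(self.phase_rad)


@dataclass(frozen=True)
class CalibrationReference:
    """Measured phasor of a reference sample with known lifetimes (ns)."""

    measured: PhasorEstimate
    known_tau_phase_ns: float
    known_tau_mod_ns: float

    def __post_init__(self) -> None:
        if self.known_tau_phase_ns < 0 or self.known_tau_mod_ns < 0:
            raise ValueError("reference lifetimes must be non-negative")


@dataclass(frozen=True)
class LifetimePair:
    tau_phase_ns: float
    tau_mod_ns: float


@dataclass(frozen=True)
class EfficiencyResult:
    e_phase_pct: float
    e_mod_pct: float
    donor_reference: LifetimePair


def phasor_coordinates(tau_ns: float, frequency_hz: float) -> tuple[float, float]:
    """(φ, M) of a mono-exponential decay: φ=arctan(ωτ), M=1/sqrt(1+(ωτ)²)."""
    wt = TWO_PI * frequency_hz * tau_ns * 1e-9
    return math.atan(wt), 1.0 / math.sqrt(1.0 + wt * wt)


def mix_phasors(
    taus_ns: np.ndarray, weights: np.ndarray, frequency_hz: float
) -> tuple[float, float]:
    """Phasor of a lifetime mixture, weighted by steady-state (DC) intensity.

    Component phasors add linearly in (G, S); returns the mixture's (φ, M).
    """
    taus = np.asarray(taus_ns, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    g = s = 0.0
    for tau, wk in zip(taus, w):
        phi, m = phasor_coordinates(tau, frequency_hz)
        g += wk * m * math.cos(phi)
        s += wk * m * math.sin(phi)
    return math.atan2(s, g) % TWO_PI, math.hypot(g, s)


def fit_phasor(stack: PhaseStack, pixel_mask: np.ndarray | None = None) -> PhasorEstimate:
    """Least-squares first-harmonic fit of I_k = DC + AC·cos(θ_k − φ).

    Solved on the linear design (1, cos θ_k, sin θ_k); for equally spaced
    steps this coincides with the discrete Fourier coefficients.  The result
    depends only on the (θ_k, frame) pairing, never on acquisition order.
    """
    theta = stack.phase_steps_rad
    design = np.column_stack([np.ones_like(theta), np.cos(theta), np.sin(theta)])
    frames = stack.frames
    flat = frames.reshape(frames.shape[0], -1)
    coef, *_ = np.linalg.lstsq(design, flat, rcond=None)
    shape = frames.shape[1:] if frames.ndim > 1 else ()
    dc = coef[0].reshape(shape) if shape else float(coef[0, 0])
    b = coef[1].reshape(shape) if shape else float(coef[1, 0])
    c = coef[2].reshape(shape) if shape else float(coef[2, 0])
    ac = np.hypot(b, c)
    phase = np.mod(np.arctan2(c, b), TWO_PI)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(np.asarray(dc) > 0, ac / np.maximum(dc, 1e-300), 0.0)
    undefined = rel < UNDEFINED_PHASE_FLOOR
    phase = np.where(undefined, 0.0, phase)
    if pixel_mask is not None:
        undefined = undefined | ~np.asarray(pixel_mask, dtype=bool)
    if not shape:
        return PhasorEstimate(float(dc), float(ac), float(phase), bool(undefined))
    return PhasorEstimate(dc, np.asarray(ac), np.asarray(phase), undefined)


def calibrate(
    sample: PhasorEstimate,
    ref: CalibrationReference,
    modulation_frequency_hz: float,
) -> PhasorEstimate:
    """Remove the instrument phase offset and modulation factor.

    The reference's true phasor is computed from its known lifetimes; the
    difference between its measured and true phasor is the instrument
    response, which is divided out of the sample.
    """
    phi_true, _ = phasor_coordinates(ref.known_tau_phase_ns, modulation_frequency_hz)
    _, m_true = phasor_coordinates(ref.known_tau_mod_ns, modulation_frequency_hz)
    m_meas = ref.measured.modulation_depth
    if np.any(np.asarray(m_meas) <= 0) or np.any(np.isnan(np.asarray(m_meas))):
        raise ValueError("reference modulation depth must be positive")
    phase_offset = ref.measured.phase_rad - phi_true
    mod_factor = m_meas / m_true
    phase = np.mod(sample.phase_rad - phase_offset, TWO_PI)
    ac = sample.ac / mod_factor
    return PhasorEstimate(sample.dc, ac, phase, sample.undefined)


def lifetimes_from_phasor(
    p: PhasorEstimate, modulation_frequency_hz: float, tol: float = 1e-6
) -> LifetimePair:
    """Phase and modulation lifetimes (ns) from a calibrated phasor."""
    omega = TWO_PI * modulation_frequency_hz
    phi = float(np.asarray(p.phase_rad))
    m = float(np.asarray(p.modulation_depth))
    # wrap phases just above 2π-ε back to small negatives for robustness
    if phi > math.pi:
        phi -= TWO_PI
    if phi >= math.pi / 2:
        raise ValueError("unphysical phase >= pi/2: check calibration")
    if m > 1.0 + tol:
        raise ValueError(f"unphysical modulation depth {m:.6f} > 1")
    m = min(m, 1.0)
    tau_phi = math.tan(phi) / omega * 1e9
    tau_m = math.sqrt(max(1.0 / (m * m) - 1.0, 0.0)) / omega * 1e9
    return LifetimePair(tau_phi, tau_m)


def fret_efficiency_from_lifetime(tau_da_ns: float, tau_d_ns: float) -> float:
    """FRET efficiency in percent: E = (1 − τ_DA/τ_D)·100.

    A quenched donor has τ_DA < τ_D; τ_DA > τ_D yields a negative E, which
    is reported as-is (it signals dequenching or an artifact).
    """
    if tau_d_ns <= 0:
        raise ValueError("donor-only lifetime must be positive")
    if tau_da_ns < 0:
        raise ValueError("donor lifetime must be non-negative")
    return (1.0 - tau_da_ns / tau_d_ns) * 100.0


def roi_phasor(estimate: PhasorEstimate, roi_mask: np.ndarray) -> PhasorEstimate:
    """Average a per-pixel phasor map over an ROI in (G, S) coordinates.

    Averaging in phasor space keeps the estimate unbiased; lifetimes are
    nonlinear in (G, S) so per-pixel lifetimes must not be averaged.
    """
    mask = np.asarray(roi_mask, dtype=bool) & ~np.asarray(estimate.undefined)
    if not mask.any():
        raise ValueError("empty ROI: no defined pixels to average")
    g = float(np.mean(np.asarray(estimate.g)[mask]))
    s = float(np.mean(np.asarray(estimate.s)[mask]))
    dc = float(np.mean(np.asarray(estimate.dc)[mask]))
    m = math.hypot(g, s)
    return PhasorEstimate(dc, dc * m, math.atan2(s, g) % TWO_PI, False)


def roi_lifetime_timecourse(
    stacks: list[PhaseStack],
    ref: CalibrationReference,
    roi_mask: np.ndarray,
    background_mask: np.ndarray | None = None,
    smoothing: str = "none",
) -> list[LifetimePair]:
    """Per-timepoint ROI-averaged lifetimes from a series of phase stacks.

    Each stack is background-subtracted (mean over ``background_mask`` per
    frame), optionally 3x3 mean-blurred, phasor-fitted, calibrated and
    averaged over the ROI before conversion to lifetimes.  The resulting
    τφ(t) trace is the raw material for agonist/antagonist step analysis.
    """
    if smoothing not in ("none", "3x3"):
        raise ValueError("smoothing must be 'none' or '3x3'")
    out: list[LifetimePair] = []
    for stack in stacks:
        frames = stack.frames
        if background_mask is not None:
            bg = frames[:, np.asarray(background_mask, dtype=bool)].mean(axis=1)
            frames = np.clip(frames - bg[:, None, None], 0.0, None)
        if smoothing == "3x3":
            frames = uniform_filter(frames, size=(1, 3, 3), mode="nearest")
        cleaned = PhaseStack(
            frames, stack.phase_steps_rad, stack.modulation_frequency_hz
        )
        est = fit_phasor(cleaned)
        est = calibrate(est, ref, stack.modulation_frequency_hz)
        avg = roi_phasor(est, roi_mask)
        out.append(lifetimes_from_phasor(avg, stack.modulation_frequency_hz))
    return out
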