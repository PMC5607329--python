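"""Synthetic-data generators standing in for the microscope.

Every input the analysis modules consume can be generated here with known
ground truth: fluorophore spectra with realistic Stokes shifts, homodyne
FD-FLIM phase stacks for known lifetime mixtures with photon noise and
instrument distortion, mixed single-cell emission spectra for a known true
FRET efficiency, donor-dequenching bleach traces and agonist/antagonist
biosensor step responses.  All generators are deterministic under a fixed
seed.

Defaults mirror the acquisition conditions of the study this toolkit
models: 75.1 MHz modulation with 12 phase steps, ~1e4 counts per pixel,
420 nm-excitation bleaches probed at 48 s and 900 s, agonist at ~44 s and
antagonist at ~150 s of a 240 s ratio recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .flim import PhaseStack, mix_phasors, phasor_coordinates
from .spectra import FluorophoreRecord, Spectrum
from .traces import IntensityTrace
from .unmixing import CellSpectra, ReferenceSet

__all__ = [
    "GroundTruth",
    "gen_spectra",
    "gen_phase_stack",
    "gen_cell_spectra",
    "gen_bleach_trace",
    "gen_gpcr_trace",
    "make_reference_set",
]

_GRID_NM = np.arange(350.0, 801.0, 1.0)


@dataclass(frozen=True)
class GroundTruth:
    """What a generator actually put into its output."""

    true_E: float | None = None
    true_tau_ns: tuple[float, ...] = ()
    tau_weights: tuple[float, ...] = ()
    true_components: dict[str, float] = field(default_factory=dict)
    bleach_rates: dict[str, float] = field(default_factory=dict)
    event_times_s: dict[str, float] = field(default_factory=dict)


def _skewed_band(peak_nm: float, width_nm: float, asymmetry: float) -> np.ndarray:
    """Smooth skewed band on the common grid: a log-normal-like profile in
    wavelength whose mode sits exactly at ``peak_nm``."""
    if width_nm <= 0:
        raise ValueError("width must be positive")
    x = (_GRID_NM - peak_nm) / width_nm
    if abs(asymmetry) < 1e-12:
        return np.exp(-0.5 * x * x)
    arg = 1.0 + asymmetry * x
    vals = np.zeros_like(x)
    ok = arg > 0
    vals[ok] = np.exp(-0.5 * (np.log(arg[ok]) / asymmetry) ** 2)
    return vals


def gen_spectra(
    peaks_nm: tuple[float, float],
    widths_nm: tuple[float, float] = (25.0, 20.0),
    asymmetry: tuple[float, float] = (-0.25, 0.3),
    epsilon_max: float = 1.0e5,
    qy: float = 0.7,
    name: str = "synthetic",
    seed: int | None = None,
) -> FluorophoreRecord:
    """Generate a fluorophore with skewed-Gaussian absorbance and emission.

    ``peaks_nm`` is (absorption peak, emission peak); the Stokes shift must
    be positive.  ``seed`` is accepted for interface symmetry — the spectra
    themselves are deterministic shapes.
    """
    abs_peak, em_peak = peaks_nm
    if em_peak <= abs_peak:
        raise ValueError("emission peak must be red of the absorption peak")
    absorbance = Spectrum(
        _GRID_NM.copy(), _skewed_band(abs_peak, widths_nm[0], asymmetry[0]), "absorbance"
    )
    emission = Spectrum(
        _GRID_NM.copy(), _skewed_band(em_peak, widths_nm[1], asymmetry[1]), "emission"
    )
    return FluorophoreRecord(
        name=name,
        absorption_peak_nm=abs_peak,
        epsilon_max=epsilon_max,
        quantum_yield=qy,
        absorbance=absorbance,
        emission=emission,
    )


def gen_phase_stack(
    tau_components_ns: tuple[float, ...] = (3.8,),
    weights: tuple[float, ...] = (1.0,),
    f_hz: float = 75.1e6,
    k_steps: int = 12,
    counts_per_pixel: float = 1.0e4,
    shape: tuple[int, int] = (16, 16),
    instrument_phase_rad: float = 0.0,
    instrument_mod_factor: float = 1.0,
    order: str = "sequential",
    noise_model: str = "none",
    seed: int = 0,
    reference_tau_ns: float = 3.8,
) -> tuple[PhaseStack, PhaseStack, GroundTruth]:
    """Homodyne phase stack for a lifetime mixture, plus a matched reference.

    Frames follow I_k = DC·(1 + M·cos(θ_k − φ)) with (φ, M) the DC-weighted
    phasor mixture of the components, shifted by the instrument phase offset
    and scaled by the instrument modulation factor.  The reference stack is
    generated from ``reference_tau_ns`` with identical distortions, which is
    exactly what calibration assumes.
    """
    if k_steps < 3:
        raise ValueError("need at least 3 phase steps")
    if counts_per_pixel <= 0:
        raise ValueError("counts_per_pixel must be positive")
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    rng = np.random.default_rng(seed)
    theta = 2.0 * math.pi * np.arange(k_steps) / k_steps
    if order == "random":
        acq = rng.permutation(k_steps)
    else:
        acq = np.arange(k_steps)

    def frames_for(phi: float, m: float) -> np.ndarray:
        phi_obs = phi + instrument_phase_rad
        m_obs = m * instrument_mod_factor
        ideal = counts_per_pixel * (1.0 + m_obs * np.cos(theta - phi_obs))
        stack = np.broadcast_to(ideal[:, None, None], (k_steps, *shape)).copy()
        if noise_model == "poisson":
            stack = rng.poisson(stack).astype(float)
        elif noise_model.startswith("gaussian"):
            sigma = 0.01 * counts_per_pixel
            stack = np.clip(stack + rng.normal(0.0, sigma, stack.shape), 0.0, None)
        elif noise_model != "none":
            raise ValueError(f"unknown noise model {noise_model!r}")
        return stack

    phi_mix, m_mix = mix_phasors(np.asarray(tau_components_ns), w, f_hz)
    phi_ref, m_ref = phasor_coordinates(reference_tau_ns, f_hz)
    sample = PhaseStack(frames_for(phi_mix, m_mix), theta, f_hz, acq)
    reference = PhaseStack(frames_for(phi_ref, m_ref), theta, f_hz)
    truth = GroundTruth(
        true_tau_ns=tuple(float(t) for t in tau_components_ns),
        tau_weights=tuple(float(x) for x in w),
    )
    return sample, reference, truth


def make_reference_set(
    donor: FluorophoreRecord,
    acceptor: FluorophoreRecord,
    direct_excitation_fraction: float = 0.1,
    acceptor_excitation_strength: float = 1.0,
    green: FluorophoreRecord | None = None,
) -> ReferenceSet:
    """Build the unmixing references consistent with :func:`gen_cell_spectra`.

    The acceptor-only control under donor excitation has, per unit of
    acceptor-excitation peak, the shape
    (direct fraction / excitation strength) · f_A / peak(f_A) — the same
    for every cell because both terms scale with acceptor abundance.  The
    peak is estimated with the same smoothed-peak rule the unmixing
    normalization uses, so the two normalizations cancel exactly.
    """
    from .unmixing import estimate_peak

    f_a = acceptor.emission.normalized("area")
    shape_vals = (
        direct_excitation_fraction
        / acceptor_excitation_strength
        * f_a.values
        / estimate_peak(f_a.values)
    )
    return ReferenceSet(
        donor_ref=donor.emission,
        acceptor_ref=acceptor.emission,
        donor_excited_acceptor_shape=Spectrum(
            f_a.wavelengths_nm.copy(), shape_vals, "emission"
        ),
        q_d=donor.quantum_yield,
        q_a=acceptor.quantum_yield,
        green_ref=green.emission if green is not None else None,
    )


def gen_cell_spectra(
    donor: FluorophoreRecord,
    acceptor: FluorophoreRecord,
    true_E: float = 0.42,
    donor_abundance: float = 1.0,
    direct_excitation_fraction: float = 0.1,
    acceptor_excitation_strength: float = 1.0,
    green_fraction: float = 0.0,
    green: FluorophoreRecord | None = None,
    acceptor_class: str = "green_yellow",
    noise_model: str = "none",
    noise_sigma_frac: float = 0.01,
    seed: int = 0,
) -> tuple[CellSpectra, ReferenceSet, GroundTruth]:
    """Single-cell donor- and acceptor-excitation spectra for a known E.

    Under donor excitation:
    F(λ) = N·(1−E)·Q_D·f_D + N·E·Q_A·f_A + N·direct·Q_A·f_A [+ green term],
    with N the number of excited donor/acceptor fusions.  Under acceptor
    excitation the same N acceptors emit with strength
    ``acceptor_excitation_strength``.  Gaussian noise (σ = 1% of peak by
    default) emulates shot/readout noise of the spectrograph.
    """
    if not 0.0 <= true_E <= 1.0:
        raise ValueError("true_E must lie in [0, 1]")
    if direct_excitation_fraction < 0 or green_fraction < 0:
        raise ValueError("fractions must be non-negative")
    rng = np.random.default_rng(seed)
    n = donor_abundance
    f_d = donor.emission.normalized("area")
    f_a = acceptor.emission.normalized("area")
    grid = f_d.wavelengths_nm
    if grid.shape != f_a.wavelengths_nm.shape or not np.allclose(
        grid, f_a.wavelengths_nm
    ):
        raise ValueError("donor and acceptor spectra must share a grid")
    donor_exc = n * (
        (1.0 - true_E) * donor.quantum_yield * f_d.values
        + true_E * acceptor.quantum_yield * f_a.values
        + direct_excitation_fraction * acceptor.quantum_yield * f_a.values
    )
    components = {
        "donor": n * (1.0 - true_E) * donor.quantum_yield,
        "sensitized": n * true_E * acceptor.quantum_yield,
        "direct": n * direct_excitation_fraction * acceptor.quantum_yield,
    }
    if green_fraction > 0:
        if green is None:
            raise ValueError("green_fraction > 0 requires a green fluorophore")
        f_g = green.emission.normalized("area")
        donor_exc = donor_exc + n * green_fraction * f_g.values
        components["green"] = n * green_fraction
    acceptor_exc = (
        acceptor_excitation_strength * n * acceptor.quantum_yield * f_a.values
    )
    if noise_model.startswith("gaussian"):
        donor_exc = np.clip(
            donor_exc + rng.normal(0, noise_sigma_frac * donor_exc.max(), grid.shape),
            0.0,
            None,
        )
        acceptor_exc = np.clip(
            acceptor_exc
            + rng.normal(0, noise_sigma_frac * acceptor_exc.max(), grid.shape),
            0.0,
            None,
        )
    elif noise_model != "none":
        raise ValueError(f"unknown noise model {noise_model!r}")
    cell = CellSpectra(
        donor_excitation=Spectrum(grid.copy(), donor_exc, "emission"),
        acceptor_excitation=Spectrum(grid.copy(), acceptor_exc, "emission"),
        acceptor_class=acceptor_class,
    )
    refs = make_reference_set(
        donor,
        acceptor,
        direct_excitation_fraction,
        acceptor_excitation_strength,
        green=green,
    )
    return cell, refs, GroundTruth(true_E=true_E, true_components=components)


def _survival(t: np.ndarray, rates: tuple[float, ...], weights: tuple[float, ...]) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    return sum(wk * np.exp(-k * t) for wk, k in zip(w, rates))


def gen_bleach_trace(
    E0: float = 0.4,
    acceptor_bleach_rates: tuple[float, ...] = (math.log(2) / 450.0,),
    acceptor_bleach_weights: tuple[float, ...] = (1.0,),
    donor_intrinsic_bleach_rate: float = 0.0,
    direct_excitation_fraction: float = 0.1,
    acceptor_qy: float = 0.7,
    duration_s: float = 900.0,
    dt_s: float = 4.0,
    noise_model: str = "none",
    noise_sigma_frac: float = 0.01,
    seed: int = 0,
) -> tuple[IntensityTrace, GroundTruth]:
    """Donor-dequenching bleach trace under continuous donor excitation.

    The acceptor pool survives as a(t) (mono- or bi-exponential).  Donor
    emission is proportional to (1 − E0·a(t)) — quenching relaxes as
    acceptors die — times the donor's own bleach survival; the acceptor
    channel collects sensitized plus directly excited emission, both ∝ a(t).
    """
    if not 0.0 <= E0 < 1.0:
        raise ValueError("E0 must lie in [0, 1)")
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    if any(k < 0 for k in acceptor_bleach_rates) or donor_intrinsic_bleach_rate < 0:
        raise ValueError("bleach rates must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    a = _survival(t, acceptor_bleach_rates, acceptor_bleach_weights)
    donor = (1.0 - E0 * a) * np.exp(-donor_intrinsic_bleach_rate * t)
    acceptor = (E0 + direct_excitation_fraction) * acceptor_qy * a
    if noise_model.startswith("gaussian"):
        donor = np.clip(donor + rng.normal(0, noise_sigma_frac, t.shape), 1e-12, None)
        acceptor = np.clip(
            acceptor + rng.normal(0, noise_sigma_frac * acceptor.max(), t.shape),
            1e-12,
            None,
        )
    elif noise_model != "none":
        raise ValueError(f"unknown noise model {noise_model!r}")
    trace = IntensityTrace(time_s=t, donor=donor, acceptor=acceptor)
    truth = GroundTruth(
        true_E=E0,
        bleach_rates={
            "acceptor": float(acceptor_bleach_rates[0]),
            "donor": donor_intrinsic_bleach_rate,
        },
    )
    return trace, truth


def gen_gpcr_trace(
    baseline_E: float = 0.30,
    activated_E: float = 0.21,
    agonist_s: float = 44.0,
    antagonist_s: float = 150.0,
    transition_tau_s: float = 3.0,
    duration_s: float = 240.0,
    dt_s: float = 2.0,
    acceptor_qy: float = 0.7,
    noise_model: str = "none",
    noise_sigma_frac: float = 0.005,
    seed: int = 0,
) -> tuple[IntensityTrace, GroundTruth]:
    """Biosensor step response: FRET drops on agonist, recovers on antagonist.

    E(t) relaxes exponentially between levels at each event; donor emission
    is ∝ (1 − E(t)) and the acceptor channel ∝ E(t)·Q_A, so receptor
    activation shows as a donor rise by (1−E_act)/(1−E_base).
    """
    if not 0.0 <= activated_E <= baseline_E < 1.0:
        raise ValueError("need 0 <= activated_E <= baseline_E < 1")
    if not 0.0 <= agonist_s < antagonist_s <= duration_s:
        raise ValueError("events must be ordered within the recording")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    e = np.full_like(t, baseline_E)
    during = (t >= agonist_s) & (t < antagonist_s)
    e[during] = activated_E + (baseline_E - activated_E) * np.exp(
        -(t[during] - agonist_s) / transition_tau_s
    )
    after = t >= antagonist_s
    e_at_antagonist = activated_E + (baseline_E - activated_E) * math.exp(
        -(antagonist_s - agonist_s) / transition_tau_s
    )
    e[after] = baseline_E - (baseline_E - e_at_antagonist) * np.exp(
        -(t[after] - antagonist_s) / transition_tau_s
    )
    donor = 1.0 - e
    acceptor = e * acceptor_qy
    if noise_model.startswith("gaussian"):
        donor = np.clip(donor + rng.normal(0, noise_sigma_frac, t.shape), 1e-12, None)
        acceptor = np.clip(
            acceptor + rng.normal(0, noise_sigma_frac, t.shape), 1e-12, None
        )
    elif noise_model != "none":
        raise ValueError(f"unknown noise model {noise_model!r}")
    trace = IntensityTrace(
        time_s=t,
        donor=donor,
        acceptor=acceptor,
        agonist_s=agonist_s,
        antagonist_s=antagonist_s,
    )
    truth = GroundTruth(
        true_E=baseline_E,
        true_components={"activated_E": activated_E},
        event_times_s={"agonist_s": agonist_s, "antagonist_s": antagonist_s},
    )
    return trace, truth
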