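# fretchar

A toolkit for characterizing FRET donor–acceptor pairs of fluorescent
proteins, built around the cyan donor mTurquoise2 and the green-to-far-red
acceptors used with it.  It is aimed at microscopists and probe engineers
who need to go from raw spectra, frequency-domain FLIM phase stacks and
two-channel time series to the quantities that decide whether a FRET pair
is any good: the Förster radius, the lifetime-based FRET efficiency, the
sensitized-emission ("apparent") efficiency, photostability under FRET
imaging conditions, and biosensor dynamic range.

## What it computes

**Förster theory.** From an area-normalized donor emission `f_D(λ)` and an
acceptor extinction spectrum scaled to `ε_max`:

    J  = ∫ f_D(λ) ε_A(λ) λ⁴ dλ                     (M⁻¹ cm⁻¹ nm⁴)
    R0⁶ = 8.79×10⁻⁵ · κ² · n⁻⁴ · Q_D · J            (Å⁶)
    E(r) = 1 / (1 + (r/R0)⁶)

with defaults κ² = 2/3, n = 1.33, Q_D = 0.93.

**Frequency-domain FLIM.** Per-pixel harmonic fits of homodyne phase
stacks `I_k = DC + AC·cos(θ_k − φ)`, reference-based calibration, phase and
modulation lifetimes `τφ = tan(φ)/ω`, `τM = √(1/M²−1)/ω`, and
`E = (1 − τ_DA/τ_D)·100%`.

**Spectral unmixing.** Non-negative decomposition of single-cell emission
spectra into donor, sensitized-emission, green-contaminant and
direct-excitation components, and the wavelength-resolved apparent
efficiency

    E_D(λ) = 1 − F_D / ( (Q_D f_D)/(Q_A f_A) · F_S + F_D )

averaged with weights `w(λ) = f_D(λ) f_A(λ)`.

**Traces.** Photobleaching percent-remaining (with the donor-dequenching
signature `donor(t) = (1 − E₀·a(t))/(1 − E₀)` made quantitative), biosensor
ratio amplitude/recovery, and T2A relative brightness.

**Synthetic data.** Generators for all four input kinds with known ground
truth (`fretchar.synth`), so every estimator is testable without a
microscope.

A registry of published constants for mTurquoise2 and its 14 acceptors is
bundled (`fretchar.registry`); `reproduce_tables()` recomputes every
derived column from the bundled scalars.

## Worked example

```
$ fretchar r0 --acceptor mNeonGreen
{
 "donor": "mTurquoise2",
 "acceptor": "mNeonGreen",
 "J": 3150000000000000.0,
 "R0_angstrom": 61.64257313214718,
 "R0_angstrom_rounded": 62
}
```

The mTurquoise2–mNeonGreen pair has an overlap integral of
3.15×10¹⁵ M⁻¹cm⁻¹nm⁴, giving a Förster radius of 61.6 Å — 62 Å after
rounding, the largest of the set, which is why mNeonGreen is the
theoretically best acceptor for this donor.  Lifetime-based efficiency for
the same tandem:

```
$ fretchar flim efficiency --tau-da 2.02 --tau-d 3.77
{
 "tau_da_ns": 2.02,
 "tau_d_ns": 3.77,
 "efficiency_pct": 46.41909814323607
}
```

a 46% FRET efficiency from the quench of the donor phase lifetime from
3.77 ns to 2.02 ns.  Simulated data round-trip end to end:

```
$ fretchar simulate cellspec --seed 1 --out demo/
$ python - <<'PY'
from fretchar import synth, unmixing
donor = synth.gen_spectra((434, 474), qy=0.93, name="donor")
acceptor = synth.gen_spectra((515, 527), qy=0.68, name="acceptor")
cell, refs, truth = synth.gen_cell_spectra(donor, acceptor, true_E=0.42)
e_d, result = unmixing.unmix_pipeline(cell, refs)
print(f"true E = {truth.true_E}, recovered E_D = {e_d:.6f}")
PY
true E = 0.42, recovered E_D = 0.420000
```

## Analysis scripts

The `analysis/` directory holds the numbered drivers that produce the
tables in `results/`:

1. `01_forster_radii.py` — radii of all 14 pairs from their overlap
   integrals (14/14 match the published values after rounding).
2. `02_lifetime_efficiencies.py` — lifetime-based efficiencies of all
   tandems (phase column 14/14; modulation column 12/14, see
   `docs/methods.md`).
3. `03_flim_recovery.py` — FD-FLIM estimator validation: machine-precision
   recovery noiseless, +0.01% ROI bias at 1e4 Poisson counts.
4. `04_spectral_unmixing.py` — unmixing chain validation at E = 0.2, 0.42,
   0.59, noiseless and under 1% Gaussian noise.
5. `05_trace_analysis.py` — bleach and biosensor closed-form checks.

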