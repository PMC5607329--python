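# Methods

`fretchar` implements the complete computational workflow used to
characterize acceptor fluorescent proteins for the cyan donor mTurquoise2:
Förster theory from spectra, frequency-domain fluorescence-lifetime imaging
(FD-FLIM), spectral unmixing of sensitized emission, and photobleaching /
ratiometric-biosensor trace analysis.  A synthetic-data generator stands in
for the microscope so that every stage can be validated against known
ground truth.

## Förster theory (`fretchar.spectra`)

The overlap integral of the area-normalized donor emission `f_D(λ)` with
the acceptor molar extinction `ε_A(λ)` is evaluated by the trapezoid rule
on a common 1 nm grid spanning the union of the measured supports:

    J = ∫ f_D(λ) ε_A(λ) λ⁴ dλ      [M⁻¹ cm⁻¹ nm⁴]

Values outside a spectrum's measured range are treated as zero, never
extrapolated.  The Förster radius follows from

    R0⁶ = 8.79×10⁻⁵ · κ² · n⁻⁴ · Q_D · J      [Å⁶]

with defaults κ² = 2/3 (isotropic dynamic averaging), n = 1.33 and
Q_D = 0.93 (mTurquoise2).  With the measured overlap integrals of all 14
acceptor pairs this formula reproduces every published radius after
rounding; rounding is half-up to integer Ångström, which matters for
borderline values such as 58.5 Å.  The 1 nm integration grid was checked
against a 0.01 nm brute-force integral (agreement better than 0.1%).

The composite emission of a pair transferring a fraction `E` is modelled by
photon bookkeeping: `(1−E)·Q_D·f_D + E·Q_A·f_A`, plus a
direct-excitation term proportional to `Q_A·f_A`.  Feeding this forward
model into the unmixing chain returns `E` to numerical precision, which
ties the two modules together.

## Frequency-domain FLIM (`fretchar.flim`)

A homodyne phase stack records K images at detector phases θ_k; each pixel
traces `I_k = DC + AC·cos(θ_k − φ)`.  The harmonic is estimated by linear
least squares on the design `(1, cos θ_k, sin θ_k)`, which reduces exactly
to the first-harmonic DFT coefficients for equally spaced steps but also
handles pseudorandom acquisition orders and unequal step sets.  The
estimate depends only on the (θ_k, frame) pairing, so it is invariant under
acquisition-order permutations (acquiring in random order is the standard
defence against bleaching trends).

Calibration uses a reference with known lifetime: its true phasor is
`φ = arctan(ωτ)`, `M = 1/√(1+(ωτ)²)`; the measured-vs-true difference is
the instrument phase offset and modulation factor, which are divided out of
the sample.  Lifetimes then follow from `τφ = tan(φ)/ω` and
`τM = √(1/M²−1)/ω`.  For mixtures τφ < τM; equality holds only for
mono-exponential decays.

Numerical choices:

* pixels with AC/DC < 1e-3 are flagged undefined rather than propagating
  arctan noise;
* ROI averaging happens in phasor coordinates (G, S) = (M cos φ, M sin φ),
  never on per-pixel lifetimes, because lifetimes are nonlinear in the
  phasor and averaging them would bias ROI means;
* modulation depths up to 1 + 1e-6 are clamped to 1 (shot noise), larger
  values and phases ≥ π/2 raise errors as unphysical.

FRET efficiency from lifetimes is `E = (1 − τ_DA/τ_D)·100%`.  The bundled
registry uses the measured donor-only references τ_D = 3.77 ns (phase) and
4.01 ns (modulation) — the constants that actually generated the published
efficiency columns — while the nominal 3.8/4.0 ns serve as calibration
lifetimes.  The phase-lifetime efficiency column reproduces for all 14
acceptors; the modulation column reproduces for 12 of 14 (TagRFP-T,
mScarlet-I differ by 1 and 5 points), which is the expected artifact of
publishing lifetimes at 2 decimals while computing efficiencies from
unrounded per-cell means.  `reproduce_tables()` reports these comparisons
explicitly rather than hiding them.

## Spectral unmixing and apparent efficiency (`fretchar.unmixing`)

Each cell contributes a donor-excitation spectrum `F(λ)` and an
acceptor-excitation spectrum.  `F` is normalized to the peak of the
acceptor-excitation spectrum (everything is then expressed per unit of
acceptor, making expression levels comparable), the direct-excitation
contribution measured on acceptor-only cells is subtracted, and the
remainder is decomposed by non-negative least squares (`scipy.optimize.nnls`;
components are photon counts, so negative coefficients are excluded):

* green/yellow acceptors: donor + acceptor shapes over 450–650 nm;
* orange/red with a green (immature-chromophore) component: donor + EGFP
  shapes over 450–525 nm, sensitized emission as the remainder;
* red without a green component: donor shape alone over 450–500 nm.

The apparent efficiency is, per wavelength,

    E_D(λ) = 1 − F_D / ( (Q_D f_D)/(Q_A f_A) · F_S + F_D )

and is constant in λ for any mixture built from the reference shapes (the
flatness that justifies averaging).  The average uses weights
`w(λ) = f_D(λ)·f_A(λ)` over a flat region: by default the wavelengths where
both reference shapes exceed 1% of their maxima, intersected with the class
fit window; for red acceptors that intersection is empty (a red acceptor
barely emits below 525 nm), so the default falls back to the unrestricted
overlap region — E_D(λ) is defined wherever both shapes carry signal, not
only where the donor was regressed.  Wavelengths with `f_A` below 1e-6 of
its peak are excluded before forming the quantum-yield ratio.

One deliberate robustness choice: the normalization peak is read off a
quadratic Savitzky–Golay smooth (21 samples at 1 nm) of the
acceptor-excitation spectrum rather than the raw maximum.  The raw maximum
of a noisy curve is upward-biased, which propagates into a systematic
over-subtraction of the direct-excitation component and a detectable
downward bias in E_D; the smooth removes that noise bias, and its small
curvature bias cancels exactly because sample and acceptor-only control are
normalized by the same rule.  Set `peak_smooth_window=0` for the raw
maximum.

Real single-cell data also carry detector spectral-sensitivity factors;
inputs here are assumed already corrected, as is conventional for
spectrograph data that have been calibrated against known emitters.

## Trace analysis (`fretchar.traces`)

Traces are background-subtracted and normalized to the mean of the first
`n` frames (n = 1 for bleach curves, 5 for biosensor recordings; the
operation is idempotent).  Percent-remaining uses the nearest frame at or
before the probe time — no interpolation, matching frame-based acquisition.
For a tandem construct whose acceptor pool survives as `a(t)` at initial
efficiency E₀, the normalized donor channel is exactly
`(1 − E₀·a(t))/(1 − E₀)`: donor dequenching mirrors acceptor loss, and the
donor channel rises above 100%.

Biosensor responses are summarised from the acceptor/donor ratio (the
conventional orientation; configurable): baseline is the pre-agonist mean,
amplitude the maximal relative deviation between agonist and antagonist,
recovery the fraction of the amplitude reversed at the post-antagonist
plateau (mean of the last 5 frames).  Cells are classed as responders when
the amplitude reaches a configurable threshold, default 5% — published
analyses typically drop "no visible response" cells without quantifying the
cut, so the threshold is explicit here and reported with the output.
Cohort summaries use the mean with a 95% normal-approximation CI across
cells.  Relative brightness from T2A co-expression is the plain
background-subtracted intensity ratio per cell.

## Synthetic data (`fretchar.synth`)

The generators emulate the statistical structure each estimator assumes,
with defaults mirroring the acquisition conditions the workflow was built
for:

* spectra: skewed-Gaussian (log-normal in wavelength) absorbance/emission
  bands on a 1 nm grid over 350–800 nm, peak positions exact to the grid.
  Measured protein spectra are not this functional form; the recovery
  proofs are shape-agnostic, so the choice only affects realism of band
  tails;
* FLIM: homodyne stacks `I_k = DC(1 + M cos(θ_k − φ))` at 75.1 MHz with 12
  phase steps and ~1e4 counts/pixel, optional Poisson noise, instrument
  phase/modulation distortion applied identically to a matched reference
  stack (which is what calibration assumes);
* cell spectra: the photon-bookkeeping forward model plus a
  direct-excitation term and optional green contaminant; Gaussian noise at
  1% of peak approximates shot/readout noise at typical spectrograph count
  levels;
* traces: mono/bi-exponential acceptor bleaching with the dequenching donor
  model (sampled every 4 s for 900 s), and biosensor steps with exponential
  relaxation between FRET levels at agonist/antagonist events (~44 s and
  ~150 s of a 240 s recording sampled every 2 s).

All generators are bit-deterministic under a fixed seed.  What they do not
emulate: monochromator drift, filter edges, detector spectral response,
photochromism, cell-to-cell maturation variability, or spatial structure in
images (stacks are spatially uniform apart from noise).  Passing the
recovery tests therefore demonstrates correctness of the estimators under
their stated assumptions, not robustness to every real-microscope artifact.

## Validation scales

The bundled analyses and tests use deliberately small problems: 16×16 ROIs
with 100 noise seeds for the FLIM bias study, 100 replicates per efficiency
level for the unmixing study, 2×2 noiseless stacks for exactness checks.
These sizes give standard errors of ~1e-4 on recovered efficiencies and
~0.01% on lifetime bias, ample for the stated tolerances.

## Known limitations

* Single modulation frequency per stack; no multi-harmonic or global
  multi-frequency analysis.
* No time-domain (TCSPC) lifetime fitting.
* No errors-in-variables treatment of noisy reference spectra in the
  unmixing regression (ordinary least squares, matching the published
  procedure).
* Published single-cell efficiency tables from spectral imaging and the
  published bleach percentages depend on the study's raw image data and are
  not recomputable from printed inputs; those pipelines are validated by
  construction on generator data instead.
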