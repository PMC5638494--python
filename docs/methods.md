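# Methods

This note documents the models the package implements, the numerical
choices behind the fits, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the underlying assay
descriptions leave the procedure open.

## Fluorescence decay analysis

Intensity decays are modelled as sums of one to three exponentials with
normalised pre-exponential factors (Σaᵢ = 1, enforced by construction
and preserved by renormalisation after every fit). Two data paths feed
the same model:

* **Time domain.** The fit target is the total intensity reconstructed
  from polarized traces, I_VV(t) + 2G·I_VH(t), which removes the
  anisotropy contribution exactly. Delta excitation is assumed — decays
  are generated without an instrument response function, and the fitted
  window starts at t = 0. Convolution with a measured IRF is out of
  scope for the generators (a deliberate simplification: the assays this
  emulates resolve nanosecond lifetimes on ~50 ns windows where the IRF
  mainly affects the sub-nanosecond components that are flagged as
  resolution-limited anyway).
* **Frequency domain.** Phase and modulation are fit jointly through the
  analytic transforms of the decay. The per-component weights are the
  fractional intensities fᵢ = aᵢτᵢ/Σaⱼτⱼ, not the amplitudes: phase and
  modulation are the polar form of the Fourier transform of I(t), and
  the test suite verifies the transforms against direct sine/cosine
  quadrature of the time-domain model. Phase residuals are taken in
  radians so the two channels contribute on comparable scales; unit
  weights are used (per-point standard deviations can be added where
  sweeps carry them).

**Fitting engine.** All nonlinear fits run damped least squares
(`scipy.optimize.least_squares`) in log-parameterisation for positive
quantities, from 8 multi-start initialisations log-spaced over
0.1–50 ns, stopping on relative parameter/cost change < 1e-8 or 500
evaluations per start; the lowest-cost solution wins, and a start that
reaches zero cost short-circuits the rest. Parameter uncertainties are
asymptotic (Gauss–Newton (JᵀJ)⁻¹s², delta-method back-transformed from
log scale). A component whose SD exceeds its estimate is flagged as
unidentifiable rather than removed.

**Anisotropy.** r(t) is computed with the G factor applied to I_VH —
the instrument correction the G measurement (I_HV/I_HH) exists for;
with G = 1 this reduces to the uncorrected textbook ratio. The analysis
window is truncated where total intensity drops below 1 % of its peak,
and the anisotropy fit accepts per-point weights. The pipeline weights
residuals by total intensity: the variance of a ratio of noisy
intensities grows as the intensity decays, and unweighted fits of noisy
r(t) showed large (~25 %) median bias on slow-correlation-time recovery
that intensity weighting removes. Fitted total anisotropies above the
fundamental limit 0.4 are flagged as unphysical but returned (noise can
legitimately push estimates past the cap); the *generators* reject
unphysical ground truth outright. Correlation times shorter than twice
the grid spacing are flagged as resolution-limited.

**A monotonicity caveat.** The modulation of any multi-exponential decay
is strictly decreasing in frequency, and this is property-tested. The
phase, however, is *not* globally monotone for heterogeneous decays —
property testing found counterexamples (e.g. equal-amplitude components
at 0.26 and 5 ns show a phase dip near 200–300 MHz). The package
therefore asserts phase monotonicity only for single-component decays
and otherwise only that phase stays in (0°, 90°).

**Average lifetime.** Amplitude weighting (Σaᵢτᵢ) is the default, on
the grounds that the decay law is stated with normalised pre-exponential
factors; intensity weighting (Σaᵢτᵢ²/Σaᵢτᵢ) is selectable.

## Polymerisation analysis

**Rate extraction.** The half-maximal time is located by linear
interpolation of the first crossing of (f_min+f_max)/2; multiple
crossings are flagged and the first wins (a deterministic rule that
needs no noise model). The slope is ordinary least squares over the
contiguous points whose intensity lies within ±5 % of the total
amplitude around the half-maximal level (window configurable). No
smoothing is applied by default — the windowed regression already
averages noise; an optional odd-width moving average is available at the
trace level. Because the window is defined in amplitude fractions, the
normalised rate (sample slope / spontaneous slope) is exactly invariant
to affine intensity rescaling.

**Ionic strength.** Computed over fully dissociated ions from a fixed
stoichiometry table (KCl, NaCl, MgCl₂, CaCl₂). The conventional
½Σcᵢzᵢ² form is the default; a ½Σcᵢ|zᵢ| variant is selectable for
comparability with sources that print the unsquared form, which for any
mixture containing multivalent ions gives a strictly smaller value.

**Critical concentration.** The two-segment model is implemented as the
continuous hinge F = F_c + L_s·min([a]−cc, 0) + R_s·max([a]−cc, 0).
For fixed cc the remaining three parameters are linear, so the fit
profiles cc: a 512-point scan over the interior of the concentration
span followed by bounded scalar refinement of the best bracket
(xatol 1e-12). The cc uncertainty is taken from the curvature of the
profile SSE. Slopes differing by less than 5 % of R_s flag the break as
unidentifiable; a breakpoint at the span edge is flagged too.

*Noise conditions for recovery benchmarks.* "2 % noise" on a
concentration series is interpreted as additive Gaussian noise with
sigma equal to 2 % of the mean series intensity — the typical measured
signal. Relative to the *full-range* amplitude instead, the three
sub-breakpoint points (which span only ~0.3 intensity units when the
upper slope is 80) would be swamped, and even an ideal two-line
intersection estimator has ~60 % relative SD there; this is consistent
with the large uncertainties such assays report for cc itself. Default
ground-truth slopes are L_s = 4, R_s = 80: a 20-fold enhancement
matching the known ~20–25× quantum-yield increase of pyrene-actin on
polymerisation.

## Binding analysis

Densitometry ratios divide molecular-weight-corrected band volumes
(defaults 42 kDa actin, 62 kDa Lmod2); staining-efficiency coefficients
default to 1.0 and are configurable per protein, since dye-binding
differences are real but rarely quantified. Lanes with zero actin band
are dropped with a warning — the no-actin control behaviour.

In the sigmoid, dx is implemented as the width parameter in the
exponent (the formula governs over the prose that calls it a slope; the
two are reciprocally related at the inflection). The stopped-flow
biexponential enforces t₁ ≤ t₂ by component ordering after the fit and
falls back to a single exponential when the second amplitude's SD
exceeds its estimate, reporting the fallback. No dead-time correction is
applied by default; an optional time offset can be introduced upstream.
The 1/t₁-versus-concentration summary is a plain OLS line with classical
standard errors; mechanistic interpretation is left to the caller.

## FRET analysis

Band integrals use trapezoidal quadrature with linear interpolation to
exactly 435 and 485 nm, so results do not depend on grid registration.
The inner-filter correction is the standard 10^((A_ex+A_em)/2) factor
(absorbances default to 0, i.e. pre-corrected data). Efficiencies may
come out slightly negative under noise and are flagged, never clipped,
so replicate averages stay unbiased. f′ = E/F_DA deliberately avoids any
distance (Förster) calculation — with one donor coupled to multiple
acceptors only the normalised temperature dependence is meaningful, and
relative f′ is anchored to exactly 1 at the lowest temperature by
construction. Slope comparisons propagate OLS slope SDs in quadrature.

## ATPase analysis

The coupled assay regenerates each hydrolysed ATP at the cost of one
NADH (1:1 stoichiometry), so the molar hydrolysis rate is
(−dA₃₄₀/dt)/(ε·l) with ε·l = 6220 M⁻¹ (NADH at 340 nm, 1 cm path; both
configurable), converted to μM/s and divided by the motor concentration
in μM. A literal division by an "ATP molarity" would not produce a rate
in μM_ATP s⁻¹ μM_protein⁻¹; the unit chain implemented here does, and is
pinned by a hand-calculated conversion test (−6.22×10⁻⁴ A/s at 0.5 μM
motor → 0.2 s⁻¹). The slope fit uses the central 80 % of the trace by
default to avoid mixing and substrate-depletion artefacts, with the
window R² as a linearity diagnostic (warning below 0.9). Activity
profiles require an explicit zero-regulator control and do not assume
monotonicity.

## Synthetic-data generators

Each generator evaluates a forward model on a grid and adds i.i.d.
Gaussian noise from a seeded stream (`numpy.random.default_rng`), making
identical parameters + seed bit-reproducible. Defaults: decays on
0–50 ns / 1024 points, polymerisation on 0–2000 s / 600 points, stopped
flow on 0–5 s / 1000 points, spectra on 380–600 nm at 1 nm — grids that
resolve the parameter scales of the emulated instruments at desk-scale
cost.

What they emulate, and what they do not:

* Polarized decays satisfy I_VV + 2G·I_VH = I(t) exactly by
  construction (I_VV = I(1+2r)/3, I_VH = I(1−r)/(3G)); no IRF
  convolution, no Poisson photon statistics.
* Frequency sweeps come from the analytic transforms; no cross-
  correlation detection artefacts.
* Pyrene curves are generalized logistics with an independent plateau
  scale (emulating the regulator-dependent quantum-yield increase, e.g.
  a 4-fold saturation-intensity ratio at saturating Lmod2). A
  mechanistic nucleation–elongation ODE is deliberately not implemented:
  no rate constants are available to parameterise one, and the analysis
  operations only consume the midpoint slope and plateau.
* The donor emission band is a single Gaussian (peak 475 nm, width
  35 nm) standing in for IAEDANS; only the 435–485 nm integral matters
  downstream, and the acceptor-present spectrum is the donor spectrum
  scaled by (1−E), which realises F_DA/F_D = 1−E exactly.
* NADH traces are straight lines; substrate depletion curvature is not
  modelled (the analysis window diagnostic exists to catch it in real
  data).

Noise sigmas have no authoritative values (instrument noise is never
reported for these assays); tests state their sigma explicitly per
scenario. Consequently, passing recovery tests demonstrate the
correctness of the analysis chain and its noise robustness under
additive Gaussian noise — not robustness to baseline drift,
photobleaching, inner-filter generation or correlated instrument noise,
none of which the generators produce.

## Problem sizes

Monte-Carlo envelopes use 200 replicates for scalar recoveries (cc
median bias, ATPase slope SD, FRET slope power) and 40–100 for the
heavier nonlinear fits (two-component sweeps, anisotropy decays,
cosedimentation sigmoids) — enough for stable medians at the asserted
tolerances while keeping the default suite fast.

## Known limitations

* Time-domain decay fits assume delta excitation; sub-nanosecond
  components are reported but flagged resolution-limited.
* The breakpoint profile can lock onto a span edge under heavy noise
  (flagged); cc is intrinsically poorly determined when the sub-cc
  segment carries few points.
* The biexponential fallback criterion (SD > |A₂|) is a heuristic;
  strongly correlated amplitudes near t₁ ≈ t₂ can defeat it.
* No global (linked) multi-dataset analysis, associated-anisotropy
  models, lifetime distributions, Kd/stoichiometry mechanistic binding
  models, or Michaelis–Menten analysis — all outside the pipeline's
  scope.
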