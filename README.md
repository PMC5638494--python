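# actospec

Quantitative analysis pipeline for the fluorescence-spectroscopy and
enzyme-kinetics assays used to characterise actin-regulator proteins such
as leiomodin (Lmod2) — lifetime and anisotropy decays of intrinsic
tryptophans, pyrene-actin polymerisation kinetics, critical-concentration
breakpoints, cosedimentation binding isotherms, stopped-flow binding
transients, inter-monomer FRET flexibility analysis, and NADH-coupled
ATPase rates.

Because such studies deposit no raw instrument data, every analysis stage
here is paired with a synthetic-data generator that produces the raw
measurement from known ground-truth parameters with seeded Gaussian noise.
The package is therefore validated end to end by *forward–inverse
parameter recovery*: generate with known truth, analyse, compare.

## Who it is for

Protein biophysicists analysing cuvette fluorescence / kinetics data who
want the standard reductions — multi-exponential decay fits, hinge
regressions, sigmoid isotherms, coupled-assay unit conversions — as
tested, scriptable building blocks rather than spreadsheet formulas.

## The models

**Intensity decay** (time or frequency domain), with normalised
pre-exponential factors:

    I(t) = Σᵢ aᵢ exp(−t/τᵢ),   Σᵢ aᵢ = 1

Frequency-domain sweeps are fit through the analytic transforms
N(ω) = Σᵢ fᵢ ωτᵢ/(1+ω²τᵢ²), D(ω) = Σᵢ fᵢ/(1+ω²τᵢ²) with fractional
intensities fᵢ = aᵢτᵢ/Σaⱼτⱼ, phase φ = atan(N/D) and modulation
m = √(N²+D²).

**Anisotropy decay**, bounded by the fundamental anisotropy 0.4:

    r(t) = (I_VV − G·I_VH)/(I_VV + 2G·I_VH) = Σᵢ r₀ᵢ exp(−t/tᵢ)

with the instrument G factor measured as I_HV/I_HH.

**Polymerisation rate**: slope of the pyrene trace at 50 % of maximal
change, normalised to spontaneous assembly. **Critical concentration**:
breakpoint cc of the continuous two-segment line
F = F_c + L_s([a]−cc) for [a] ≤ cc, F_c + R_s([a]−cc) above.

**Binding**: bound-ratio sigmoid
y = (y_min−y_max)/(1+exp((x−x₀)/dx)) + y_max for cosedimentation;
rising biexponential y(t) = A₁(1−e^(−t/t₁)) + A₂(1−e^(−t/t₂)) for
stopped flow.

**FRET**: E = 1 − F_DA/F_D from 435–485 nm band integrals;
f′ = E/F_DA, whose temperature slope (after normalising to the lowest
temperature) ranks protein-matrix flexibility.

**ATPase**: k = (−dA₃₄₀/dt)/(ε·l)/[HMM] in μM_ATP s⁻¹ μM_protein⁻¹,
with ε·l = 6220 M⁻¹ for NADH in a 1 cm cuvette.

## Worked example

The `demo` subcommand generates one synthetic dataset per assay at the
package's reference parameter values for cardiac Lmod2, analyses each, and
tabulates recovered versus true values:

```sh
actospec demo --seed 1 --out demo_out
```

```
         stage                         quantity  truth  recovered   rel_error       units
         decay                 average lifetime   2.92       2.92 5.19013e-10          ns
         decay slow rotational correlation time   35.9       35.9 5.68038e-14          ns
         decay          steady-state anisotropy  0.083      0.083 5.01607e-16
polymerisation           critical concentration   0.12       0.12 7.74516e-10          uM
polymerisation                    max fold rate     12    11.9935 0.000540634        fold
polymerisation              high-salt fold rate      4    4.00025  6.1718e-05        fold
       binding               half-saturation x0    1.5        1.5           0          uM
          fret   FRET efficiency bare filaments   0.26       0.26           0
          fret       FRET efficiency with Lmod2   0.32       0.32 5.20417e-16
        atpase                basal ATPase rate   0.04       0.04 1.73472e-16 uM_ATP/s/uM
        atpase      actin-activated ATPase rate  0.164      0.164           0 uM_ATP/s/uM
        atpase      fraction of control at 3 uM    0.4        0.4           0
```

Every row is a full generate → analyse → compare cycle: e.g. the 2.92 ns
row generates a 10-frequency phase/modulation sweep from a 2.92 ns
single-exponential decay and refits it; the 120 nM row generates the
9-point pyrene concentration series and refits the hinge model. The
fold-rate rows carry ~5×10⁻⁴ relative discretisation error from the
finite slope window; everything else recovers to numerical precision.
With `--config`, noise levels and ground-truth values can be varied.

Individual stages are available as subcommands operating on CSV files
(`actospec decay fit`, `actospec polym cc`, `actospec bind cosed`,
`actospec fret efficiency`, `actospec atpase rate`, …) or directly as
library functions.

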