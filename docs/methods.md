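# Methods

## The model

`loxsim` simulates what happens in the first ~100 minutes after soybean
seeds are homogenized. Before crushing, lipoxygenase (LOX) and its
substrate, free linoleic acid (LA), are compartmentalized; homogenization
mixes them and the pathway starts producing the "green/beany" C6 aldehyde
n-hexanal.

The network has 11 species: LA, eight hydroperoxy-octadecadienoic acid
(HOD) isomers (13/9-positional × S/R × (Z,E)/(E,E)), n-hexanal and its
cleavage co-product 12-oxo-(Z)-9-dodecenoic acid. Two reaction layers act
on them:

1. **LOX.** The three seed isozymes L-1, L-2, L-3 each consume LA with an
   irreversible Michaelis–Menten law, vᵢ = Vmaxᵢ·[LA]/(Kmᵢ+[LA]), and
   distribute the product over the eight isomers with isozyme-specific
   fixed branching fractions. The three reactions compete additively for
   the single shared LA pool; a genotype lacking an isozyme simply drops
   that flux (exactly equivalent to Vmax = 0, which a test asserts).
2. **HPL.** Hydroperoxide lyase cleaves the two (Z,E) 13-isomers —
   13HOD-S(Z,E) (preferred) and 13HOD-R(Z,E) — into n-hexanal + the
   oxo-acid, 1:1, through two independent Michaelis–Menten channels.
   The other six isomers are terminal pools.

Assumptions inherited from the source kinetic data: oxygen and enzyme
levels are non-limiting (not state variables), no feedback or product
inhibition, no n-hexanal sink (the ADH conversion to n-hexanol matters
only at alkaline pH and is out of scope), and initial concentrations are
zero for everything except LA. Consequently LA is non-increasing,
n-hexanal is non-decreasing and equals the oxo-acid at all times, and
LA + ΣHOD + hexanal is conserved.

## Parameters and units

Everything lives in one unit system: concentrations in nmol/mL, rates in
nmol·mL⁻¹·min⁻¹, time in minutes.

| enzyme | Km (nmol/mL) | Vmax at 15 mg protein/mL (nmol·mL⁻¹·min⁻¹) |
|---|---|---|
| L-1 | 490 000 | 8 250 |
| L-2 | 490 000 | 39 000 |
| L-3 | 490 000 | 2 550 |
| HPL on 13HOD-S(Z,E) | 50 000 | 285 000 |
| HPL on 13HOD-R(Z,E) | 50 000 | 38 500 |

The L-2/L-3 Michaelis constants are borrowed from the purified-L-1
measurement (their Vmax values come from relative whole-bean activities),
which is why the sensitivity module sweeps Km. The HPL Vmax on the R
isomer is 13.5% of the S-isomer value and is stored as the independently
rounded 38 500, so the scaled/specific ratio is 14.8 rather than exactly
15; the invariant allows 2%. Initial free LA is 67 nmol/mL, scaled from
typical seed fatty-acid composition at a protein reference of 15 mg/mL
(midpoint of the 10–20 mg/mL reported range).

The branching-fraction table is stored exactly as published (percent
rows summing to 100.0–100.1 due to rounding); the rate equations use
rows renormalized to exactly 1, otherwise mass conservation could only
hold to ~10⁻³. The renormalization shifts the genotype-scan relatives by
less than 10⁻³ and no 2-decimal reported value changes.

Note that the free-LA pool (67 nmol/mL) sits four orders of magnitude
below every Km: the model operates deep in the sub-saturated, first-order
regime. Absolute n-hexanal predictions (~49 nmol/mL for wild type) are
therefore roughly linear in the initial LA estimate and exceed measured
homogenate values ~10-fold; the meaningful outputs are the *relative*
values between genotypes, which are insensitive to LA₀ and to the HPL
constants.

## Numerical choices

* Integrator: `scipy.integrate.solve_ivp` with LSODA (adaptive,
  stiffness-switching; the HPL channel is ~50× faster than LOX
  turnover), rtol 10⁻⁸, atol 10⁻¹² nmol/mL. The tight tolerances are
  needed because species span ~5 orders of magnitude and reported ratios
  round to 2 decimals.
* Output grid: 1001 even points over [0, duration]; peak detection and
  conservation checks use this grid. "Peak" n-hexanal is the grid
  maximum, which equals the final value because the model has no hexanal
  sink; it is kept as an explicit max so the operation survives a future
  ADH extension.
* Rates are evaluated with substrate clamped at 0; non-negativity of the
  solution is asserted post hoc, not enforced by projection.
* The degenerate cascade case κ ≈ K in the closed form switches to the
  analytic limit (1+Kt)e^(−Kt) when |κ−K| < 10⁻⁸·max(κ,K).
* No randomness anywhere: identical configs produce byte-identical CSVs.

## The closed-form oracle

Because LA₀ ≪ Km, every Michaelis–Menten law linearizes to v = (Vmax/Km)s
and the network becomes an analytically solvable linear cascade
(`loxsim.oracle`). With K = Σ Vmaxᵢ/Kmᵢ over active isozymes, lumped
branching F_j, and κ_j = Vmax_HPL,j/Km_HPL:

* LA(t) = LA₀e^(−Kt); terminal isomers fill as LA₀F_j(1−e^(−Kt));
* HPL-active isomers follow the two-exponential intermediate solution,
  and per-channel hexanal is LA₀F_j·[1−(κ_j e^(−Kt)−K e^(−κ_j t))/(κ_j−K)].

The oracle shares no code with the integrator and agrees with it to
≤10⁻³ relative on every species at every output time at the default
parameters (measured ≈1.4×10⁻⁴, the size of the saturation correction
LA₀/Km). It refuses to run when LA₀/min(Km) ≥ 10⁻², e.g. after a
1000-fold Km decrease, where only the ODE answer is meaningful.

## Design choices where the source was open

* **Unit reading.** The kinetic table prints Km in "mmol mL⁻¹" while the
  sensitivity discussion calls the same number "0.49 mM" — a 1000-fold
  discrepancy. The table-literal reading (Km = 490 000 nmol/mL) is
  adopted because it is the only one that reproduces the published
  genotype-scan column and the ~50 nmol/mL wild-type prediction; under
  the mM reading LA would saturate all enzymes and every genotype ratio
  would collapse onto the branching fractions.
* **HPL channels.** The two HPL reactions are modeled as independent
  Michaelis–Menten channels (separate Vmax per substrate, as tabulated)
  rather than as one enzyme pool with competitive binding.
* **In-range flags.** The comparison module flags a genotype "in range"
  by a strict inclusive interval check of the 2-decimal model value
  against the non-missing study values (missing entries are excluded,
  not treated as zero). Under this check the L3 prediction (0.07) falls
  0.03 below the lowest published value (0.10) and is flagged out of
  range, although qualitatively it is the closest-to-range miss.
* **Sweeps vary Km only.** Vmax is held fixed; in the sub-saturated
  regime the dynamics depend on Vmax/Km only, so a Km sweep doubles as a
  Vmax sweep (a property test checks the equivalence to 10⁻³).
* **Config dialect.** One flat YAML mapping with dotted keys
  (`kinetics.L1.km: …`), rejecting unknown keys, so every override is
  greppable and the round trip is exact.

## Known limitations and diagnostic notes

* Two published Fig-6-style sensitivity claims do not reproduce at the
  100-minute horizon under this parameterization: a 1000-fold L-2 Km
  increase gives ≈0.70 (not ≈0.6) of the default peak, and a 10-fold
  L-2 Km decrease drives the L2-only line to ≈1.0× wild type (not
  ≈1.5×), because the wild type itself becomes L-2-dominated. Both are
  reported diagnostically; the robust sensitivity results (L-3 Km ÷ 1000
  → ≈0.19, impact ordering L-3 > L-2 > L-1) do reproduce.
* The model omits the experimentally observed background n-hexanal in
  LOX-free beans (0.06–0.22× wild type): its L0 prediction is exactly 0.
* pH dependence, the ADH n-hexanal→n-hexanol reaction, α-linolenic acid
  as a second substrate, and parameter fitting are all out of scope.
* The SBML export is a self-defined Level 3 Version 2 layout (species,
  global Km/Vmax parameters, one irreversible reaction per isozyme ×
  isomer branch with its MathML rate law); `validate_sbml` is a
  structural consistency checker, not a full SBML semantic validator.
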