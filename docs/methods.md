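# Methods

## Reactor model and assumptions

The simulated system is a closed homogeneous batch reactor: perfectly mixed,
spatially uniform, no inflow or outflow, held at constant temperature and
constant volume (100 cm³ by default; volume is bookkeeping only, since all
kinetics are intensive). The gas mixture obeys the ideal gas law, so the
initial concentrations are c_i = x_i·P0/(R_u·T) with R_u = 82.057
cm³·atm·mol⁻¹·K⁻¹ and P0 = 1 atm. Temperature is converted as T[K] =
T[°C] + 273.15.

Constant temperature and constant volume cannot both coexist with constant
pressure once total moles change (the oxygen-addition step reduces moles);
we hold volume fixed and let pressure be a diagnostic output. The drift is
about 0.2% over 12 h at 90 °C and far smaller below, so the distinction is
invisible at the precision of the reported tables. For the same reason the
choice of mole-fraction denominator (instantaneous vs initial total moles)
matters only in the fourth significant digit at the hottest condition; we
report fractions against the instantaneous total, the convention of
general-purpose kinetics codes.

The mechanism treats species as lumped surrogates (FRAG12 stands for the
non-volatile C12 fragment of hydroperoxide scission), so elemental balances
are not meaningful; the conserved quantities are the stoichiometric moiety
sums returned by `conservation_laws` — the integer left null space of the
stoichiometry matrix, computed exactly over the rationals. For the bundled
mechanism that space is six-dimensional (the stoichiometry matrix has rank
5: propagation − ROO scavenging + LINRAD scavenging cancels exactly), and it
contains the interpretable sums {N₂}, {LYCOPENE+LYCORAD},
{LINOLEIC+LINRAD+ROO+ROOH+HEXANAL}, and {HEXANAL−FRAG12}.

## Kinetics

All six steps are irreversible with modified-Arrhenius coefficients
k = A·Tⁿ·exp(−Ea/(R·T)); n is carried in the data model but is zero for every
bundled step. Ea is in cal·mol⁻¹ with R = 1.98720425 cal·mol⁻¹·K⁻¹.
Bimolecular pre-exponentials are in cm³·mol⁻¹·s⁻¹; the unimolecular
hydroperoxide decomposition uses s⁻¹. A single unit header covering both
molecularities would be dimensionally inconsistent, and the s⁻¹ reading is
the standard convention of gas-kinetics input formats; it also reproduces
the published endpoint tables, which a cm³·mol⁻¹·s⁻¹ reading does not.

## Numerical solution

The ODE system is stiff: radical concentrations sit up to ten orders of
magnitude below the bulk species and equilibrate on sub-second time scales
while the simulation spans 43 200 s. Defaults: scipy `solve_ivp` with BDF,
analytic Jacobian, rtol = 1e-10, atol = 1e-24 mol·cm⁻³. Concentrations are
clipped at zero inside the right-hand side (mass action is undefined for
negative states); integration fails loudly if any state undershoots below
max(atol, 1e-12·c_total). Output is sampled every 600 s plus the 4 h and
12 h marks; tightening rtol tenfold changes the reported endpoint fractions
by well under 0.1% (tested).

A zero-duration run returns the single initial state, so downstream tables
degrade gracefully to the initial composition.

## Quasi-steady-state cross-check

`qssa_oracle` provides an independent closed form used to verify the
integrator at low conversion. Assumptions: lipid radicals are consumed
effectively instantly by oxygen addition; the only chain termination is
antioxidant scavenging of ROO; substrate depletion is negligible. Then

    [ROO]ss  = k_init[LIN][O₂] / (k_scav[LYC])
    d[LIN]/dt ≈ −k_prop[ROO]ss[LIN]                     (constant rate)
    [ROOH](t) ≈ (k_prop[LIN] + k_scav[LYC])·[ROO]ss·t  (linear growth)
    [HEXANAL] ≈ k_dec·([ROOH]_final/2)·t               (trapezoid)

At 50 °C this agrees with the full integration within 8% on all three
quantities; at 90 °C it over-predicts by design (no substrate depletion), and
a validity flag is raised whenever predicted loss exceeds 2%. Because the
closed form needs a nonzero antioxidant concentration, it raises on
antioxidant-free mechanisms rather than dividing by zero.

## Derived metrics

Loss percentages are defined on mole fractions, loss = (x₀−x)/x₀·100, which
makes the loss tables algebraically consistent with the mole-fraction tables.
Oxygen uptake is the same quantity for O₂ (relative to its initial 0.210).
The selectivity ratio is linoleic loss % over lycopene loss %, undefined at
zero lycopene loss. Hexanal normalization divides each value by the maximum
across the temperature set at the same time point, so the hottest condition
maps to 1 exactly and the operation is invariant under positive rescaling —
this is what lets mole fractions be compared against chromatographic peak
areas. (The bundled experimental normalized-hexanal table is used as-is; the
corresponding published *simulated* normalized values are not reproducible
from the published mole fractions by this definition — direct division gives
ratios ~100× smaller at 50/70 °C — so reports print our recomputed ratios and
no agreement with those entries is asserted.)

## Validation statistics

RMSE = √(mean((sim−exp)²)). MPE is the mean absolute percentage deviation
relative to the experimental value (the signed mean is also reported; its
sign shows under- vs over-prediction). R² is reported in both common
conventions — squared Pearson correlation, and 1 − SSres/SStot — because they
differ materially on model-vs-data pairings and the convention behind the
published summary statistics is not documented; the report prints recomputed
values beside the published ones with absolute differences and asserts
nothing about them. Pairings with a zero experimental value are excluded
from percentage errors with a warning. Each marker pools the six conditions
(3 temperatures × 2 times). Points where |sim − mean| > 2·SD are flagged in
the report (with the published simulated values, the mild 50 °C/4 h linoleic
pairing is such a point).

## Synthetic data and calibration

The generator emulates the study design: per marker and condition, n = 3
replicates drawn as Normal(mean, SD) truncated at zero (markers are
nonnegative), with the published experimental means and SDs as default truth
and every draw governed by an explicit seed. What it does **not** emulate:
matrix effects (diffusion limitation, lipid compartmentalization),
between-batch variation, or any correlation between markers — replicates are
independent Gaussians. Passing recovery tests therefore demonstrate that the
calibration machinery works on well-specified problems, not that the
mechanism is identifiable from real pomace measurements.

Calibration minimizes Σ((sim − mean)/max(SD, 10⁻⁶))² over the chosen markers
and conditions with scipy's bounded trust-region least squares; every
objective evaluation re-integrates the reactor (at rtol = 1e-8, atol = 1e-22
— looser than the reporting defaults, ample for an objective smooth in the
parameters). Free parameters are log₁₀A and/or Ea per reaction, with finite
bounds; optional seeded multistart guards against the (rare) multi-modal
case. ODE failure at a trial point contributes a large penalty residual
instead of aborting the fit; non-convergence is reported in the result, not
raised. Known-truth recovery of the propagation Ea succeeds within 1% from
noiseless data and within 5% across seeds at the published noise level with
triplicates. Over the narrow 323–363 K range, A and Ea of one reaction are
nearly collinear (Δ(1/T) is small), so joint (A, Ea) fits report the
parameter correlation from the Gauss–Newton covariance rather than silently
returning two sharp numbers.

## Problem sizes

All shipped analyses use the 11-species/6-reaction mechanism over 43 200 s;
one integration takes on the order of 10–100 ms, a single-parameter
calibration a few seconds (tens of objective evaluations × three
temperatures). The test suite and the acceptance script run the full study
conditions — nothing is scaled down.

## Known limitations

- Isothermal, homogeneous, gas-phase idealization: no energy balance, no
  diffusion–reaction coupling, no phase partitioning; real solid matrices
  oxidize slower than the intrinsic kinetics simulated here.
- The thermo module evaluates NASA-7 polynomials for reporting and format
  completeness only; no coefficients for the lumped species are shipped
  (records in tests are synthetic), and thermodynamic consistency (reverse
  rates from Gibbs energy) is out of scope since all steps are irreversible.
- The CHEMKIN-style parser covers the irreversible subset only: no third
  bodies, pressure dependence, duplicates, or reversible equilibria.
- Hexanal is reported as mole fraction or normalized ratio; no conversion to
  mass per sample is attempted (it would need a matrix-specific calibration
  that is not part of the model).
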