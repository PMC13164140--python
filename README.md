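# lipoxkin

Kinetic simulation of lipid autoxidation and carotenoid radical scavenging in
a closed, isothermal, constant-volume batch reactor — built for food
scientists and reaction engineers who want a mechanistic, testable model of
oxidative deterioration in lipid-rich plant by-products (the bundled
mechanism targets tomato pomace: linoleic acid as the oxidizable substrate,
lycopene as the chain-breaking antioxidant, hexanal as the secondary-oxidation
marker).

## The model

Eleven species and six irreversible elementary steps describe the radical
chain, with mass-action kinetics and Arrhenius rate coefficients
k = A·exp(−Ea/(R·T)):

| step | reaction | A | Ea (cal·mol⁻¹) |
|---|---|---|---|
| initiation | LINOLEIC + O₂ → LINRAD + HO₂ | 1.0×10¹³ | 24 500 |
| oxygen addition | LINRAD + O₂ → ROO | 1.0×10¹² | 0 |
| propagation | ROO + LINOLEIC → ROOH + LINRAD | 1.0×10¹⁴ | 14 000 |
| hydroperoxide decomposition | ROOH → HEXANAL + FRAG12 | 1.0×10¹⁴ | 35 000 |
| ROO scavenging | ROO + LYCOPENE → ROOH + LYCORAD | 1.0×10¹¹ | 10 000 |
| LINRAD scavenging | LINRAD + LYCOPENE → LINOLEIC + LYCORAD | 1.0×10¹⁰ | 10 000 |

Bimolecular A is in cm³·mol⁻¹·s⁻¹, unimolecular in s⁻¹; R = 1.98720425
cal·mol⁻¹·K⁻¹. The initial mixture is N₂ 0.779, O₂ 0.210, LINOLEIC 0.010,
LYCOPENE 0.001 by mole fraction at 1 atm; concentrations follow from the
ideal gas law, and the stiff ODE system dc/dt = S·q(c) is integrated with
scipy's BDF method over 12 h at 50, 70 and 90 °C.

On top of the trajectories the package computes loss percentages
((x₀−x)/x₀·100), oxygen uptake, the substrate/antioxidant selectivity ratio,
per-time-point max-normalization of hexanal, a closed-form quasi-steady-state
cross-check, validation statistics (two R² conventions, RMSE, mean percentage
error) against bundled experimental marker tables, and a seeded synthetic-
replicate generator plus bounded least-squares calibration of Arrhenius
parameters.

## Worked example

```python
from lipoxkin import (ReactorConditions, loss_percent, selectivity_ratio,
                      simulate, tomato_pomace_mechanism)

mech = tomato_pomace_mechanism()
traj = simulate(mech, ReactorConditions.from_celsius(90.0, t_end=43_200.0))
print(f"x_LINOLEIC(12 h) = {traj.species_fraction('LINOLEIC', 43_200):.6f}")
print(f"linoleic loss    = {loss_percent(traj, 'LINOLEIC', 43_200):.2f} %")
print(f"lycopene loss    = {loss_percent(traj, 'LYCOPENE', 43_200):.2f} %")
print(f"selectivity      = {selectivity_ratio(traj, 43_200):.2f}")
```

prints

```
x_LINOLEIC(12 h) = 0.008184
linoleic loss    = 18.16 %
lycopene loss    = 4.73 %
selectivity      = 3.84
```

i.e. after 12 h at 90 °C the model predicts 18.2% of the linoleic acid
oxidized while the antioxidant loses only 4.7% — polyunsaturated lipid is
about 3.8× more susceptible than the carotenoid under the propagation-
dominated high-temperature regime. At 50 °C the same quantities stay below
0.2%: the chain is effectively suppressed by scavenging.

The same pipeline is available from the shell:

```sh
lipoxkin reproduce-tables --outdir out/   # species, loss and hexanal tables + report
lipoxkin simulate -T 90 --duration 12 --out traj.tsv
lipoxkin synth --seed 1 --outdir synth/   # seeded triplicate pseudo-data
lipoxkin calibrate --seed 1               # known-truth Ea recovery demo
```

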