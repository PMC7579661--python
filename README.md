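# admethane

Anaerobic-digestion evaluation of organic byproducts — here, the three
residue streams of industrial green-coffee roasting (pellets, roasted
coffee powder, green coffee powder) — covering the full chain from bench
characterization to full-scale plant balances:

* **Stoichiometric methane potential.** From a CHNS-O elemental analysis
  the oxygen demand of `C_a H_b O_c N_d` is
  `COD/VS = 8 (4a + b − 2c − 3d) / (12a + b + 16c + 14d)` (a…d molar
  amounts per 100 g dry matter), and the theoretical methane potential is
  `B_th = COD/VS × 0.350` Nm³ CH₄/kg VS at normal conditions (0 °C, 10⁵ Pa).
* **First-order kinetics.** Batch cumulative methane follows
  `B(t) = VS · V · B₀ (1 − e^{−kt})`; fed-batch tests with impulse feedings
  `M_in(t_i)` follow `du/dt = Σ mᵢ/V δ(t−tᵢ) − k u`, `dB/dt = u k B₀ V`.
  `(B₀, k)` are estimated by residual-sum-of-squares minimization
  (deterministic coarse grid + bounded Nelder–Mead); absolute
  biodegradability is `Y = B₀ / B_th`.
* **Mix cross-validation.** Blend kinetics predicted as mix-fraction
  weighted averages of single-substrate `(B₀, k)` are compared against
  directly fitted blend curves.
* **Plant balances.** CHP sizing (methane × LHV × η_el over availability
  hours) and the biomethane route: daily mass flows through membrane
  upgrading, annual energy flows, and a greenhouse-gas account
  (produced terms vs. avoided natural-gas emissions).
* **Synthetic test data.** A generator emulating the lab protocol
  (weekday readings, duplicate reactors, inoculum blanks, reading noise)
  with the ground truth always emitted, so fitting is testable without the
  original raw curves.

Intended for bioprocess and waste-valorization engineers who need a
reproducible path from bench batch/fed-batch tests to preliminary
full-scale feasibility numbers.

## Worked example

Characterize the bundled substrate table (COD/VS in g/g, B_th in
Nm³ CH₄/kg VS):

```sh
$ admethane characterize --table src/admethane/data/coffee_substrates.csv --out out/
substrate                  COD/VS    Bth
pellets                     1.420   0.50
roasted_coffee_powder       1.584   0.55
green_coffee_powder         1.399   0.49
```

Fit a synthetic blank-corrected batch test generated at B₀ = 0.22,
k = 0.31 (2 % reading noise, 14 weekday observations over 18 d):

```python
from admethane import (FirstOrderModel, KineticParams, SynthConfig,
                       blank_correct, make_batch_dataset)

cfg = SynthConfig(true_params=KineticParams(b0=0.22, k=0.31), seed=1)
tests, blanks, truth = make_batch_dataset(cfg)
res = FirstOrderModel(blank_correct(tests[0], blanks)).fit()
print(res.summary())
```

```
First-order methane production fit
==================================
mode:        batch
n obs:       14
B0:          0.2225 Nm3 CH4/kg VS
k:           0.3033 1/d
RSS:         2.50714e-07 Nm3^2
RMSE:        0.000133821 Nm3
evaluations: 1735
converged:   True
bounds hit:  none
```

The estimate recovers the generating B₀ within ~1 % and k within ~2 %.
Run the full-scale balance for a reference scenario:

```sh
$ admethane balance --scenario plant_b --out out/
Scenario plant_b - route: biomethane
========================================
Substrate input (t/d):               4.24
Biogas produced (t/d):               0.78
...
GHG balance (t CO2e/y):              -114.7
```

A negative GHG balance means the avoided natural-gas emissions exceed the
process emissions: the plant is a net emission reducer.

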