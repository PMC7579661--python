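# Methods

## Scope and model chain

The package evaluates organic residues as anaerobic-digestion feedstock in
four linked stages: (1) stoichiometric characterization of each substrate,
(2) first-order kinetic modelling of batch and fed-batch methane curves,
(3) cross-validation of blend predictions built from single-substrate
parameters, and (4) full-scale mass/energy/greenhouse-gas balances for two
valorization routes (onsite CHP combustion, membrane upgrading to
biomethane). The bundled reference data describe the three byproduct
streams of industrial green-coffee roasting and two roasting plants of one
producer.

## Stoichiometric methane potential

For a dry-matter composition `C_a H_b O_c N_d` (molar amounts per 100 g,
from CHNS-O mass fractions), complete oxidation requires
`(4a + b − 2c − 3d)/4` mol O₂, giving

    COD/VS = 8 (4a + b − 2c − 3d) / (12a + b + 16c + 14d)   [g COD / g VS]

and the theoretical methane potential

    B_th = COD/VS × 0.350   [Nm³ CH₄ / kg VS]

where 0.350 Nm³/kg COD is the maximum conversion of COD to methane at
normal conditions (0 °C, 10⁵ Pa; 22.414/64 on ideal-gas molar volume over
the O₂-equivalent of one mole of CH₄). Sulfur is carried as metadata but
excluded from the oxidation balance — at the ≤0.1 % levels seen in these
substrates its effect is below the rounding of the elemental analysis.
The ratio is homogeneous of degree zero in the mass fractions, so
percent-vs-fraction input conventions cannot change it; the I/O layer
still demands an explicit units flag rather than guessing.

`B_th` is an upper bound: the measured biochemical methane potential `B₀`
realizes a fraction `Y = B₀ / B_th` (absolute biodegradability). Values of
`Y` above 1 are reported with a warning rather than clipped — they signal
measurement error, not a modelling regime.

## First-order kinetics

Hydrolysis of particulate lignocellulosic substrates is the rate-limiting
step, so cumulative methane in a batch digester is modelled as

    B(t) = VS · V · B₀ (1 − e^{−k t})

with `VS` the charged volatile-solids concentration (kg/m³), `V` the
working volume (m³), `B₀` in Nm³ CH₄/kg VS and `k` in 1/d. This is
evaluated in closed form (no integration error).

Fed-batch operation adds substrate impulses `m_i` at times `t_i`. The
degradable pool `u` (kg VS/m³ equivalent) obeys

    du/dt = Σ_i (m_i/V) δ(t − t_i) − k u,       dB/dt = u k B₀ V.

The simulator integrates this piecewise with a stiff-capable adaptive
solver (LSODA, rtol 1e−8, atol 1e−9), applying exact state jumps at feed
times and carrying the true end-of-segment state across each jump; an
observation falling exactly on a feed time reports the post-jump pool.
The independent closed-form superposition solution (one decaying
exponential per feeding) is used in the test suite as an oracle, never in
the implementation path, keeping the two routes separate.

### Y-inclusion convention in fed-batch mode

The two model formulations are dimensionally ambiguous about whether the
biodegradable fraction `Y` scales the fed mass on entry into the pool. The
package supports both readings via `y_at_entry`:

* `y_at_entry=False` (default): the full fed VS enters the pool and the
  asymptotic specific yield per kg VS fed is `B₀`. This is the convention
  under which blend curves predicted from single-substrate parameters land
  on the measured blend yields (weighted `B₀` 0.2465 vs measured
  0.24 ± 0.01 Nm³/kg VS for the plant-A recipe), so it is the default.
* `y_at_entry=True`: feedings are scaled by `Y` on entry (the pool tracks
  `Y·VS`) and the asymptote per kg fed is `Y·B₀`.

### Fitting

`(B₀, k)` minimize the residual sum of squares between observed and
modelled cumulative methane (absolute volumes; for a single reactor the
argmin is identical under specific-yield residuals, since the two differ
by the constant factor `(VS·V)²`). The search is deterministic:

1. a log-spaced coarse grid over `B₀ ∈ (0.001·B₀_max, B₀_max]` with
   `B₀_max = 2 × max observed specific yield`, and `k ∈ [10⁻³, 2]` 1/d
   (40×40 points in batch mode, evaluated vectorized; 16×16 in fed-batch
   mode where each point costs an ODE solve);
2. bounded Nelder–Mead refinement from the best grid point
   (xatol 1e−10, fatol 1e−14), no random restarts.

The `k` box spans slowly hydrolysing lignocellulosics (k ≈ 0.001/d) to
effectively instantaneous conversion (k = 2/d ≈ 97 % in one day); the `B₀`
cap at twice the observed maximum specific yield excludes asymptotes the
data cannot support. Diagnostics report RSS, RMSE, objective-evaluation
count, convergence and bound-hit flags. Duplicate reactors are fitted
separately and pooled as mean ± half-range, matching the duplicate-reactor
reporting convention of bench tests.

Degenerate inputs: an all-zero series is rejected; a locally decreasing
cumulative series (measurement noise) is accepted with a warning; fewer
than 4 observations cannot constrain the 2-parameter model and are
rejected.

## Synthetic data generator

The generator emulates the bench protocol the fitting stage targets:
thermophilic batch tests of 18 d in 2 L working volume (default VS charge
20 kg/m³, a typical potential-assay loading) and fed-batch tests of 35 d
in 4 L; readings every working day Monday–Friday (day 1 = Monday, so an
18-d batch test yields 14 observations); duplicate test reactors plus
duplicate inoculum-only blanks.

Noise model: each gas reading carries an independent Gaussian error with
standard deviation `noise_sd_frac × asymptotic yield` (default 2 %). The
error is applied through the increments (a reading error perturbs the
increment it closes and the next one with opposite sign), so cumulative
curves carry reading-level i.i.d. noise, are unbiased, and are
non-decreasing in expectation while occasionally showing the locally
decreasing pairs real curves show. Increments are deliberately **not**
floored at zero: a one-sided floor inflates the plateau and was measured
to bias fitted `B₀` upward by 2–6 % at this noise level, breaking
parameter recovery. The inoculum background is a shared first-order term
(default 10 % of the test asymptote, same rate constant as the substrate
unless overridden) added to tests and blanks alike; blank correction
subtracts the blank mean, floors at zero and enforces monotonicity by
running maximum. When biogas rather than methane volumes are requested,
the default methane content is 50 % v/v.

What the generator does not emulate: gas-bag saturation, analyzer drift,
O₂ contamination, temperature excursions, or inoculum adaptation over
repeated feedings. Passing recovery tests therefore demonstrate estimator
correctness under well-behaved measurement noise, not robustness to
instrument pathology.

Measured recovery under the default conditions (package-chosen problem
sizes): over 100 batch datasets, median `|ΔB₀|/B₀` ≈ 0.5 % (max 2.6 %)
without background and ≈ 1.7 % with background and blank correction; over
25 fed-batch datasets at the blend kinetics with weekly feedings, median
≈ 1.5 %.

## Plant balances

Three production anchors — annual methane volume (Nm³/y), daily biogas
mass (t/d) and gross biogas energy (MWh/y) — are deliberately independent
scenario inputs. At preliminary-assessment scale they originate in
different sub-models with separately rounded defaults and are not mutually
consistent to the last digit; each balance therefore uses the anchor
closest to it rather than rederiving one from another. A `B₀ × annual VS
mass` pathway is also provided and documents the gap between the kinetic
chain (≈238,000 Nm³/y for plant A) and the configured sizing value
(150,000 Nm³/y).

* **CHP route**: electricity = methane × LHV × η_el with LHV = 9.97
  kWh/Nm³ (standard lower heating value of methane at normal conditions;
  with it, 150,000 Nm³/y × 0.40 → 598 MWh/y, printed as 600,000 kWh/y)
  and η_el = 0.40; engine rating = annual electricity / availability
  (default 8000 h/y).
* **Biomethane route, mass**: fugitive biogas is a direct input (default:
  the 1.6 % CH₄-loss fraction applied to produced biogas); the CH₄ mass
  fraction of the remaining stream follows from the volumetric methane
  content (50 % v/v) and the CH₄/CO₂ densities at normal conditions
  (0.716 / 1.977 kg/Nm³); the upgrading efficiency (default 98.6 %)
  splits that methane into product biomethane and off-gas slip. Closure
  `biogas = biomethane + off-gas + fugitive` holds to 1e−9 t/d by
  construction.
* **Biomethane route, energy**: net useful energy = gross × upgrading
  efficiency; thermal and electric autoconsumptions are covered externally
  (no internal CHP on this route).
* **GHG account** (t CO₂e/y): produced = handling+fugitive term (an input
  from the upstream full-scale model's defaults) + electricity demand ×
  grid factor (337 g CO₂e/kWh) + thermal demand × natural-gas factor
  (206 g CO₂e/kWh); avoided = −net energy × natural-gas factor
  (biomethane) or −(electricity × grid factor + recovered heat × gas
  factor) (CHP). Produced terms are ≥ 0, avoided ≤ 0, and the balance is
  their exact sum.

Two parameter sets exist for the reference plants' autoconsumptions; the
canonical scenarios (`plant_a.yaml`, `plant_b.yaml`) carry the set that
arithmetically reproduces the reference GHG rows, and the alternates ship
as `*_table3.yaml` with a warning header.

## Numerical and reporting conventions

* Year length 365 d. The resulting plant-A substrate flow, 3.0959 t/d,
  is compared to the conventionally reported 3.09 at one unit in the last
  printed digit, since the reported value is not reproducible by
  round-half-away under a 365-d year.
* Report formatting rounds half away from zero to the printed precision
  (2 decimals for potentials, 1 for MWh and t CO₂e, integer kW); internal
  computation is never rounded.
* All gas volumes are at normal conditions (0 °C, 10⁵ Pa).
* Seeded `numpy.random.Generator` everywhere; a fixed seed makes datasets
  bit-reproducible, and the fitter itself is deterministic.

## Known limitations

* Single first-order pool: no multi-stage digestion chain, no inhibition
  (pH, ammonia, VFA), no temperature correction between mesophilic and
  thermophilic regimes.
* The blend predictor weights `(B₀, k)` linearly by mix fraction; real
  co-digestion can be synergistic or antagonistic.
* Upgrading technology is reduced to an efficiency and autoconsumption
  pair; no membrane/amine/PSA process internals.
* The handling+fugitive GHG term and the fugitive mass flow are inputs,
  not mechanistically derived.
* Economics (subsidies, capex/opex) are out of scope.
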