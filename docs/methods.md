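# Methods

## Model

The package treats glycerol biotransformation by resting (non-growing)
*L. reuteri* cells as a four-flux network around the aldehyde branch node:

* v1: glycerol → 3HPA (B12-dependent glycerol/diol dehydratase, PduCDE);
* v2: 3HPA + NADH → 1,3PDO + NAD+ (PduQ);
* v3: 3HPA + NAD+ → 3HP + NADH + ATP, the three oxidative steps
  (PduP, PduL, PduW) lumped into one net flux because the acyl
  intermediates (3HP-CoA, 3HP-phosphate) are intracellular and never
  measured; CoA cycles internally and nets to zero;
* v4: net accumulation of free 3HPA, a bookkeeping flux defined by the
  node balance v4 = |v1| − v2 − v3.

Assumptions: resting cells neither grow nor assimilate glycerol as carbon
(no by-product fluxes, biomass constant); the NAD+/NADH pair cycles only
between v2 and v3, so after the growth-phase NADH carryover has drained
the branches are locked equimolar (v2 = v3); the reactor is well mixed and
isothermal; volume changes only through the feed.

Sign convention: consumption fluxes are stored negative, matching the
published rate tables; balance algebra uses |v1| explicitly. Mass rates
convert through the species each flux is conventionally expressed in
(v1 glycerol 92.09, v2 1,3PDO 76.09, v3 3HP 90.08, v4 3HPA 74.08 g/mol,
fixed 2-decimal standard values, configurable only through the network
config file).

## Rate extraction

Batch mode uses volumetric differences, `Q = (C_f − C_i)/Δt` (g/L.h) and
`q = Q·1000/X` (mg/g_CDW.h, X in g_CDW/L). Variable-volume fed-batch mode
balances mass, `production = (P_f·V_f − P_i·V_i)/Δt`,
`consumption = (S_f·V_f − S_feed·V_feed − S_i·V_i)/Δt` with
`V_feed = F_vol·Δt`, and `q = rate·1000/x` (x total g_CDW). The endpoint
(two-sample) estimator is the default, mirroring the difference equations;
window endpoints snap to the nearest recorded sample and are never
interpolated. A least-squares slope over all in-window samples is
available (`estimator="regression"`) and reports the standard error of the
slope; the endpoint estimator reports none (experimental uncertainty is
instead emulated by duplicate synthetic runs).

Because cofactors carried over from growth inflate early apparent rates,
the default analysis policy excludes the first 10 h of the run plus the
first hour after each feed-rate change. The 10 h figure follows the
published practice; since the first feeding step spans 1–11 h, the exact
intended window is ambiguous, so the policy object exposes both cut-offs.
v4 is taken from the measured 3HPA accumulation, not forced by closure;
the node residual |v1| − v2 − v3 − v4 and redox residual v3 − v2 are
reported as diagnostics (≤ 5% of |v1| is considered closed for estimates
from data; constructed flux vectors close to 1e-9 mmol/g_CDW.h).

## Simulator

No kinetic constants are published for this system, so the simulator uses
the simplest rate laws consistent with the qualitative record, with every
constant exposed in `KineticParams`:

| parameter | default | units | role |
|---|---|---|---|
| vmax_gdh | per scenario | mmol/g_CDW.h | GDH capacity (max \|v1\|) |
| Km_gly | 0.5 | g/L | GDH half-saturation (low-mM literature range) |
| Ki_gly | 150 | g/L | Haldane substrate inhibition of GDH |
| Ki_pdo | 50 | g/L | non-competitive 1,3PDO inhibition of GDH |
| vmax_branch | per scenario | mmol/g_CDW.h | shared branch capacity (max v2 = max v3) |
| Km_hpa | 0.05 | g/L | branch half-saturation for free 3HPA |
| hpa_pdup_threshold | 0.6 | g/L | onset of PduP inhibition |
| pdup_inhibition_depth / width | 0.15 / 0.1 | – / g/L | mild smooth (logistic) penalty above the threshold, keeping the ODE Lipschitz; fluxes demonstrably persist above 1 g/L, hence the shallow depth |
| hpa_toxic_threshold / toxic_width | 3.0 / 0.05 | g/L | logistic GDH shut-off standing in for aldehyde-mediated inactivation and viability loss |
| nadh_pool / nadh_relax | 0.05 / 2.0 | mmol/g_CDW, 1/h | growth-phase NADH carryover and its first-order drawdown (drained well before the 10 h exclusion ends) |
| k_scavenge / scavenger_stoich | 5000 / 1 | L/mol.h, mol/mol | fast irreversible 1:1 carbohydrazide complexation |

GDH: `v1 = vmax_gdh · S/(Km + S + S²/Ki_gly) · Ki_pdo/(Ki_pdo + PDO) ·
gate(A)`. Branches: `r = vmax_branch · A/(Km_hpa + A) · pen(A)` with
`r3 = r` and `r2 = r + nadh_relax·nadh·A/(Km_hpa + A)`; the NADH state
integrates `d(nadh)/dt = r3 − r2`, so redox coupling is enforced
structurally rather than by NAD+/NADH mass action (pool sizes are
unknown; the single-parameter transient reproduces the inflated apparent
early rates). pH is a scenario label selecting calibrated capacities, not
a mechanistic variable. The GDH suicide-inactivation/reactivase cycle is
not simulated (no published constants); the toxicity shut-off is the
coarse stand-in.

The state vector is species amounts in moles plus the NADH pool; volume is
piecewise-linear and exact (`V = V0 + Σ F_vol·in-step time`). Each
constant-feed segment is integrated with LSODA at rtol 1e-8 / atol 1e-10
and sampled on a fixed 0.25 h output grid; rate laws evaluate on
non-negative state projections (no state clipping), and any state more
negative than −1e-7 mol aborts with the failing time. Halving (or
coarsening by two decades) the tolerances moves sampled concentrations by
< 0.1%.

## Calibration of the scenario catalogue

Scenarios encode the published protocols exactly (fed-batch: 1 L, 2 g/L
glycerol, 6 g_CDW, 50 g/L feed at 12/31.1/50 mL/h × 10 h at pH 7 or
12 mL/h × 11 h + 19.8/38.1 mL/h × 10 h at pH 5; batch: 0.5 L, 50 g/L
glycerol, 50.6 g/L carbohydrazide, 6 g_CDW/L). Note the pump rates are
authoritative: 31.1 mL/h × 50 g/L = 1.555 g/h, slightly below the nominal
"1.6 g/h" label.

GDH capacities are anchored to each strain's measured batch uptake (pH 7)
or fitted to the capacity-limited uptake of the middle pH-5 step (wild
type). Branch capacities are fitted by secant iteration
(`estimate.fit_branch_capacity`) so that the simulated analysis-window
3HPA accumulation (pH 7) or 3HP production (pH 5) of the top step matches
the measured value; the fitted numbers are frozen in the catalogue. A
mass-conserving simulator cannot match every cell of rows that do not
close the 3HPA node within their printed values (the mutant pH-7 1.6 g/h
row is open by ≈0.27 mmol/g_CDW.h, and both top pH-5 rows are worse), so
for those cells the catalogue prioritises uptake and the calibrated
branch observable and surfaces the discrepancy through the residual
diagnostics rather than forcing agreement.

## Synthetic data

The measurement model multiplies every concentration observation by
`1 + cv·N(0,1)` (cv default 2%, the scale-free precision typical of HPLC
quantification, giving duplicate-run spreads of the same order as the
published ± values), clamps at zero and zeroes values below a 0.05 g/L
detection floor. Time and volume are controlled variables and stay exact.
Seeding: one master seed with fixed per-replicate sub-streams
(`SeedSequence([seed, replicate])`), recorded in the truth sidecar along
with the noiseless trajectory and the node-closed steady-step fluxes.

What passing tests on these data do show: the difference equations,
exclusion windows and balance algebra recover the generator's fluxes under
realistic noise. What they do not show: robustness to sampling-volume
losses, base-addition dilution (both ignored in the volume bookkeeping —
known bias sources the record does not quantify), sensor drift, or model
error in the hand-written rate laws.

## Known limitations

* The simulated whole-run two-product molar yield of the pH-7 mutant
  protocol is ≈0.94 mol/mol: once the top step's 3HPA accumulation is
  calibrated to the measured rate, ≈5–6% of the fed carbon necessarily
  remains as aldehyde. Yield summaries rounding to "~1 mol/mol" are
  reproduced in direction but not to better than ~0.05.
* In scavenger-batch mode the simulator routes nearly all carbon to the
  complex; the measured batch runs also formed several g/L of 3HP and
  1,3PDO, implying a transiently higher branch capacity during batch
  operation than the fed-batch-calibrated one. Batch product titers are
  therefore indicative only.
* The batch "overall" specific rates are not reproducible from the
  published volumetric rate via q = Q·1000/X (ambiguous Δt/X); the
  formulas are implemented as stated and those cells are not targeted.
* No DHA branch, no growth, no thermodynamics, no genome-scale model and
  no pH mechanism; "linear-phase" batch windows are user-specified.
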