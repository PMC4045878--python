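# pduflux

Metabolic flux analysis of glycerol biotransformation by resting cells of
*Lactobacillus reuteri* through the propanediol-utilization (Pdu) pathway:

```
                 v1                v2  (PduQ, +NADH)
   glycerol  ───────►  3HPA  ──┬──────────►  1,3-propanediol
  (PduCDE, B12)                │
                               │   v3  (PduP→PduL→PduW, +NAD+, +ATP)
                               ├──────────►  3-hydroxypropionic acid
                               │
                               └──  v4 = |v1| − v2 − v3   (net 3HPA accumulation)
```

The aldehyde 3-hydroxypropionaldehyde (3HPA, reuterin) is a rigid branch
node: the reductive branch to 1,3-propanediol (1,3PDO) consumes NADH and
the oxidative branch to 3-hydroxypropionic acid (3HP) regenerates it, so a
closed redox balance in non-growing cells forces **v2 = v3** — equimolar
co-production of the diol and the hydroxyacid. Specific fluxes are carried
in mmol (or mg) per g cell dry weight per hour.

The package is aimed at bioprocess and systems-biology work on glycerol
valorisation with whole-cell biocatalysts. It provides:

* `pduflux.network` — the stoichiometric matrix of the four net fluxes
  (with NADH/NAD+, ATP and CoA rows), unit bridges, node/redox residuals,
  flux split ratio and the redox-constrained branch inference
  `v2 = v3 = (|v1| − v4)/2`;
* `pduflux.rates` — the batch (`Q = ΔP/Δt`, `q = Q·1000/X`) and
  variable-volume fed-batch (`(P_f·V_f − P_i·V_i)/Δt`,
  `(S_f·V_f − S_feed·V_feed − S_i·V_i)/Δt`, `q = rate·1000/x`) rate
  equations, cumulative molar yields and product ratios;
* `pduflux.simulate` — a kinetic ODE simulator of the two published
  resting-cell protocols (multi-step variable-volume fed-batch at stepped
  feed rates; constant-volume batch with a carbohydrazide 3HPA scavenger)
  with a calibrated scenario catalogue for the wild-type (DSM 20016) and
  *pdu*-overexpressing (RPRB3007) strains;
* `pduflux.estimate` — per-feed-step flux extraction from concentration
  time series with start-up/settling exclusion windows, balance
  diagnostics and a Monte-Carlo recovery harness;
* `pduflux.synth` — synthetic datasets (simulated trajectories degraded
  with multiplicative HPLC-like noise plus truth sidecars);
* a `pduflux` command-line tool (`simulate | generate | estimate |
  recover | report`).

## Worked example

Simulate the engineered strain's pH-7 protocol (1 h batch at 2 g/L
glycerol, then 50 g/L glycerol fed at 12, 31.1 and 50 mL/h for 10 h each
to 6 g_CDW of cells in 1 L), then re-estimate the fluxes from the sampled
trajectory:

```sh
pduflux simulate --scenario mutant_ph7 --out runs/
pduflux estimate --input runs/mutant_ph7.csv --scenario mutant_ph7 --out runs/
```

which prints (rates in mg/g_CDW.h, consumption negative):

```
step  feed_g_h      q_S   q_3HPA    q_3HP  q_1,3PDO
   0      0.60   -100.0      0.0     48.9      41.3
   1      1.55   -258.9      0.4    126.4     106.8
   2      2.50   -416.0     36.2    181.4     153.2
max q_3HP = 181.4 (step 2); max q_1,3PDO = 153.2 (step 2)
```

Reading the table: in every step glycerol uptake equals the feed per unit
biocatalyst (the feed is limiting, e.g. 2.5 g/h over 6 g_CDW → ≈417
mg/g_CDW.h); the 3HP and 1,3PDO rates are equimolar (a 50/50 mol% split,
181.4/90.08 ≈ 153.2/76.09 ≈ 2.0 mmol/g_CDW.h); and only in the top step
does the feed outrun the branch capacity, so 3HPA accumulates (q_3HPA =
36.2). The same analysis on noisy synthetic data is one command away
(`pduflux generate`, then `estimate`), and `pduflux recover` quantifies
how well steady-step fluxes survive measurement noise.

The equivalent library calls:

```python
from pduflux import calibrate_scenario, estimate_step_fluxes, simulate

cfg = calibrate_scenario("mutant_ph7")
series = simulate(cfg)
for report in estimate_step_fluxes(series, cfg.schedule):
    print(report.step_index, report.mass_rates, report.split_to_hp)
```

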