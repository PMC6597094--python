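# fcatools

Floating catchment area (FCA) methods for measuring spatial accessibility
to services — typically health care — with a *balanced* variant that
allocates demand and level of service proportionally, so that accessibility
keeps its interpretation as a local provider-to-population ratio (PPR).

## Who this is for

Health geographers, epidemiologists and planners who have (1) a table of
population centers with populations `P_i`, (2) a table of facilities with
supplies `S_j` (physicians, beds, ...), and (3) an origin–destination
travel-cost matrix `d_ij` (minutes), and who want per-facility levels of
service and per-center accessibility under any of the standard FCA
variants, plus diagnostics for the demand/service *inflation* the
unadjusted variants suffer from.

## The methods

All variants share a two-step skeleton built on an impedance
(distance-decay) function `W(d) ∈ [0, 1]`:

**Step 1 (demand and level of service).** `D_j = Σ_i P_i · W1_ij` and
`L_j = S_j / D_j` — a local PPR, to the extent `D_j` is a meaningful head
count.

**Step 2 (accessibility).** `A_i = Σ_j L_j · W2_ij`.

| method | `W1` | `W2` | notes |
|---|---|---|---|
| `2sfca` | `W` (binary) | `W` | classic all-or-nothing catchment |
| `e2sfca` | `W` (stepwise) | `W` | same computation, decaying weights |
| `3sfca` | `G ⊙ W` | `Gʲ ⊙ W` | `G` = row-normalized selection weights |
| `m2sfca` | `W` | `W ⊙ W` | squared impedance in step 2 |
| `balanced` | `Wⁱ` (row-standardized) | `Wʲ` (column-standardized) | mass-conserving |

The unadjusted variants double-count population wherever catchments
overlap: summing `D_j` over facilities can greatly exceed the actual
population (*demand inflation*), and summing `A_i` over centers exceeds
the total level of service (*service inflation*). The balanced variant
standardizes the impedance matrix — `Wⁱ_ij = W_ij / Σ_j W_ij` for demand,
`Wʲ_ij = W_ij / Σ_i W_ij` for service, the row/column standardization
familiar from spatial weights matrices — so each covered center's
population is allocated exactly once (`Σ_j D*_j = Σ P_i`) and each
patronized facility's level of service exactly once
(`Σ_i A*_i = Σ_j L*_j`). Slack factors `kⁱ_i`, `kʲ_j` can deliberately
inflate or deflate a unit's shares to model inefficient sorting, and a
disparity index `A_i − L̄` (with `L̄` the equitable per-center share of
the total level of service) supports equity analysis.

## Worked example

A nine-center, three-clinic system (total population 4,500; supplies
1, 3, 2; regional PPR 1.33 physicians per 1,000) with overlapping
15-minute catchments:

```python
import fcatools as f

scenario, specs = f.simulated_nine_centers()
r = f.run_method(scenario, specs["binary"], "balanced")
print(r.demand.facility_demand)   # [ 708.333 1958.333 1833.333]  — sums to 4500
print(r.los.per_scale)            # [1.412 1.532 1.091]  physicians per 1,000
print(r.access.per_scale)         # [0.353 0.544 0.7 0.7 0.347 ... 0.347]

d = f.disparity(r)
print(d.disparity * 1000)         # [-0.095 0.096 0.252 0.252 -0.101 ... -0.101]
```

Adjusted demand sums exactly to the population of 4,500, and each clinic's
level of service is a genuine local PPR. The disparity column shows
centers 3 and 4 (inside all three catchments) receiving 0.25 per 1,000
more than their equitable share. Running the unadjusted method instead
(`f.run_method(scenario, specs["binary"], "2sfca")`) gives total nominal
demand 9,750 — more than twice the population — and total accessibility
11.8 per 1,000 against a total level of service of only 1.87: the
inflation artifact the balanced variant removes.

The same comparison from the shell:

```sh
fcatools demo simulated --out demo/
fcatools run --centers centers.csv --facilities facilities.csv \
    --costs costs.csv --impedance binary:15 --method 2sfca \
    --compare --out results/
```

`demo` writes the scenario CSVs plus per-method comparison tables;
`run --compare` additionally runs the balanced method and writes
per-facility demand and per-center accessibility inflation ratios.
Impedance strings: `binary:15`, `stepwise:5=0.946,10=0.801,...`,
`gaussian:15@45` (sigma@cutoff), or `gstep:15@5,10,15,20,30,45` to
discretize a Gaussian over breaks (with sigma 15 minutes this yields the
survey-calibrated weights 0.946, 0.801, 0.607, 0.411, 0.135, 0.011).

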