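# Methods

## Model

Floating catchment area (FCA) methods estimate spatial accessibility as an
ensemble of two gravity models. Given populations `P_i` at centers
`i = 1..N`, supplies `S_j` at facilities `j = 1..J`, travel costs `d_ij`
(minutes) and an impedance function `W(d)`, step 1 aggregates demand into
each facility's catchment and converts it to a level of service (LOS),
`D_j = Σ_i P_i W1_ij`, `L_j = S_j / D_j`; step 2 floats the catchments
back and aggregates `A_i = Σ_j L_j W2_ij`. The variants differ only in the
allocation matrices `W1`/`W2` (see the README table). All arithmetic is
dense double-precision linear algebra; there is no randomness anywhere in
the engine, so results are bitwise deterministic given inputs.

Assumptions shared by the whole family: services are undifferentiated
(competing, not complementary); demand is *potential* interaction, not
realized visits; travel cost fully captures the friction of access
(aspatial barriers — cost, language, insurance — are out of scope).

### The balanced variant

The package's central method replaces `W1` with the row-standardized
matrix `Wⁱ_ij = W_ij / Σ_j W_ij` and `W2` with the column-standardized
`Wʲ_ij = W_ij / Σ_i W_ij`. Row shares sum to 1 per covered center, so
`Σ_j D*_j` equals the covered population exactly (a pycnophylactic,
mass-preserving allocation); column shares sum to 1 per patronized
facility, so `Σ_i A*_i = Σ_j L*_j` exactly. Consequences for
interpretation:

- `L*_j` is a genuine local provider-to-population ratio;
- `A*_i` is the share of system LOS a center receives — with one facility
  and `n` covered centers each gets `L*/n`, while the *unadjusted* 2SFCA
  would report `L` for every center. Totals, not per-center values, agree
  with the unadjusted method's population-weighted identity.
- under binary impedance the balanced method is exactly an equal-split
  allocator (each center splits its population equally over reachable
  facilities, each facility splits its LOS equally over reaching centers);
  the test suite checks this against an independent brute-force loop.

Slack factors multiply the standardized shares after normalization
(`kⁱ_i Wⁱ_ij`): a demand slack of 1.10 inflates center i's allocated
demand by 10%, a supply slack of 0.9 deflates facility j's allocated
service by 10%. They model imperfect sorting (incomplete information,
preference for central locations) and default to 1 — exact proportional
allocation. Standardization always starts from the raw impedance weights;
re-standardizing an already standardized matrix is a pipeline error
(row-standardization happens to be idempotent, so the mistake is silent).

### Unadjusted variants and inflation diagnostics

2SFCA/E2SFCA overcount population wherever catchments overlap: a center
inside `K_i` catchments contributes `K_i · P_i` (binary case) to total
demand. The diagnostics module reports `K_i` per center, total nominal
demand vs population, total accessibility vs total LOS, and the
regional vs implied PPR (supply over population vs supply over nominal
demand). The *demand inflation factor* is defined as the unadjusted-to-
balanced facility demand ratio `D_j / D*_j`, mirroring the accessibility
ratio `A_i / A*_i`; both reduce to 1 when catchments form a one-to-one
pairing, and ratios with zero denominators are reported as missing rather
than ±inf.

### 3SFCA interpretation

3SFCA composes selection weights `G_ij = T(d_ij) / Σ_j T(d_ij)` (propensity
of center i to choose facility j; `T` defaults to the same impedance as
`W`, and may be supplied separately, e.g. a Gaussian) with the impedance:
demand uses `G ⊙ W`. For step 2 this implementation uses the symmetric
form with the selection subindices reversed: `A_i = Σ_j Gʲ_ij L*_j W_ij`
where `Gʲ` is the column-normalized analogue of `G`. Published worked
examples of 3SFCA accessibility are not always reconstructible from the
stated formulas (the step-2 selection weights are ambiguous between
row- and column-normalization, and some printed tables appear internally
inconsistent); we document and test the interpretation above, which keeps
the method literal and reproducible, and do not tune toward any printed
accessibility row. 3SFCA demand and LOS are unambiguous and are tested
against worked values.

### M2SFCA

M2SFCA squares the impedance in step 2 (`W2 = W ⊙ W`) to penalize
suboptimally located supply. Step 1 here uses the *same* impedance as
step 2 — worked tables show M2SFCA demand identical to the E2SFCA column
under stepwise impedance — although the method is sometimes described as
sharing 2SFCA's (binary) demand; with matching impedances the two
descriptions coincide anyway. Since all weights are ≤ 1, M2SFCA
accessibility never exceeds the unadjusted value elementwise (tested).

## Impedance functions

- `binary:d0` — 1 for `d ≤ d0`, else 0. `d0 > 0` minutes.
- `stepwise:d1=k1,...` — `k_r` on `(d_{r-1}, d_r]`, 0 beyond `d_R`;
  breaks strictly increasing, weights non-increasing in `(0, 1]`.
  Boundaries are closed on the right: a cost exactly at a break takes the
  nearer ring's weight.
- `gaussian:σ[@cutoff]` — `exp(−d²/2σ²)`, optionally truncated.
- `gstep:σ@d1,d2,...` — Gaussian discretized by evaluating at each upper
  break: with σ = 15 min over breaks (5, 10, 15, 20, 30, 45), weights
  (0.946, 0.801, 0.607, 0.411, 0.135, 0.011) — the travel-survey
  calibration used in practice for urban primary care (median car trip
  ~15 min).

Unreachable pairs (missing OD entries in long CSVs, `inf` costs) have
weight exactly 0 under every kind. Missing means *unreachable*, never
cost 0 — cost 0 would silently create a maximal weight.

## Parameters that matter

| parameter | units | default | rationale |
|---|---|---|---|
| binary threshold `d0` | minutes | 15 (examples) | median car travel time for care-seeking trips in urban systems |
| stepwise breaks/weights | minutes / — | user-supplied | from survey quantiles via `gstep` |
| Gaussian σ | minutes | — | matched to `d0` when both are used |
| LOS reporting scale | persons | 1,000 | PPRs are conventionally per 1,000; stored per person internally |
| slack factors | — | 1 | exact proportional allocation |
| CSV output precision | sig. digits | 6 | readable files; full precision kept in memory |

## Degenerate inputs and numerical choices

- Facilities with zero demand: LOS is undefined (NaN), logged, excluded
  from totals, contributes 0 to accessibility — not an exception, since
  real systems legitimately have unpatronized facilities.
- Centers reaching no facility: zero rows stay zero under standardization
  and are reported as uncovered; balanced totals then conserve the
  *covered* population.
- Ids are matched as trimmed strings; no fuzzy matching. Wide and long
  cost layouts are re-aligned to the entity-table order and must agree
  bit for bit.
- Conservation identities hold to ~1e−12 relative (plain summation at
  these problem sizes); tests assert 1e−10.

## Synthetic data

`random_scenario` places centers and facilities uniformly in a square
region (default 30 × 30, read as minutes via Euclidean distance),
populations log-uniform in [100, 2000] and supplies integer-uniform in
[1, 5] — the few-hundred-to-few-thousand person, few-physician magnitudes
of census-unit analyses. It emulates the *structure* of a real system
(overlapping catchments, skewed populations) but not road-network travel
times, spatially correlated density, or facility size distributions; what
passing property tests show is that the algebraic identities (mass
conservation, the equal-split equivalence, the mass identity
`Σ P_i A_i = Σ S_j` for unadjusted runs, permutation equivariance) hold on
arbitrary geometries, not that any empirical pattern is reproduced.
Property suites run on 100 seeded scenarios of 6–10 centers × 2–5
facilities — sizes at which the brute-force oracles are trivially exact —
and the identities are scale-free, so nothing is lost by staying small.
The two built-in worked examples encode their impedance weight patterns
through constructed cost matrices (3/8/12 minutes for the stepwise rings,
`inf` outside), which the bundled specs map back to the intended weights
exactly.

## Known limitations

- No network routing: costs must be supplied (or Euclidean for synthetic
  work). No geocoding.
- The Huff-model 3SFCA variant, kernel-density and commuter-based FCA
  extensions, and multi-modal travel are out of scope.
- Slack factors are a mechanism, not a calibration: estimating them from
  data or expert opinion is left to the user.
- Disparity measures assume balanced results (conserved totals); they are
  computed for any run but lose their "share of system LOS"
  interpretation on unadjusted results.
- No choropleth mapping; results export to CSV/GeoJSON for GIS tools.
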