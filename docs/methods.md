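# Methods

## Model

The optimisation problem is a capacitated facility-location MIP over a set
of gene banks, each identified with a regional vicinity of farm zones. A
bank can collect a breed in any region where the breed is available, either
at farm zones (incurring the source region's round-trip farm distance `d_j`
on top of the inter-bank distance `D_gb,j`) or at the region's collection
point (inter-bank distance only; zero for a bank's own region). Collected
doses are stored by the collecting bank. The model treats one planning
horizon of `T` years (default 1) with no discounting.

Decision variables: doses collected per (breed, bank, source region) and
mode (`SF`, `SP`, continuous ≥ 0), the implied stock `SB`, one binary
conservation indicator `y_b` per breed and, under campaign costing, one
binary campaign activation per (breed, bank, region, mode). Cost variables
`MC, CC, TC, VC, C` per bank are defined by equality rows so that both
objectives and the budget constraint are linear.

Semicontinuity: a conserved breed's network-wide stock must lie in
[μ_b, M_b], enforced by the indicator pair
`μ_b·y_b ≤ Σ_gb SB_b,gb ≤ M_b·y_b` plus disaggregated variable-upper-bound
rows `SB_b,gb ≤ M_b·y_b`, the standard strengthening for facility-location
LP relaxations. μ_b is 0.8·M_b by default; M_b is the per-species target
collection size (cattle 585, sheep 198, goat 105, horse 58, pig 150,
poultry 46 doses).

## Cost conventions

All monetary quantities are EUR; the bank table stores fixed costs in EUR
(not thousands) to keep every identity in one unit.

* **Maintenance** `MC = T(F + mc·stored)`. The fixed cost `F` of every bank
  in the network is charged whether or not the bank stores anything (a
  network-membership reading); `charge_fixed_always=False` switches to
  charging only occupied banks in the re-pricing engine.
* **Travel** `TC = (doses/k)·tc·dist` with fractional trips (no ceiling),
  `k = 400` doses per trip and `tc = 2.5` EUR/km per bank by default. `d` is
  a round-trip figure and is used as stored; `D` is used as printed, not
  doubled.
* **Collection** has two readings, selected by `costing_mode`:
  * `campaign` (default): mobilising `r = 25` donor animals costs
    `r·cf` (farm) or `r·cc` (collection point) once per
    (breed, bank, region, mode) campaign with positive doses. This is the
    only reading on which the packaged budget range (600–118,800 EUR) and
    per-breed cost figures are meaningful; it is implemented in the MIP with
    activation binaries linked by `SF ≤ demand·z`, plus a covering cut
    `y_b ≤ Σ z` (a conserved breed runs at least one campaign) that keeps
    the LP bound tight.
  * `per_dose`: the literal linear form `r·cf·doses`. It prices a cattle
    dose at ~2,500 EUR and inflates network totals by three orders of
    magnitude; it is retained for fidelity comparisons and used for the
    structural (variable/constraint count) reporting, where the model is
    instantiated over the full breed × bank × region index domain with
    unavailable combinations fixed to zero by bounds.

## Recollection demand

Reallocation scenarios re-collect each breed's full current network-wide
stock (`Σ_gb A_b,gb`). Stocks above the species target M_b exist in the data
(one cattle breed holds 9,670 doses against M = 585), so for such breeds the
semicontinuous interval is extended to the stock itself rather than
truncating the demand. A `clamp_demand_at_M` option implements the
alternative reading (recollect at most M_b per breed); it shrinks network
demand ~14-fold and with it every distance-driven effect, which is why the
full-stock reading is the default: it preserves the dose-proportional
economics under which centralisation is expensive and tank capacities can
bind.

## Scenarios

All scenarios price the same demand, so the baseline is a feasible point of
every relaxation and the dominance chain `SUC ≤ SC50`, `SUC ≤ single:k`,
`SUC ≤ S0` holds by construction (verified in tests).

* **S0** – each bank collects its own holdings from its own region; per
  (breed, bank) the cheaper of farm/point mode is chosen (point wins ties).
  Choosing the cheaper mode makes the baseline as favourable as possible,
  so reported savings of the optimised scenarios are conservative.
* **SUC** – min-cost reallocation, cross-region collection, no capacity.
* **SC50** – as SUC with per-bank tank capacities enforced. Capacities in
  the bank table equal twice the current stocks (stocks at 50% occupancy),
  and a reallocation may use the full tank; `residual_capacity=True`
  instead reserves the currently used half.
* **single:k** – all storage forced to bank *k* (zero bounds on every other
  bank's variables), unlimited capacity. All eleven fixed costs remain
  charged, consistent with the maintenance convention.

## Budget–diversity sweep

Budgets follow the affine grid `B_i = B0 + i(BMax−B0)/n`, i = 1..n. At each
point the model maximises the number of conserved breeds with stocks free
in {0} ∪ [μ, M]. Only variable costs (campaigns, travel, per-dose storage)
count against the budget: the fixed maintenance sum (1.267 M EUR) exceeds
the entire budget grid, so a budget constraint including it would be
trivially infeasible; fixed costs are sunk for the marginal conservation
decision. Two solver aids keep each point exact and fast:

* a lossless dominance reduction for uncapacitated sweeps — any selection
  of breeds can be served by giving each breed its single cheapest
  (bank, region, mode) campaign, so support elsewhere is fixed to zero and
  the model collapses to a knapsack over breeds;
* an ε (10⁻⁶/dose) objective term preferring minimal doses among equal
  breed counts, so the reported spend is the cost of the selection rather
  than an arbitrary budget-filling allocation. The term's total magnitude
  (< 0.15) cannot change the optimal breed count.

Raw per-point optima are reported; monotonicity of D(B) is a property the
test suite asserts, not a post-processing step. Per-species curves solve on
the species-restricted sub-instance.

## Synthetic inventory

The generator reconstructs the unpublished breed × bank survey matrix from
its published aggregates. It emulates: per-bank dose totals (11 banks,
1.647 M doses), species dose shares (cattle 55%, sheep 25%, pig 9%, poultry
4% exactly; goat and horse split the ~7% remainder left by rounding),
concentration of sheep doses in B1/B6/B9 (78% soft target) and pigs in B7
(82%), multi-bank duplication for 10% of breeds (up to 5 banks), and
availability exactly where stock exists. Calibration is by iterative
proportional fitting of a concentration-weighted seed matrix to both
marginals, re-fitted on the occupied cells after breeds are placed, so both
marginals hold to rounding (well under the 0.5% test tolerance on every
seed tried). Breed counts per species are not published; they are derived
by making counts proportional to species doses divided by M (so per-breed
holdings scale with the species' collection size), normalised to 489.
Per-record doses are log-normal splits (σ = 0.8) of each cell.

It does **not** emulate: real breed names or the actual survey breed list,
transboundary status (21 of 489 breeds in reality), within-breed genetic
distinctness across banks, or correlations between a breed's endangerment
and its holdings. Tests passing on this stand-in show the pipeline's
behaviour under the published marginal structure, not conclusions about any
real breed.

## Numerical choices

* Solver: HiGHS branch-and-bound through `scipy.optimize.milp`, sparse
  matrix form; single-threaded and deterministic for a fixed model.
* MIP gap 10⁻⁶ relative, time limit 600 s per solve (network-scale scenario
  solves finish in seconds).
* Solver solutions are independently re-priced by the cost engine; for
  cost-minimisation the re-priced total must match the solver objective to
  10⁻⁶ relative (asserted in tests). Allocation values below 10⁻⁶ doses are
  treated as zero; `y` is derived from the allocation so the indicator
  invariant (y = 1 iff stock > 0) holds exactly even when the raw binary is
  degenerate.
* Ties between equal-cost allocations are broken by the solver; reports
  sort rows by (breed, bank, region, mode) so artifacts are stable.
* The exhaustive oracle (≤ 4 banks, ≤ 5 breeds) enumerates single-combo
  assignments per breed, valid because linear per-dose rates concentrate a
  breed's demand and campaign charges only accumulate under splitting; with
  capacities it rejects violating combinations, which is exact as long as
  capacities never force one breed's demand to split.
* Generator output is a pure function of its config including the seed
  (NumPy `default_rng`); identical configs give byte-identical CSV files.

## Problem sizes

The test suite runs the full 489-breed × 11-bank network for calibration,
scenario-dominance and model-structure checks, a 40-breed network instance
for fast MIP properties, and 3-bank × 4-breed random instances against the
exhaustive oracle. The headline scenario statistics average five generator
seeds; sweeps in tests use 6–10 budget points (the CLI default is n = 100).

## Known limitations

* The collection-cost unit convention is genuinely ambiguous in the source
  cost structure; both readings are provided, and absolute network totals
  differ by orders of magnitude between them. Relative scenario rankings
  are stable, but percentage savings depend on the convention.
* Fixed costs have no activation logic inside the MIP; "only occupied banks
  pay F" is available in re-pricing but is not optimised over.
* Single-year horizon; no discounting, failure rates, or genetic weighting
  of breeds (endangerment, distinctness) — the diversity objective counts
  breeds equally.
* The oracle's concentration argument fails if tank capacities force a
  single breed's demand to split; oracle comparisons therefore use ample
  capacities.
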