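# genebankopt

Least-cost planning of semen collection and cryogenic storage across a
network of livestock gene banks.

European gene banks hold frozen semen doses of hundreds of local cattle,
sheep, goat, horse, pig and poultry breeds as an ex situ backup to live
populations. Collections overlap across countries, and banks differ sharply
in fixed maintenance costs, per-dose storage costs, collection fees and
distance to the farm zones where donor animals live. `genebankopt` is a tool
for conservation planners and resource economists who want to ask: *given a
network of banks and a breed inventory, what is the cheapest way to collect
and store this diversity — and how much diversity does each extra euro buy?*

## The model

The problem is a capacitated facility-location MIP. For breed *b*, bank *gb*
and source region *j* (each bank's vicinity is a region), continuous
variables SF<sub>b,gb,j</sub> and SP<sub>b,gb,j</sub> are the doses collected
by *gb* at the farm zones or at the collection point of region *j*, and
SB<sub>b,gb</sub> = Σ<sub>j</sub>(SF + SP) is the resulting stock. Per-bank
costs decompose as

```
C_gb  = MC_gb + VC_gb                 total
MC_gb = T (F_gb + mc_gb Σ_b SB_b,gb)  maintenance (fixed + per-dose storage)
VC_gb = CC_gb + TC_gb                 collection + travel
TC_gb = (tc_gb/k_gb) Σ_b Σ_j [(d_j + D_gb,j) SF + D_gb,j SP]
```

with travel priced per fractional trip of *k* doses over the inter-bank
distance *D* plus, for farm collection, the source region's round-trip farm
distance *d*. Collection cost CC charges a campaign of *r* donor animals at
the per-animal rate cf (farm) or cc (collection point) once per breed
campaign (a literal per-dose variant is available as
`costing_mode="per_dose"`). A binary indicator y<sub>b</sub> makes each
breed's total stock semicontinuous, μ<sub>b</sub>·y<sub>b</sub> ≤
Σ<sub>gb</sub> SB<sub>b,gb</sub> ≤ M<sub>b</sub>·y<sub>b</sub>: a conserved
breed is collected at between 80% and 100% of its species' target dose count
(585 for cattle down to 46 for poultry). Availability flags
e<sub>b,j</sub> restrict *where* a breed can be collected; any bank may
travel there. Optional constraints cap each bank's cryotank occupancy and
the network-wide spend. The model minimises ΣC<sub>gb</sub>
(cost objective) or maximises Σy<sub>b</sub> (diversity objective), and is
solved with HiGHS branch-and-bound via `scipy.optimize.milp`.

The packaged data cover an 11-bank European network (tables of fixed and
storage costs, tank capacities, current stocks, farm distances, per-species
collection fees, and the symmetric inter-bank distance matrix). The
breed-level survey matrix behind that network is not public, so
`genebankopt.synth` reconstructs a statistically consistent stand-in:
iterative proportional fitting calibrates a bank × species dose matrix to
the published per-bank totals and species shares (55% cattle, 25% sheep, 9%
pig, 4% poultry), honouring the known concentrations (sheep in B1/B6/B9,
pigs in B7) and duplicating ~10% of breeds across banks.

## Worked example

```
$ genebankopt generate --seed 42 --out demo/
wrote instance with 489 breeds to demo

$ genebankopt report demo/ --scenarios S0,SUC,SC50,single:B7 --out demo/comparison.csv
 scenario  status  total_cost_eur  pct_vs_S0
       S0 optimal     2,999,687.1        0.0
     SC50 optimal     2,544,738.0      -15.2
      SUC optimal     2,543,321.0      -15.2
single:B7 optimal     9,350,894.5      211.7
```

`S0` prices the current configuration: every bank re-collects its own
holdings from its own region (cheapest mode per breed). `SUC` is the
least-cost reallocation with cross-region collection and unlimited tanks —
here it cuts the annual bill by 15.2%, mostly by moving campaigns away from
banks with expensive collection fees. `SC50` repeats this with tank
capacities enforced (stocks currently occupy 50% of tanks); only one bank's
optimal load exceeds its tanks, so the saving barely changes. Forcing the
whole collection into the single largest bank (`single:B7`) triples the
cost: cross-country travel for 1.6 million doses dwarfs any storage saving.
Scenario solves on this 489-breed × 11-bank instance take a few seconds
each.

The budget–diversity frontier (`genebankopt sweep demo/ --b0 600 --bmax
118800 --n 100 --out curve.csv`) reports, per budget level, the maximum
number of breeds conservable when only variable costs count against the
budget, and the marginal cost per extra breed.

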