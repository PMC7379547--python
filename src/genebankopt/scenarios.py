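"""Named reallocation scenarios and their comparison.

* ``S0``   – the current configuration: each bank recollects its own holdings
             from its own region, choosing farm vs collection-point mode per
             breed to minimise cost; no optimisation across banks.
* ``SUC``  – least-cost reallocation with cross-region collection and
             unlimited tank capacity.
* ``SC50`` – as SUC but per-bank tank capacities enforced (capacities equal
             twice the currently stored doses, i.e., stocks sit at 50% of
             capacity, and a reallocation may use the full tanks).
* ``single:<bank>`` – all breeds forced into one bank, unlimited capacity.

All scenarios price the same recollection demand (each breed's full
network-wide current stock), so the baseline allocation is a feasible point
of every relaxed model and the dominance chain
cost(SUC) <= cost(SC50), cost(SUC) <= cost(single:k), cost(SUC) <= cost(S0)
holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .costs import Allocation, CostBreakdown, CostingMode, collection_cost, \
    price_allocation, travel_cost
from .instance import Instance
from .model import ModelConfig, Solution, build_model, effective_demand, solve

__all__ = ["ScenarioSpec", "ScenarioResult", "run_S0", "run_scenario",
           "compare_scenarios", "allocation_summary"]

SINGLE_PREFIX = "single:"


@dataclass(frozen=True)
class ScenarioSpec:
    """A named scenario; resolves to exactly one model configuration."""

    name: str
    costing_mode: CostingMode = "campaign"
    residual_capacity: bool = False   # SC50: use cp - current instead of cp
    mip_gap: float = 1e-6
    time_limit: float = 600.0

    def model_config(self) -> ModelConfig:
        base = ModelConfig(objective="min_cost", demand_rule="recollect_current",
                           costing_mode=self.costing_mode, mip_gap=self.mip_gap,
                           time_limit=self.time_limit, drop_unavailable=True)
        if self.name == "SUC":
            return base
        if self.name == "SC50":
            return replace(base, capacity_on=True)
        if self.name.startswith(SINGLE_PREFIX):
            return replace(base, forced_bank=self.name[len(SINGLE_PREFIX):])
        raise ValueError(f"unknown scenario {self.name!r}")


@dataclass(frozen=True)
class ScenarioResult:
    spec: ScenarioSpec
    solution: Solution
    relative_cost_vs_S0: float | None = None   # percent; negative = saving

    @property
    def total_cost(self) -> float:
        return self.solution.total_cost

    @property
    def status(self) -> str:
        return self.solution.solver_status


def run_S0(instance: Instance, costing_mode: CostingMode = "campaign") -> ScenarioResult:
    """Price the current configuration without cross-bank optimisation.

    Each breed's recollection demand equals its current stocks per storing
    bank; every bank collects from its own region, in whichever of the two
    modes is cheaper for that breed there (point wins ties: equal cost with
    no travel).
    """
    demand = effective_demand(instance)
    stock = instance.inventory.stock()
    species_of = instance.inventory.species_of()
    totals: dict[str, float] = {}
    for (b, _), a in stock.items():
        totals[b] = totals.get(b, 0.0) + a

    rows = []
    for (breed, bank), a in sorted(stock.items()):
        if a <= 0 or totals[breed] <= 0:
            continue
        doses = demand[breed] * a / totals[breed]
        sp = species_of[breed]
        cost_mode = {}
        for mode in ("farm", "point"):
            cost_mode[mode] = (collection_cost(instance, sp, bank, mode, doses,
                                               costing_mode)
                               + travel_cost(instance, bank, bank, mode, doses))
        mode = "point" if cost_mode["point"] <= cost_mode["farm"] else "farm"
        rows.append((breed, bank, bank, mode, doses))
    allocation = Allocation.from_records(rows)
    breakdown = price_allocation(instance, allocation, costing_mode=costing_mode)
    y = {b: int(demand.get(b, 0.0) > 0) for b in instance.inventory.breeds()}
    sol = Solution(allocation=allocation, y=y, breakdown=breakdown,
                   objective_value=breakdown.total, solver_status="optimal")
    return ScenarioResult(spec=ScenarioSpec(name="S0", costing_mode=costing_mode),
                          solution=sol, relative_cost_vs_S0=0.0)


def run_scenario(instance: Instance, spec: ScenarioSpec,
                 s0: ScenarioResult | None = None) -> ScenarioResult:
    """Run one scenario; the relative cost is computed against a supplied or
    freshly priced baseline."""
    if spec.name == "S0":
        return run_S0(instance, costing_mode=spec.costing_mode)
    config = spec.model_config()
    if spec.name == "SC50" and spec.residual_capacity:
        banks = tuple(replace(b, cp=max(b.cp - b.current_doses, 0.0))
                      for b in instance.banks)
        instance_cap = replace(instance, banks=banks)
        model = build_model(instance_cap, config)
    else:
        model = build_model(instance, config)
    sol = solve(model)
    if s0 is None:
        s0 = run_S0(instance, costing_mode=spec.costing_mode)
    rel = None
    if sol.solver_status in ("optimal", "feasible") and s0.total_cost > 0:
        rel = 100.0 * (sol.total_cost - s0.total_cost) / s0.total_cost
    return ScenarioResult(spec=spec, solution=sol, relative_cost_vs_S0=rel)


def compare_scenarios(instance: Instance, specs: list[ScenarioSpec]) -> pd.DataFrame:
    """One row per scenario: total cost, percent vs S0, per-bank occupancy."""
    s0 = run_S0(instance, costing_mode=specs[0].costing_mode if specs else "campaign")
    rows = []
    for spec in specs:
        res = s0 if spec.name == "S0" else run_scenario(instance, spec, s0=s0)
        occ = res.solution.allocation.stored_by_bank()
        row = {"scenario": spec.name, "status": res.status,
               "total_cost_eur": res.total_cost,
               "pct_vs_S0": res.relative_cost_vs_S0}
        for g in instance.bank_ids:
            row[f"doses_{g}"] = occ.get(g, 0.0)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("scenario", ignore_index=True)


def allocation_summary(instance: Instance, solution: Solution) -> pd.DataFrame:
    """Bank x species dose totals of a solution's allocation."""
    species_of = instance.inventory.species_of()
    df = solution.allocation.to_frame()
    if df.empty:
        return pd.DataFrame(columns=["bank", "species", "doses"])
    df["species"] = df["breed"].map(species_of)
    out = (df.groupby(["bank", "species"], as_index=False)
             .agg(doses=("doses", "sum")))
    return out.sort_values(["bank", "species"], ignore_index=True)
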