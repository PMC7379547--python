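"""Budget–diversity frontiers and marginal cost per conserved breed.

For a grid of budgets B_i = B0 + i*(BMax - B0)/n (i = 1..n), the model
maximises the number of conserved breeds subject to spending at most B_i,
with each conserved breed's stock free in [mu, M] (semicontinuous). Only
variable costs — collection campaigns, travel and per-dose storage — count
against the budget: the network's fixed maintenance costs are sunk for the
purposes of choosing *which* breeds to add, and the interesting budget range
sits far below their sum. D(B) is nondecreasing by relaxation dominance; raw
optima are reported, monotonicity is a property to verify, not enforce.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .costs import collection_cost, travel_cost
from .instance import Instance
from .model import MipModel, ModelConfig, build_model, solve

__all__ = ["SweepConfig", "SweepResult", "budget_grid", "run_sweep", "marginal_costs"]


@dataclass(frozen=True)
class SweepConfig:
    B0: float
    BMax: float
    n: int
    species_filter: tuple[str, ...] | None = None
    capacity_on: bool = False
    costing_mode: str = "campaign"
    mip_gap: float = 1e-6
    time_limit: float = 600.0

    def __post_init__(self):
        if not (0 <= self.B0 < self.BMax):
            raise ValueError("need 0 <= B0 < BMax")
        if self.n < 1:
            raise ValueError("need n >= 1")


@dataclass(frozen=True)
class SweepResult:
    config: SweepConfig
    table: pd.DataFrame   # columns: i, B_i, D_i, cost_used, feasible


def budget_grid(config: SweepConfig) -> list[float]:
    """B_i = B0 + i*(BMax - B0)/n for i = 1..n (endpoint B_n = BMax)."""
    step = (config.BMax - config.B0) / config.n
    return [config.B0 + i * step for i in range(1, config.n + 1)]


def _restrict_species(instance: Instance, keep: tuple[str, ...]) -> Instance:
    records = tuple(r for r in instance.inventory.records if r.species in keep)
    return instance.with_inventory(replace(instance.inventory, records=records))


def cheapest_combo(instance: Instance, breed: str,
                   costing_mode: str = "campaign") -> tuple[str, str, str, float]:
    """The (bank, region, mode) minimising the cost of conserving one breed
    at its minimum collection mu, and that cost (campaign + travel + one
    year's variable storage). Ties break lexicographically."""
    sp = instance.inventory.species_of()[breed]
    mu = instance.species_params(sp).mu
    regions = sorted(j for (b, j), f in instance.inventory.availability().items()
                     if b == breed and f)
    best = None
    for g in instance.bank_ids:
        for j in regions:
            for mode in ("farm", "point"):
                c = (collection_cost(instance, sp, g, mode, mu, costing_mode)
                     + travel_cost(instance, g, j, mode, mu)
                     + instance.T * instance.bank(g).mc * mu)
                key = (c, g, j, mode)
                if best is None or key < best:
                    best = key
    c, g, j, mode = best
    return g, j, mode, c


def _restrict_to_cheapest(model: MipModel) -> None:
    """Dominance reduction for uncapacitated budget sweeps.

    With no tank-capacity coupling, any selection of breeds can be served by
    giving each breed its single cheapest (bank, region, mode) campaign at
    minimal doses, at no loss of diversity; support elsewhere is fixed to
    zero by bounds. Lossless for the optimum, and it collapses the search to
    a knapsack over breeds the solver handles quickly.
    """
    inst = model.instance
    chosen = {b: cheapest_combo(inst, b, model.config.costing_mode)[:3]
              for b in model.breeds}
    g_idx = {g: i for i, g in enumerate(model.banks)}
    b_idx = {b: i for i, b in enumerate(model.breeds)}
    pick = {(b_idx[b], g_idx[g], g_idx[j]): mode
            for b, (g, j, mode) in chosen.items()}
    nt = model.triples.shape[0]
    for i, (b, g, j) in enumerate(model.triples):
        mode = pick.get((b, g, j))
        if mode != "farm":
            model.ub[model.off_sf + i] = 0.0
        if mode != "point":
            model.ub[model.off_sp + i] = 0.0
    if model.z_triples is not None:
        for i, (b, g, j) in enumerate(model.z_triples):
            mode = pick.get((b, g, j))
            if mode != "farm":
                model.ub[model.off_zf + i] = 0.0
            if mode != "point":
                model.ub[model.off_zp + i] = 0.0


def run_sweep(instance: Instance, config: SweepConfig) -> SweepResult:
    """Solve the diversity-maximisation model at every budget point.

    ``cost_used`` is the independently re-priced variable cost (collection +
    travel + per-dose storage) of the optimal selection; ``D_i`` counts the
    breeds with positive stock.
    """
    if config.species_filter is not None:
        instance = _restrict_species(instance, tuple(config.species_filter))
    fixed = instance.T * sum(b.F for b in instance.banks)
    rows = []
    for i, B_i in enumerate(budget_grid(config), start=1):
        mconfig = ModelConfig(
            objective="max_diversity", demand_rule="free_semicontinuous",
            diversity_measure="breed_count", costing_mode=config.costing_mode,
            capacity_on=config.capacity_on, budget_on=True, TB=B_i,
            budget_includes_fixed=False, mip_gap=config.mip_gap,
            time_limit=config.time_limit, drop_unavailable=True)
        model = build_model(instance, mconfig)
        if not config.capacity_on:
            _restrict_to_cheapest(model)
        sol = solve(model)
        feasible = sol.solver_status in ("optimal", "feasible")
        D_i = int(sum(sol.y.values())) if feasible else None
        cost_used = (sol.breakdown.total - fixed) if feasible else None
        rows.append({"i": i, "B_i": B_i, "D_i": D_i,
                     "cost_used": cost_used, "feasible": feasible})
    return SweepResult(config=config, table=pd.DataFrame(rows))


def marginal_costs(result: SweepResult) -> dict:
    """Per-step marginal cost dB/dD between consecutive budget points with a
    diversity gain; rows where diversity decreases (solver-gap noise) are
    excluded. Also reports the min/max marginal over the curve and the
    average cost per conserved breed at the final (saturation) point."""
    df = result.table[result.table["feasible"]].reset_index(drop=True)
    steps = []
    for a, b in zip(df.itertuples(), df.iloc[1:].itertuples()):
        dD = b.D_i - a.D_i
        if dD > 0:
            steps.append({"i_from": a.i, "i_to": b.i,
                          "dB": b.B_i - a.B_i, "dD": dD,
                          "marginal_eur_per_breed": (b.B_i - a.B_i) / dD})
    steps_df = pd.DataFrame(steps, columns=["i_from", "i_to", "dB", "dD",
                                            "marginal_eur_per_breed"])
    out = {"steps": steps_df,
           "min_marginal": steps_df["marginal_eur_per_breed"].min() if len(steps_df) else None,
           "max_marginal": steps_df["marginal_eur_per_breed"].max() if len(steps_df) else None,
           "avg_cost_per_breed_at_saturation": None}
    if len(df) and df.iloc[-1]["D_i"]:
        out["avg_cost_per_breed_at_saturation"] = (
            float(df.iloc[-1]["cost_used"]) / int(df.iloc[-1]["D_i"]))
    return out
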