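"""The gene-bank collection MIP: build, solve, count, and a brute-force oracle.

The decision problem is a capacitated facility-location model. Continuous
variables SF[b,gb,j] / SP[b,gb,j] are the doses of breed ``b`` collected by
bank ``gb`` at the farm zones / collection point of region ``j`` (regions are
identified with bank vicinities); SB[b,gb] is the resulting stock. A binary
indicator y_b linearises the semicontinuous requirement that a conserved
breed's total stock lies in [mu_b, M_b]:

    mu_b * y_b  <=  sum_gb SB[b,gb]  <=  M_b * y_b

together with disaggregated variable-upper-bound rows SB[b,gb] <= M_b * y_b,
the standard strengthening of facility-location formulations. Per-bank cost
variables MC/CC/TC/VC/C are defined by equality rows so the objective is
simply sum_gb C_gb; diversity maximisation optimises sum_b y_b instead.

Two demand regimes exist: ``recollect_current`` fixes each breed's total to
its current network-wide stock clamped at M_b (reallocation scenarios), and
``free_semicontinuous`` lets the model choose any total in {0} u [mu, M]
(budget sweeps). Under campaign costing, activation binaries z per
(breed, bank, region, mode) carry the once-per-campaign collection charge,
linked by SF <= demand * z.

The model is assembled in sparse matrix form and solved with the HiGHS
branch-and-bound solver via ``scipy.optimize.milp``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .costs import Allocation, CostBreakdown, price_allocation
from .instance import Instance

__all__ = ["ModelConfig", "Solution", "InfeasibleModelError", "build_model",
           "solve", "brute_force_min_cost", "count_model_size", "effective_demand"]


class InfeasibleModelError(ValueError):
    """The configuration is structurally infeasible before any solve."""


@dataclass(frozen=True)
class ModelConfig:
    objective: Literal["min_cost", "max_diversity"] = "min_cost"
    demand_rule: Literal["recollect_current", "free_semicontinuous"] = "recollect_current"
    capacity_on: bool = False
    budget_on: bool = False
    TB: float | None = None
    budget_includes_fixed: bool = True
    forced_bank: str | None = None
    costing_mode: Literal["campaign", "per_dose"] = "campaign"
    diversity_measure: Literal["breed_count", "total_doses"] = "breed_count"
    # Clamp recollection demand at the species maximum M instead of
    # recollecting full current stocks (stocks above M then stay uncollected).
    clamp_demand_at_M: bool = False
    charge_fixed_always: bool = True
    mip_gap: float = 1e-6
    time_limit: float = 600.0
    # Instantiate SF/SP over all source regions (unavailable ones fixed to
    # zero by bounds) or only over available ones. Same optimum either way.
    drop_unavailable: bool = False


@dataclass(frozen=True)
class Solution:
    allocation: Allocation
    y: dict[str, int]
    breakdown: CostBreakdown
    objective_value: float | None
    solver_status: Literal["optimal", "feasible", "infeasible", "unbounded", "failed"]
    achieved_gap: float | None = None

    @property
    def total_cost(self) -> float:
        return self.breakdown.total


def effective_demand(instance: Instance, clamp_at_M: bool = False) -> dict[str, float]:
    """Per-breed recollection demand: the breed's current network-wide stock
    (optionally clamped at the species maximum M, in which case stocks above
    M are not recollected in full)."""
    totals: dict[str, float] = {}
    species_of = instance.inventory.species_of()
    for r in instance.inventory.records:
        totals[r.breed] = totals.get(r.breed, 0.0) + r.A
    if not clamp_at_M:
        return totals
    return {b: min(a, instance.species_params(species_of[b]).M)
            for b, a in totals.items()}


@dataclass
class MipModel:
    """Built model handle: sparse constraint system plus index bookkeeping."""

    instance: Instance
    config: ModelConfig
    c: np.ndarray
    A: sp.csr_matrix
    row_lb: np.ndarray
    row_ub: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    integrality: np.ndarray
    breeds: list[str]
    banks: list[str]
    triples: np.ndarray          # (n_triples, 3) of (b, g, j) indices for SF/SP
    off_sf: int
    off_sp: int
    off_sb: int
    off_y: int
    off_zf: int | None = None    # campaign activation binaries, farm block
    off_zp: int | None = None    # ... point block (aligned with z triples)
    z_triples: np.ndarray | None = None

    @property
    def n_variables(self) -> int:
        return self.c.size

    @property
    def n_constraints(self) -> int:
        return self.A.shape[0]


def build_model(instance: Instance, config: ModelConfig) -> MipModel:
    """Instantiate the MIP in sparse matrix form for the given instance."""
    if config.mip_gap < 0:
        raise ValueError("mip_gap must be nonnegative")
    if config.budget_on and config.TB is None:
        raise ValueError("budget_on requires TB")
    banks = instance.bank_ids
    G = len(banks)
    if config.forced_bank is not None and config.forced_bank not in banks:
        raise ValueError(f"forced_bank {config.forced_bank!r} not in instance")
    breeds = instance.inventory.breeds()
    B = len(breeds)
    species_of = instance.inventory.species_of()
    b_index = {b: i for i, b in enumerate(breeds)}
    g_index = {g: i for i, g in enumerate(banks)}

    e = np.zeros((B, G), dtype=bool)
    for (breed, region), flag in instance.inventory.availability().items():
        if flag:
            e[b_index[breed], g_index[region]] = True

    M = np.array([instance.species_params(species_of[b]).M for b in breeds])
    mu = np.array([instance.species_params(species_of[b]).mu for b in breeds])
    r_par = np.array([instance.species_params(species_of[b]).r for b in breeds])

    recollect = config.demand_rule == "recollect_current"
    if recollect:
        dem_map = effective_demand(instance, clamp_at_M=config.clamp_demand_at_M)
        demand = np.array([dem_map[b] for b in breeds])
        if np.any((demand > 0) & ~e.any(axis=1)):
            bad = [breeds[i] for i in np.flatnonzero((demand > 0) & ~e.any(axis=1))]
            raise InfeasibleModelError(
                f"breeds with demand but no available region: {bad[:5]}")
        cap = demand.copy()
        mu_eff = np.minimum(mu, demand)
    else:
        demand = None
        cap = M.copy()
        mu_eff = mu.copy()

    # --- SF/SP index triples (b, g, j)
    if config.drop_unavailable:
        bb, jj = np.nonzero(e)
        tb = np.repeat(bb, G)
        tj = np.repeat(jj, G)
        tg = np.tile(np.arange(G), bb.size)
    else:
        tb, tg, tj = np.unravel_index(np.arange(B * G * G), (B, G, G))
    nt = tb.size

    off_sf = 0
    off_sp = nt
    off_sb = 2 * nt
    off_y = off_sb + B * G
    off_mc = off_y + B
    off_cc = off_mc + G
    off_tc = off_cc + G
    off_vc = off_tc + G
    off_c = off_vc + G
    n_vars = off_c + G

    campaign = config.costing_mode == "campaign"
    if campaign:
        zb, zj = np.nonzero(e)
        ztb = np.repeat(zb, G)
        ztj = np.repeat(zj, G)
        ztg = np.tile(np.arange(G), zb.size)
        nz = ztb.size                      # one z per mode: farm block, point block
        off_zf = n_vars
        off_zp = n_vars + nz
        n_vars += 2 * nz
        if config.drop_unavailable:
            zf_sf = np.arange(nt)          # aligned with the SF triples
        else:
            zf_sf = ztb * G * G + ztg * G + ztj
    else:
        nz = 0

    # --- bounds
    lb = np.zeros(n_vars)
    ub = np.full(n_vars, np.inf)
    avail = e[tb, tj]
    ub[off_sf:off_sf + nt] = np.where(avail, cap[tb], 0.0)
    ub[off_sp:off_sp + nt] = np.where(avail, cap[tb], 0.0)
    sb_b, sb_g = np.unravel_index(np.arange(B * G), (B, G))
    ub[off_sb:off_sb + B * G] = cap[sb_b]
    ub[off_y:off_y + B] = 1.0
    if campaign:
        ub[off_zf:off_zf + 2 * nz] = 1.0
    if config.forced_bank is not None:
        gf = g_index[config.forced_bank]
        ub[off_sf:off_sf + nt][tg != gf] = 0.0
        ub[off_sp:off_sp + nt][tg != gf] = 0.0
        ub[off_sb:off_sb + B * G][sb_g != gf] = 0.0
        if campaign:
            ub[off_zf:off_zf + nz][ztg != gf] = 0.0
            ub[off_zp:off_zp + nz][ztg != gf] = 0.0

    integrality = np.zeros(n_vars)
    integrality[off_y:off_y + B] = 1
    if campaign:
        integrality[off_zf:off_zf + 2 * nz] = 1

    # --- constraint rows, accumulated as COO entries
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    row_lb: list[np.ndarray] = []
    row_ub: list[np.ndarray] = []
    n_rows = 0

    def add_block(rr, cc, vv, lo, hi, count):
        nonlocal n_rows
        rows.append(np.asarray(rr) + n_rows)
        cols.append(np.asarray(cc))
        vals.append(np.asarray(vv, dtype=float))
        row_lb.append(np.asarray(lo, dtype=float))
        row_ub.append(np.asarray(hi, dtype=float))
        n_rows += count

    # (1) stock definition: SB[b,g] - sum_j (SF + SP) = 0
    rdef = np.concatenate([np.arange(B * G), tb * G + tg, tb * G + tg])
    cdef = np.concatenate([off_sb + np.arange(B * G),
                           off_sf + np.arange(nt), off_sp + np.arange(nt)])
    vdef = np.concatenate([np.ones(B * G), -np.ones(2 * nt)])
    add_block(rdef, cdef, vdef, np.zeros(B * G), np.zeros(B * G), B * G)

    # (2) disaggregated linking: SB[b,g] - cap_b * y_b <= 0
    rvub = np.concatenate([np.arange(B * G)] * 2)
    cvub = np.concatenate([off_sb + np.arange(B * G), off_y + sb_b])
    vvub = np.concatenate([np.ones(B * G), -cap[sb_b]])
    add_block(rvub, cvub, vvub, np.full(B * G, -np.inf), np.zeros(B * G), B * G)

    # (3) aggregate upper: sum_g SB[b,g] - cap_b * y_b <= 0
    ragg = np.concatenate([sb_b, np.arange(B)])
    cagg = np.concatenate([off_sb + np.arange(B * G), off_y + np.arange(B)])
    vagg = np.concatenate([np.ones(B * G), -cap])
    add_block(ragg, cagg, vagg, np.full(B, -np.inf), np.zeros(B), B)

    # (4) aggregate lower: mu_eff_b * y_b - sum_g SB[b,g] <= 0
    rlow = np.concatenate([np.arange(B), sb_b])
    clow = np.concatenate([off_y + np.arange(B), off_sb + np.arange(B * G)])
    vlow = np.concatenate([mu_eff, -np.ones(B * G)])
    add_block(rlow, clow, vlow, np.full(B, -np.inf), np.zeros(B), B)

    # (5) recollection demand: sum_g SB[b,g] = demand_b
    if recollect:
        add_block(sb_b, off_sb + np.arange(B * G), np.ones(B * G),
                  demand, demand, B)

    # (6) campaign activation links: SF <= cap_b * z
    if campaign:
        rz = np.concatenate([np.arange(nz), np.arange(nz),
                             nz + np.arange(nz), nz + np.arange(nz)])
        cz = np.concatenate([off_sf + zf_sf, off_zf + np.arange(nz),
                             off_sp + zf_sf, off_zp + np.arange(nz)])
        vz = np.concatenate([np.ones(nz), -cap[ztb],
                             np.ones(nz), -cap[ztb]])
        add_block(rz, cz, vz, np.full(2 * nz, -np.inf), np.zeros(2 * nz), 2 * nz)
        # covering cut: a conserved breed runs at least one campaign
        # (y_b - sum z <= 0); valid always, tightens the LP bound sharply
        rcov = np.concatenate([np.arange(B), ztb, ztb])
        ccov = np.concatenate([off_y + np.arange(B),
                               off_zf + np.arange(nz), off_zp + np.arange(nz)])
        vcov = np.concatenate([np.ones(B), -np.ones(2 * nz)])
        add_block(rcov, ccov, vcov, np.full(B, -np.inf), np.zeros(B), B)

    # --- cost definition rows (per bank)
    T = instance.T
    mc_g = np.array([instance.bank(g).mc for g in banks])
    F_g = np.array([instance.bank(g).F for g in banks])
    tc_g = np.array([instance.bank(g).tc for g in banks])
    k_g = np.array([instance.bank(g).k for g in banks])
    d_g = np.array([instance.bank(g).d for g in banks])
    Dmat = np.array([[instance.distances(i, j) for j in banks] for i in banks])
    cf_arr = np.array([[instance.costs.farm(g, species_of[b]) for g in banks]
                       for b in breeds])
    cc_arr = np.array([[instance.costs.point(g, species_of[b]) for g in banks]
                       for b in breeds])

    # (7) MC_g - T*mc_g * sum_b SB[b,g] = T*F_g (F dropped if only-used banks pay)
    rhs_F = T * F_g if config.charge_fixed_always else np.zeros(G)
    rmc = np.concatenate([np.arange(G), sb_g])
    cmc = np.concatenate([off_mc + np.arange(G), off_sb + np.arange(B * G)])
    vmc = np.concatenate([np.ones(G), -T * mc_g[sb_g]])
    add_block(rmc, cmc, vmc, rhs_F, rhs_F, G)
    if not config.charge_fixed_always:
        # F_g charged iff the bank stores anything: needs per-bank use binaries;
        # handled by scenario-level re-pricing instead of inside the MIP.
        pass

    # (8) CC_g definition
    if campaign:
        unit_f = r_par[ztb] * cf_arr[ztb, ztg]
        unit_p = r_par[ztb] * cc_arr[ztb, ztg]
        rcc = np.concatenate([np.arange(G), ztg, ztg])
        ccc = np.concatenate([off_cc + np.arange(G),
                              off_zf + np.arange(nz), off_zp + np.arange(nz)])
        vcc = np.concatenate([np.ones(G), -unit_f, -unit_p])
    else:
        unit_f = r_par[tb] * cf_arr[tb, tg]
        unit_p = r_par[tb] * cc_arr[tb, tg]
        rcc = np.concatenate([np.arange(G), tg, tg])
        ccc = np.concatenate([off_cc + np.arange(G),
                              off_sf + np.arange(nt), off_sp + np.arange(nt)])
        vcc = np.concatenate([np.ones(G), -unit_f, -unit_p])
    add_block(rcc, ccc, vcc, np.zeros(G), np.zeros(G), G)

    # (9) TC_g definition: rate * ((d_j + D_gj)*SF + D_gj*SP)
    rate = tc_g[tg] / k_g[tg]
    w_farm = rate * (d_g[tj] + Dmat[tg, tj])
    w_point = rate * Dmat[tg, tj]
    rtc = np.concatenate([np.arange(G), tg, tg])
    ctc = np.concatenate([off_tc + np.arange(G),
                          off_sf + np.arange(nt), off_sp + np.arange(nt)])
    vtc = np.concatenate([np.ones(G), -w_farm, -w_point])
    add_block(rtc, ctc, vtc, np.zeros(G), np.zeros(G), G)

    # (10) VC_g = CC_g + TC_g ; (11) C_g = MC_g + VC_g
    rvc = np.concatenate([np.arange(G)] * 3)
    cvc = np.concatenate([off_vc + np.arange(G), off_cc + np.arange(G),
                          off_tc + np.arange(G)])
    vvc = np.concatenate([np.ones(G), -np.ones(G), -np.ones(G)])
    add_block(rvc, cvc, vvc, np.zeros(G), np.zeros(G), G)
    rc = np.concatenate([np.arange(G)] * 3)
    ccol = np.concatenate([off_c + np.arange(G), off_mc + np.arange(G),
                           off_vc + np.arange(G)])
    vc = np.concatenate([np.ones(G), -np.ones(G), -np.ones(G)])
    add_block(rc, ccol, vc, np.zeros(G), np.zeros(G), G)

    # (12) tank capacity
    if config.capacity_on:
        cp_g = np.array([instance.bank(g).cp for g in banks])
        add_block(sb_g, off_sb + np.arange(B * G), np.ones(B * G),
                  np.full(G, -np.inf), cp_g, G)

    # (13) budget
    if config.budget_on:
        tb_limit = config.TB
        if not config.budget_includes_fixed and config.charge_fixed_always:
            tb_limit = tb_limit + T * F_g.sum()
        add_block(np.zeros(G), off_c + np.arange(G), np.ones(G),
                  [-np.inf], [tb_limit], 1)

    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_rows, n_vars)).tocsr()

    c = np.zeros(n_vars)
    if config.objective == "min_cost":
        c[off_c:off_c + G] = 1.0
    elif config.diversity_measure == "breed_count":
        c[off_y:off_y + B] = -1.0
        # epsilon tiebreak: among equal breed counts prefer minimal doses so
        # realized spend is meaningful; total effect << 1 breed
        c[off_sb:off_sb + B * G] = 1e-6
    else:
        c[off_sb:off_sb + B * G] = -1.0

    return MipModel(
        instance=instance, config=config, c=c, A=A,
        row_lb=np.concatenate(row_lb), row_ub=np.concatenate(row_ub),
        lb=lb, ub=ub, integrality=integrality,
        breeds=breeds, banks=banks,
        triples=np.column_stack([tb, tg, tj]),
        off_sf=off_sf, off_sp=off_sp, off_sb=off_sb, off_y=off_y,
        off_zf=off_zf if campaign else None,
        off_zp=off_zp if campaign else None,
        z_triples=np.column_stack([ztb, ztg, ztj]) if campaign else None)


def count_model_size(model: MipModel) -> tuple[int, int]:
    """(variables, constraint rows) as instantiated; simple bounds excluded."""
    return model.n_variables, model.n_constraints


def solve(model: MipModel, config: ModelConfig | None = None) -> Solution:
    """Solve the built model with HiGHS branch-and-bound."""
    config = config or model.config
    res = milp(
        c=model.c,
        constraints=LinearConstraint(model.A, model.row_lb, model.row_ub),
        bounds=Bounds(model.lb, model.ub),
        integrality=model.integrality,
        options={"mip_rel_gap": config.mip_gap,
                 "time_limit": config.time_limit,
                 "disp": False})
    status_map = {0: "optimal", 1: "feasible", 2: "infeasible",
                  3: "unbounded", 4: "failed"}
    status = status_map.get(res.status, "failed")
    if res.x is None:
        empty = Allocation(records=())
        breakdown = price_allocation(model.instance, empty,
                                     costing_mode=config.costing_mode,
                                     charge_fixed_always=config.charge_fixed_always)
        return Solution(allocation=empty, y={b: 0 for b in model.breeds},
                        breakdown=breakdown, objective_value=None,
                        solver_status="infeasible" if status == "infeasible" else "failed")

    x = res.x
    tol = 1e-6
    recs = []
    for off, mode in ((model.off_sf, "farm"), (model.off_sp, "point")):
        vals = x[off:off + model.triples.shape[0]]
        for idx in np.flatnonzero(vals > tol):
            b, g, j = model.triples[idx]
            recs.append((model.breeds[b], model.banks[g], model.banks[j],
                         mode, float(vals[idx])))
    allocation = Allocation.from_records(recs)
    sb_tot = allocation.SB()
    totals: dict[str, float] = {}
    for (breed, _), v in sb_tot.items():
        totals[breed] = totals.get(breed, 0.0) + v
    y = {b: int(totals.get(b, 0.0) > tol) for b in model.breeds}
    breakdown = price_allocation(model.instance, allocation,
                                 costing_mode=config.costing_mode,
                                 charge_fixed_always=config.charge_fixed_always)
    if model.config.objective == "min_cost":
        objective = float(res.fun)
    elif model.config.diversity_measure == "breed_count":
        objective = float(sum(y.values()))
    else:
        objective = float(sum(totals.values()))
    gap = getattr(res, "mip_gap", None)
    return Solution(allocation=allocation, y=y, breakdown=breakdown,
                    objective_value=objective, solver_status=status,
                    achieved_gap=None if gap is None else float(gap))


# ---------------------------------------------------------------------------
# Exhaustive oracle for tiny instances

MAX_ORACLE_BANKS = 4
MAX_ORACLE_BREEDS = 5
_MAX_COMBOS = 200_000


def brute_force_min_cost(instance: Instance,
                         costing_mode: Literal["campaign", "per_dose"] = "campaign",
                         capacity_on: bool = False) -> Solution:
    """Exhaustive minimum-cost recollection for tiny instances.

    Per breed, every assignment of its full demand to a single
    (collecting bank, available source region, mode) triple is enumerated;
    concentrating a breed's demand is optimal because per-dose rates are
    linear and campaign charges only accumulate when demand is split. Each
    combination is priced with the independent cost engine; combinations
    violating tank capacities are rejected (valid as long as capacities do
    not force a single breed's demand to split across banks).
    """
    banks = instance.bank_ids
    breeds = instance.inventory.breeds()
    if len(banks) > MAX_ORACLE_BANKS or len(breeds) > MAX_ORACLE_BREEDS:
        raise ValueError(
            f"oracle limited to {MAX_ORACLE_BANKS} banks and "
            f"{MAX_ORACLE_BREEDS} breeds; got {len(banks)} x {len(breeds)}")
    demand = effective_demand(instance)
    avail = instance.inventory.availability()
    options: list[list[tuple[str, str, str]]] = []
    active = [b for b in breeds if demand[b] > 0]
    for b in active:
        regions = sorted(j for (bb, j), f in avail.items() if bb == b and f)
        opts = [(g, j, mode) for g in banks for j in regions
                for mode in ("farm", "point")]
        opts.sort()
        options.append(opts)
    n_combos = int(np.prod([len(o) for o in options])) if options else 1
    if n_combos > _MAX_COMBOS:
        raise ValueError(f"combination count {n_combos} exceeds {_MAX_COMBOS}")

    cp = {g: instance.bank(g).cp for g in banks}
    best = None
    best_alloc = None
    for combo in itertools.product(*options):
        if capacity_on:
            load = dict.fromkeys(banks, 0.0)
            for b, (g, _, _) in zip(active, combo):
                load[g] += demand[b]
            if any(load[g] > cp[g] + 1e-9 for g in banks):
                continue
        alloc = Allocation.from_records(
            [(b, g, j, mode, demand[b]) for b, (g, j, mode) in zip(active, combo)])
        cost = price_allocation(instance, alloc, costing_mode=costing_mode).total
        if best is None or cost < best - 1e-12:
            best, best_alloc = cost, alloc
    if best_alloc is None:
        empty = Allocation(records=())
        return Solution(allocation=empty, y={b: 0 for b in breeds},
                        breakdown=price_allocation(instance, empty,
                                                   costing_mode=costing_mode),
                        objective_value=None, solver_status="infeasible")
    breakdown = price_allocation(instance, best_alloc, costing_mode=costing_mode)
    y = {b: int(demand.get(b, 0.0) > 0) for b in breeds}
    return Solution(allocation=best_alloc, y=y, breakdown=breakdown,
                    objective_value=best, solver_status="optimal")
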