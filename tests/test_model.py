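"""MIP model: structure, oracle equivalence, semicontinuity, dominance."""

import dataclasses

import pytest

from genebankopt.instance import BreedInventory, InventoryRecord, fixture_instance
from genebankopt.model import (
    InfeasibleModelError, ModelConfig, brute_force_min_cost, build_model,
    count_model_size, effective_demand, solve,
)

from conftest import make_tiny_instance


def structural_counts(B, G, recollect=True):
    """Hand formula for the literal (per-dose) model: SF+SP over the full
    b x gb x j domain, SB, y, five cost variables per bank; stock definition,
    disaggregated + aggregate linking, lower bound, demand, cost rows."""
    n_vars = 2 * B * G * G + B * G + B + 5 * G
    n_rows = 2 * B * G + (3 if recollect else 2) * B + 5 * G
    return n_vars, n_rows


class TestStructure:
    def test_minimal_model_counts(self):
        inv = BreedInventory(records=(
            InventoryRecord(breed="b", species="cattle", bank="B1", A=100.0, e=1),))
        inst = dataclasses.replace(fixture_instance(inv),
                                   banks=fixture_instance(inv).banks[:1])
        model = build_model(inst, ModelConfig(costing_mode="per_dose"))
        assert count_model_size(model) == structural_counts(1, 1)

    def test_counts_match_formula_at_network_scale(self, network_instance):
        model = build_model(network_instance, ModelConfig(costing_mode="per_dose"))
        assert count_model_size(model) == structural_counts(489, 11)

    def test_counts_invariant_to_cost_values(self, small_instance):
        cfg = ModelConfig(costing_mode="per_dose")
        doubled = dataclasses.replace(
            small_instance, costs=dataclasses.replace(
                small_instance.costs,
                cf={k: 2 * v for k, v in small_instance.costs.cf.items()},
                cc={k: 3 * v for k, v in small_instance.costs.cc.items()}))
        assert count_model_size(build_model(small_instance, cfg)) == \
            count_model_size(build_model(doubled, cfg))

    def test_capacity_and_budget_add_rows(self, small_instance):
        base = build_model(small_instance, ModelConfig())
        cap = build_model(small_instance, ModelConfig(capacity_on=True))
        bud = build_model(small_instance, ModelConfig(budget_on=True, TB=1e9))
        G = len(small_instance.banks)
        assert cap.n_constraints == base.n_constraints + G
        assert bud.n_constraints == base.n_constraints + 1

    def test_uncollectable_breed_reported_before_solve(self):
        inv = BreedInventory(records=(
            InventoryRecord(breed="b", species="cattle", bank="B1", A=100.0, e=0),))
        inst = dataclasses.replace(fixture_instance(
            BreedInventory(records=(InventoryRecord(
                breed="b", species="cattle", bank="B1", A=100.0, e=1),))),
            inventory=inv)
        with pytest.raises(InfeasibleModelError):
            build_model(inst, ModelConfig())


class TestOracleEquivalence:
    @pytest.mark.parametrize("costing", ["campaign", "per_dose"])
    def test_mip_matches_exhaustive_enumeration(self, costing):
        for seed in range(20):
            inst = make_tiny_instance(seed)
            oracle = brute_force_min_cost(inst, costing_mode=costing)
            sol = solve(build_model(inst, ModelConfig(costing_mode=costing,
                                                      drop_unavailable=True)))
            assert sol.solver_status == "optimal"
            assert sol.objective_value == pytest.approx(
                oracle.objective_value, rel=1e-6), f"seed {seed}"

    def test_oracle_refuses_large_instances(self, small_instance):
        with pytest.raises(ValueError, match="oracle"):
            brute_force_min_cost(small_instance)

    def test_tie_break_prefers_first_option(self):
        inst = make_tiny_instance(0, n_banks=2, n_breeds=1)
        # make the two banks economically identical
        b1, b2 = inst.banks
        b2 = dataclasses.replace(b2, F=b1.F, mc=b1.mc, d=b1.d, cp=b1.cp)
        cf = {k: 100.0 for k in inst.costs.cf}
        cc = {k: 100.0 for k in inst.costs.cc}
        D = {k: (0.0 if k[0] == k[1] else 10.0) for k in inst.distances.D}
        inv = BreedInventory(records=(
            InventoryRecord(breed="b0", species="cattle", bank="G1", A=100.0, e=1),
            InventoryRecord(breed="b0", species="cattle", bank="G2", A=0.0, e=1)))
        inst = dataclasses.replace(
            inst, banks=(b1, b2),
            costs=dataclasses.replace(inst.costs, cf=cf, cc=cc),
            distances=dataclasses.replace(inst.distances, D=D), inventory=inv)
        sol = brute_force_min_cost(inst)
        (record,) = sol.allocation.records
        assert (record.bank, record.region, record.mode) == ("G1", "G1", "farm") \
            or record.bank == "G1"   # lexicographically first bank wins the tie


class TestSolutionProperties:
    def test_conservation_collected_equals_demand(self, small_instance):
        sol = solve(build_model(small_instance, ModelConfig(drop_unavailable=True)))
        demand = effective_demand(small_instance)
        totals = {}
        for (b, _), v in sol.allocation.SB().items():
            totals[b] = totals.get(b, 0.0) + v
        for breed, d in demand.items():
            assert totals.get(breed, 0.0) == pytest.approx(d, rel=1e-6)

    def test_repricing_matches_solver_objective(self, small_instance):
        for costing in ("campaign", "per_dose"):
            sol = solve(build_model(small_instance, ModelConfig(
                costing_mode=costing, drop_unavailable=True)))
            assert sol.breakdown.total == pytest.approx(sol.objective_value, rel=1e-6)

    def test_forced_bank_concentrates_storage(self, small_instance):
        sol = solve(build_model(small_instance, ModelConfig(
            forced_bank="B7", drop_unavailable=True)))
        assert sol.solver_status == "optimal"
        assert set(r.bank for r in sol.allocation.records) == {"B7"}

    def test_availability_respected(self, small_instance):
        sol = solve(build_model(small_instance, ModelConfig(drop_unavailable=True)))
        avail = small_instance.inventory.availability()
        for r in sol.allocation.records:
            assert avail.get((r.breed, r.region), 0) == 1

    def test_relaxation_dominance(self):
        for seed in (1, 5, 9):
            inst = make_tiny_instance(seed)
            base = solve(build_model(inst, ModelConfig(drop_unavailable=True)))
            capped = solve(build_model(inst, ModelConfig(
                capacity_on=True, drop_unavailable=True)))
            forced = solve(build_model(inst, ModelConfig(
                forced_bank=inst.bank_ids[0], drop_unavailable=True)))
            if capped.solver_status == "optimal":
                assert capped.objective_value >= base.objective_value - 1e-6
            if forced.solver_status == "optimal":
                assert forced.objective_value >= base.objective_value - 1e-6

    def test_semicontinuous_totals(self):
        inst = make_tiny_instance(2)
        for TB in (5_000.0, 20_000.0, 100_000.0):
            sol = solve(build_model(inst, ModelConfig(
                objective="max_diversity", demand_rule="free_semicontinuous",
                budget_on=True, TB=TB, budget_includes_fixed=False,
                drop_unavailable=True)))
            totals = {}
            for (b, _), v in sol.allocation.SB().items():
                totals[b] = totals.get(b, 0.0) + v
            for breed, tot in totals.items():
                sp = inst.inventory.species_of()[breed]
                params = inst.species_params(sp)
                assert tot <= params.M + 1e-6
                assert tot >= params.mu - 1e-6 or tot <= 1e-6

    def test_diversity_nondecreasing_in_budget(self):
        inst = make_tiny_instance(4)
        counts = []
        for TB in (2_000.0, 10_000.0, 50_000.0, 200_000.0):
            sol = solve(build_model(inst, ModelConfig(
                objective="max_diversity", demand_rule="free_semicontinuous",
                budget_on=True, TB=TB, budget_includes_fixed=False,
                drop_unavailable=True)))
            counts.append(sum(sol.y.values()))
        assert counts == sorted(counts)

    def test_y_indicator_consistent_with_stock(self, small_instance):
        sol = solve(build_model(small_instance, ModelConfig(drop_unavailable=True)))
        totals = {}
        for (b, _), v in sol.allocation.SB().items():
            totals[b] = totals.get(b, 0.0) + v
        for breed, flag in sol.y.items():
            assert flag == int(totals.get(breed, 0.0) > 1e-6)
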