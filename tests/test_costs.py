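"""Cost engine: frozen arithmetic on the packaged tables and structural
properties (additivity, linearity, identities)."""

import dataclasses

import pytest

from genebankopt.costs import (
    Allocation, collection_cost, maintenance_cost, price_allocation, travel_cost,
)
from genebankopt.instance import BreedInventory, InventoryRecord, fixture_instance


@pytest.fixture(scope="module")
def inst():
    inv = BreedInventory(records=(
        InventoryRecord(breed="herd1", species="cattle", bank="B2", A=400.0, e=1),
        InventoryRecord(breed="flock1", species="poultry", bank="B5", A=40.0, e=1)))
    return fixture_instance(inv)


class TestMaintenance:
    @pytest.mark.parametrize("bank_id,doses,expected", [
        ("B1", 303_888, 155_466.56),   # F + mc*doses on the largest French bank
        ("B5", 2_062, 46_000.56),
    ])
    def test_storage_cost_arithmetic(self, inst, bank_id, doses, expected):
        assert maintenance_cost(inst.bank(bank_id), doses, T=1.0) == pytest.approx(expected)

    def test_zero_stock_costs_exactly_fixed(self, inst):
        for g in inst.bank_ids:
            assert maintenance_cost(inst.bank(g), 0.0) == inst.bank(g).F

    def test_negative_inputs_rejected(self, inst):
        with pytest.raises(ValueError):
            maintenance_cost(inst.bank("B1"), -1.0)


class TestCollection:
    def test_campaign_charges_once_per_campaign(self, inst):
        # 25 donors x 50 EUR at B2's farm zones, independent of dose count
        assert collection_cost(inst, "cattle", "B2", "farm", 400, "campaign") == 1250.0
        assert collection_cost(inst, "cattle", "B2", "farm", 10_000, "campaign") == 1250.0
        assert collection_cost(inst, "poultry", "B5", "point", 37, "campaign") == 25.0

    def test_per_dose_mode_scales_with_doses(self, inst):
        assert collection_cost(inst, "cattle", "B2", "farm", 400, "per_dose") == \
            pytest.approx(25 * 50 * 400)

    @pytest.mark.parametrize("mode", ["campaign", "per_dose"])
    def test_zero_doses_zero_cost(self, inst, mode):
        assert collection_cost(inst, "cattle", "B2", "farm", 0, mode) == 0.0


class TestTravel:
    def test_cross_region_collection_point(self, inst):
        # one trip of 400 doses over the 39.7 km B2-B11 hop
        assert travel_cost(inst, "B2", "B11", "point", 400) == pytest.approx(99.25)

    def test_own_region_point_is_free(self, inst):
        for g in inst.bank_ids:
            assert travel_cost(inst, g, g, "point", 4000) == 0.0

    def test_own_region_farm_uses_round_trip_distance(self, inst):
        assert travel_cost(inst, "B1", "B1", "farm", 400) == pytest.approx(500.0)

    def test_fractional_trips(self, inst):
        assert travel_cost(inst, "B1", "B1", "farm", 200) == pytest.approx(250.0)


class TestPriceAllocation:
    def test_empty_allocation_is_fixed_costs_only(self, inst):
        bd = price_allocation(inst, Allocation(records=()))
        assert bd.total == pytest.approx(1_267_000.0)
        assert all(v == 0.0 for v in bd.CC.values())

    def test_componentwise_single_record(self, inst):
        alloc = Allocation.from_records([("herd1", "B2", "B2", "farm", 400.0)])
        bd = price_allocation(inst, alloc, costing_mode="campaign")
        assert bd.MC["B2"] == pytest.approx(41_000 + 0.56 * 400)
        assert bd.CC["B2"] == pytest.approx(1_250.0)
        assert bd.TC["B2"] == pytest.approx((400 / 400) * 2.5 * 300)
        assert bd.C["B2"] == pytest.approx(bd.MC["B2"] + bd.VC["B2"])

    def test_doubling_collection_rates_doubles_cc_only(self, inst):
        alloc = Allocation.from_records([("herd1", "B2", "B2", "farm", 400.0),
                                         ("flock1", "B5", "B5", "point", 37.0)])
        doubled = dataclasses.replace(
            inst, costs=dataclasses.replace(
                inst.costs,
                cf={k: 2 * v for k, v in inst.costs.cf.items()},
                cc={k: 2 * v for k, v in inst.costs.cc.items()}))
        bd1, bd2 = price_allocation(inst, alloc), price_allocation(doubled, alloc)
        assert sum(bd2.CC.values()) == pytest.approx(2 * sum(bd1.CC.values()))
        assert bd2.MC == bd1.MC and bd2.TC == bd1.TC

    def test_variable_costs_additive_over_disjoint_allocations(self, inst):
        a = Allocation.from_records([("herd1", "B2", "B2", "farm", 400.0)])
        b = Allocation.from_records([("flock1", "B5", "B5", "point", 37.0)])
        both = Allocation.from_records(
            [("herd1", "B2", "B2", "farm", 400.0), ("flock1", "B5", "B5", "point", 37.0)])
        bd_a, bd_b, bd_ab = (price_allocation(inst, x) for x in (a, b, both))
        for g in inst.bank_ids:
            assert bd_ab.CC[g] == pytest.approx(bd_a.CC[g] + bd_b.CC[g])
            assert bd_ab.TC[g] == pytest.approx(bd_a.TC[g] + bd_b.TC[g])

    def test_unknown_breed_rejected(self, inst):
        with pytest.raises(KeyError):
            price_allocation(inst, Allocation.from_records(
                [("ghost", "B2", "B2", "farm", 1.0)]))
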