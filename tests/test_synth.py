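"""Synthetic inventory generator: calibration, determinism, overlap."""

from dataclasses import replace

import pytest

from genebankopt.synth import (
    CalibrationError, default_generator_config, generate_inventory,
    inventory_summary,
)
from genebankopt.instance import BreedInventory, InventoryRecord


def bank_totals(inventory):
    out = {}
    for r in inventory.records:
        out[r.bank] = out.get(r.bank, 0.0) + r.A
    return out


def species_shares(inventory):
    tot, by_sp = 0.0, {}
    for r in inventory.records:
        tot += r.A
        by_sp[r.species] = by_sp.get(r.species, 0.0) + r.A
    return {sp: v / tot for sp, v in by_sp.items()}


class TestDefaultConfig:
    def test_network_wide_defaults(self):
        cfg = default_generator_config()
        assert cfg.n_breeds == 489
        assert cfg.bank_dose_totals["B7"] == pytest.approx(441_235)
        assert sum(cfg.normalized_shares().values()) == pytest.approx(1.0)
        assert cfg.species_dose_shares["cattle"] == pytest.approx(0.55)


class TestCalibration:
    @pytest.mark.parametrize("seed", range(20))
    def test_marginals_within_half_percent(self, seed):
        cfg = default_generator_config(seed=seed)
        inv = generate_inventory(cfg)
        totals = bank_totals(inv)
        for b, target in cfg.bank_dose_totals.items():
            assert abs(totals[b] - target) <= 0.005 * target, b
        shares = species_shares(inv)
        for sp, target in cfg.normalized_shares().items():
            assert abs(shares[sp] - target) <= 0.005 * target, sp

    def test_exact_breed_count_and_collectability(self, default_inventory):
        breeds = default_inventory.breeds()
        assert len(breeds) == 489
        avail = default_inventory.availability()
        for b in breeds:
            assert any(flag for (bb, _), flag in avail.items() if bb == b)

    def test_concentration_rules_shape_distribution(self, default_inventory):
        shares = {}
        for r in default_inventory.records:
            shares.setdefault(r.species, {}).setdefault(r.bank, 0.0)
            shares[r.species][r.bank] += r.A
        sheep = shares["sheep"]
        assert sum(sheep.get(b, 0) for b in ("B1", "B6", "B9")) / sum(sheep.values()) > 0.6
        pig = shares["pig"]
        assert pig.get("B7", 0) / sum(pig.values()) > 0.6


class TestDeterminismAndOverlap:
    def test_same_seed_identical_output(self):
        cfg = default_generator_config(seed=7)
        assert generate_inventory(cfg) == generate_inventory(cfg)

    def test_overlap_fraction_honoured(self, default_inventory):
        multi = sum(1 for b in default_inventory.breeds()
                    if len([r for r in default_inventory.records if r.breed == b]) > 1)
        assert multi == round(0.10 * 489)

    def test_zero_overlap_means_single_bank_breeds(self):
        cfg = replace(default_generator_config(seed=3), overlap_fraction=0.0)
        inv = generate_inventory(cfg)
        for b in inv.breeds():
            assert len([r for r in inv.records if r.breed == b]) == 1

    def test_availability_iff_stock(self, default_inventory):
        for r in default_inventory.records:
            assert (r.A > 0) == (r.e == 1)


class TestSummaryAndErrors:
    def test_summary_marginals_exact(self, default_inventory):
        summ = inventory_summary(default_inventory)
        assert summ["doses"].sum() == pytest.approx(
            sum(r.A for r in default_inventory.records))
        assert summ["breeds"].ge(1).all()

    def test_empty_inventory_empty_summary(self):
        assert inventory_summary(BreedInventory(records=())).empty

    def test_single_breed_summary(self):
        inv = BreedInventory(records=(
            InventoryRecord(breed="x", species="goat", bank="B1", A=100.0, e=1),))
        summ = inventory_summary(inv)
        assert len(summ) == 1
        assert summ.loc[0, "doses"] == 100.0 and summ.loc[0, "breeds"] == 1

    def test_infeasible_configs_raise(self):
        cfg = default_generator_config()
        with pytest.raises(CalibrationError):
            generate_inventory(replace(cfg, n_breeds=5))   # cannot cover 11 banks
        with pytest.raises(CalibrationError):
            generate_inventory(replace(cfg, species_dose_shares={"cattle": 0.0}))
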