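"""Deterministic cost accounting for a fixed collection/storage allocation.

The cost of running the network decomposes per bank ``gb`` as

    C_gb  = MC_gb + VC_gb
    MC_gb = T * (F_gb + mc_gb * stored_gb)          maintenance
    VC_gb = CC_gb + TC_gb                           variable (collection)
    TC_gb = (tc_gb / k_gb) * sum over collections of
            (d_j + D_gb,j) * farm doses  +  D_gb,j * point doses

Collection cost CC supports two unit conventions:

``campaign`` (default)
    A collection campaign for one breed mobilises ``r`` donor animals once;
    the charge ``r * cf`` (farm) or ``r * cc`` (collection point) is incurred
    once per (breed, bank, source region, mode) with positive doses. This is
    the scale consistent with the packaged budget range and per-breed cost
    figures.
``per_dose``
    The literal linear reading: ``r * cf`` charged per dose. Retained for
    fidelity comparisons; it prices a cattle dose at thousands of EUR.

Travel uses fractional trips (doses / k); ``d`` is the (round-trip) distance
of the *source* region's farm zones, ``D`` the inter-bank distance as given.
This module is independent of the optimisation model and is used both to
price the baseline and to re-price solver solutions as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .instance import Instance

Mode = Literal["farm", "point"]
CostingMode = Literal["campaign", "per_dose"]

__all__ = ["Allocation", "AllocationRecord", "CostBreakdown", "maintenance_cost",
           "collection_cost", "travel_cost", "price_allocation"]


@dataclass(frozen=True)
class AllocationRecord:
    """Doses of one breed collected by `bank` in `region` in a given mode."""
    breed: str
    bank: str
    region: str
    mode: Mode
    doses: float


@dataclass(frozen=True)
class Allocation:
    records: tuple[AllocationRecord, ...]

    @classmethod
    def from_records(cls, rows: Iterable[tuple[str, str, str, str, float]]) -> "Allocation":
        recs = tuple(AllocationRecord(breed=b, bank=g, region=j, mode=m, doses=float(x))
                     for b, g, j, m, x in rows)
        return cls(records=tuple(sorted(
            recs, key=lambda r: (r.breed, r.bank, r.region, r.mode))))

    def stored_by_bank(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for r in self.records:
            out[r.bank] = out.get(r.bank, 0.0) + r.doses
        return out

    def SB(self) -> dict[tuple[str, str], float]:
        """Doses of each breed stored per bank (summed over source regions)."""
        out: dict[tuple[str, str], float] = {}
        for r in self.records:
            out[(r.breed, r.bank)] = out.get((r.breed, r.bank), 0.0) + r.doses
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.breed, r.bank, r.region, r.mode, r.doses) for r in self.records],
            columns=["breed", "bank", "region", "mode", "doses"])


@dataclass(frozen=True)
class CostBreakdown:
    """Per-bank cost components (EUR); identities C=MC+VC, VC=CC+TC hold."""

    MC: dict[str, float]
    CC: dict[str, float]
    TC: dict[str, float]

    @property
    def VC(self) -> dict[str, float]:
        return {g: self.CC[g] + self.TC[g] for g in self.MC}

    @property
    def C(self) -> dict[str, float]:
        return {g: self.MC[g] + self.CC[g] + self.TC[g] for g in self.MC}

    @property
    def total(self) -> float:
        return sum(self.C.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, self.MC[g], self.CC[g], self.TC[g], self.VC[g], self.C[g])
                for g in self.MC]
        return pd.DataFrame(rows, columns=["bank", "MC", "CC", "TC", "VC", "C"])


def maintenance_cost(bank, stored_doses: float, T: float = 1.0) -> float:
    """T * (F + mc * stored). The fixed cost F is charged even at zero stock."""
    if stored_doses < 0 or T < 0:
        raise ValueError("stored_doses and T must be nonnegative")
    return T * (bank.F + bank.mc * stored_doses)


def collection_cost(instance: Instance, species: str, bank: str, mode: Mode,
                    doses: float, costing_mode: CostingMode = "campaign") -> float:
    """Collection charge for one (breed, bank, region, mode) record."""
    if doses < 0:
        raise ValueError("doses must be nonnegative")
    if doses == 0:
        return 0.0
    sp = instance.species_params(species)
    unit = (instance.costs.farm(bank, species) if mode == "farm"
            else instance.costs.point(bank, species))
    if costing_mode == "campaign":
        return sp.r * unit
    return sp.r * unit * doses


def travel_cost(instance: Instance, bank: str, region: str, mode: Mode,
                doses: float) -> float:
    """Travel cost of collecting `doses` in `region`; fractional trips."""
    if doses < 0:
        raise ValueError("doses must be nonnegative")
    b = instance.bank(bank)
    D = instance.distances(bank, region)
    dist = D + (instance.bank(region).d if mode == "farm" else 0.0)
    return (doses / b.k) * b.tc * dist


def price_allocation(instance: Instance, allocation: Allocation,
                     costing_mode: CostingMode = "campaign",
                     charge_fixed_always: bool = True) -> CostBreakdown:
    """Assemble the full per-bank cost breakdown of an allocation.

    With ``charge_fixed_always`` (default) every bank in the network carries
    its fixed cost F; otherwise only banks with positive stored doses do
    (relevant to single-bank centralisation accounting).
    """
    species_of = instance.inventory.species_of()
    bank_ids = instance.bank_ids
    MC = dict.fromkeys(bank_ids, 0.0)
    CC = dict.fromkeys(bank_ids, 0.0)
    TC = dict.fromkeys(bank_ids, 0.0)

    stored = dict.fromkeys(bank_ids, 0.0)
    # campaign charges are per distinct (breed, bank, region, mode) with doses>0
    agg: dict[tuple[str, str, str, str], float] = {}
    for r in allocation.records:
        if r.bank not in stored:
            raise KeyError(f"allocation references unknown bank {r.bank!r}")
        if r.breed not in species_of:
            raise KeyError(f"allocation references unknown breed {r.breed!r}")
        key = (r.breed, r.bank, r.region, r.mode)
        agg[key] = agg.get(key, 0.0) + r.doses

    for (breed, bank, region, mode), doses in agg.items():
        if doses == 0:
            continue
        stored[bank] += doses
        CC[bank] += collection_cost(instance, species_of[breed], bank, mode,
                                    doses, costing_mode)
        TC[bank] += travel_cost(instance, bank, region, mode, doses)

    for g in bank_ids:
        b = instance.bank(g)
        fixed = b.F if (charge_fixed_always or stored[g] > 0) else 0.0
        MC[g] = instance.T * (fixed + b.mc * stored[g])
    return CostBreakdown(MC=MC, CC=CC, TC=TC)
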