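"""Domain types, validation and CSV round-trip for gene-bank network instances.

An *instance* bundles everything the optimisation model needs: the banks with
their economic parameters (fixed maintenance cost ``F``, per-dose storage cost
``mc``, tank capacity ``cp``, distance ``d`` to the farm zones of their own
region), per-bank and per-species collection costs at farm zones (``cf``) and
at collection points (``cc``), the symmetric inter-bank distance matrix ``D``,
species-level collection parameters (maximum ``M`` and minimum ``mu`` doses per
breed, donors ``r`` per campaign) and the breed-level inventory: how many doses
``A`` of each breed each bank currently stores and where each breed is
available for collection (``e``).

All monetary values are stored in EUR (never thousands), distances in km,
stock in semen doses.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

SPECIES_ORDER = ("cattle", "goat", "horse", "pig", "poultry", "sheep")

REQUIRED_FILES = {
    "banks.csv": ["id", "location", "F_eur", "mc_eur_per_dose", "cp_doses",
                  "current_doses", "d_km", "tc_eur_per_km", "k_doses_per_trip"],
    "collection_costs.csv": ["bank", "species", "cf_eur_per_animal", "cc_eur_per_animal"],
    "distances.csv": ["id"],
    "species.csv": ["species", "M_doses", "mu_factor", "r_animals"],
    "inventory.csv": ["breed", "species", "bank", "A_doses", "e_available"],
}


class InstanceFormatError(ValueError):
    """A required file or column is missing or unparseable."""


class InstanceValidationError(ValueError):
    """An instance invariant is violated; message names the offending record."""


@dataclass(frozen=True)
class SpeciesParams:
    """Collection parameters for one species.

    M is the maximum number of semen doses collected per breed, ``mu_factor``
    the fraction of M that is the minimum worthwhile collection, and ``r`` the
    number of donor animals a collection campaign requires.
    """

    species: str
    M: float
    mu_factor: float = 0.8
    r: float = 25.0

    @property
    def mu(self) -> float:
        return self.mu_factor * self.M


@dataclass(frozen=True)
class Bank:
    """One gene bank and the economics of its region."""

    id: str
    location: str
    F: float                  # fixed annual maintenance cost, EUR/year
    mc: float                 # liquid-N / storage cost, EUR/dose/year
    cp: float                 # cryotank capacity, doses
    current_doses: float      # total doses currently stored
    d: float                  # round-trip distance bank <-> farm zones, km
    tc: float = 2.5           # travel cost, EUR/km
    k: float = 400.0          # doses collected per journey


@dataclass(frozen=True)
class CollectionCostTable:
    """Per (bank, species) campaign costs: cf at farm zones, cc at the
    collection centre, both EUR per donor animal."""

    cf: Mapping[tuple[str, str], float]
    cc: Mapping[tuple[str, str], float]

    def farm(self, bank: str, species: str) -> float:
        return self.cf[(bank, species)]

    def point(self, bank: str, species: str) -> float:
        return self.cc[(bank, species)]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric inter-bank distances in km, zero on the diagonal."""

    D: Mapping[tuple[str, str], float]

    def __call__(self, i: str, j: str) -> float:
        return self.D[(i, j)]


@dataclass(frozen=True)
class InventoryRecord:
    breed: str
    species: str
    bank: str
    A: float   # doses currently stored in `bank`
    e: int     # 1 if the breed is available for collection in `bank`'s region


@dataclass(frozen=True)
class BreedInventory:
    """Breed-level stocks and availability across the bank network."""

    records: tuple[InventoryRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def breeds(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.breed, None)
        return sorted(seen)

    def species_of(self) -> dict[str, str]:
        return {r.breed: r.species for r in self.records}

    def stock(self) -> dict[tuple[str, str], float]:
        """A[breed, bank] summed over records."""
        out: dict[tuple[str, str], float] = {}
        for r in self.records:
            out[(r.breed, r.bank)] = out.get((r.breed, r.bank), 0.0) + r.A
        return out

    def availability(self) -> dict[tuple[str, str], int]:
        """e[breed, region]; regions are identified with bank ids."""
        out: dict[tuple[str, str], int] = {}
        for r in self.records:
            out[(r.breed, r.bank)] = max(out.get((r.breed, r.bank), 0), r.e)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.breed, r.species, r.bank, r.A, r.e) for r in self.records],
            columns=["breed", "species", "bank", "A_doses", "e_available"],
        )


@dataclass(frozen=True)
class Instance:
    """A complete, validated problem instance."""

    banks: tuple[Bank, ...]
    costs: CollectionCostTable
    distances: DistanceMatrix
    species: tuple[SpeciesParams, ...]
    inventory: BreedInventory
    T: float = 1.0            # storage horizon, years
    TB: float | None = None   # total budget, EUR; None = unbounded

    @property
    def bank_ids(self) -> list[str]:
        return [b.id for b in self.banks]

    def bank(self, bank_id: str) -> Bank:
        for b in self.banks:
            if b.id == bank_id:
                return b
        raise KeyError(f"unknown bank {bank_id!r}")

    def species_params(self, species: str) -> SpeciesParams:
        for s in self.species:
            if s.species == species:
                return s
        raise KeyError(f"unknown species {species!r}")

    def with_inventory(self, inventory: BreedInventory) -> "Instance":
        return replace(self, inventory=inventory)


# ---------------------------------------------------------------------------
# Validation

def validate_instance(instance: Instance) -> list[str]:
    """Check every invariant; return findings (empty list means valid).

    Each finding names the offending entity and the violated rule; no
    exception is raised so callers can report all problems at once.
    """
    findings: list[str] = []
    bank_ids = instance.bank_ids
    bank_set = set(bank_ids)
    if len(bank_set) != len(bank_ids):
        findings.append("banks: duplicate bank ids")
    species_set = {s.species for s in instance.species}

    for b in instance.banks:
        for attr, rule in [("F", "F >= 0"), ("mc", "mc >= 0"), ("cp", "cp >= 0"),
                           ("d", "d >= 0"), ("tc", "tc >= 0"),
                           ("current_doses", "current_doses >= 0")]:
            if getattr(b, attr) < 0:
                findings.append(f"bank {b.id}: violates {rule}")
        if b.k <= 0:
            findings.append(f"bank {b.id}: violates k > 0")

    for s in instance.species:
        if s.M <= 0:
            findings.append(f"species {s.species}: violates M > 0")
        if not (0 < s.mu_factor <= 1):
            findings.append(f"species {s.species}: violates 0 < mu_factor <= 1")
        if s.r <= 0:
            findings.append(f"species {s.species}: violates r > 0")

    for gb in bank_ids:
        for sp in species_set:
            for table, name in [(instance.costs.cf, "cf"), (instance.costs.cc, "cc")]:
                v = table.get((gb, sp))
                if v is None:
                    findings.append(f"collection_costs ({gb},{sp}): missing {name}")
                elif v < 0:
                    findings.append(f"collection_costs ({gb},{sp}): {name} < 0")

    D = instance.distances.D
    for i in bank_ids:
        if D.get((i, i), 0.0) != 0.0:
            findings.append(f"distances {i}: nonzero diagonal")
        for j in bank_ids:
            dij = D.get((i, j))
            if dij is None:
                findings.append(f"distances ({i},{j}): missing entry")
                continue
            if dij < 0:
                findings.append(f"distances ({i},{j}): negative distance")
            dji = D.get((j, i))
            if dji is not None and i < j and dij != dji:
                findings.append(f"distances ({i},{j}): asymmetric ({dij} vs {dji})")

    has_available: dict[str, bool] = {}
    for r in instance.inventory.records:
        if r.bank not in bank_set:
            findings.append(f"inventory ({r.breed},{r.bank}): unknown bank")
        if r.species not in species_set:
            findings.append(f"inventory ({r.breed},{r.bank}): unknown species {r.species}")
        if r.A < 0:
            findings.append(f"inventory ({r.breed},{r.bank}): A < 0")
        if r.e not in (0, 1):
            findings.append(f"inventory ({r.breed},{r.bank}): e not in {{0,1}}")
        if r.A > 0 and r.e == 0:
            findings.append(
                f"inventory ({r.breed},{r.bank}): stored doses imply availability (A>0 requires e=1)")
        has_available[r.breed] = has_available.get(r.breed, False) or r.e == 1
    for breed, ok in has_available.items():
        if not ok:
            findings.append(f"inventory {breed}: no region with e=1 (breed uncollectable)")
    sp_of: dict[str, str] = {}
    for r in instance.inventory.records:
        prev = sp_of.setdefault(r.breed, r.species)
        if prev != r.species:
            findings.append(f"inventory {r.breed}: inconsistent species ({prev} vs {r.species})")

    if instance.T <= 0:
        findings.append("config: violates T > 0")
    if instance.TB is not None and instance.TB < 0:
        findings.append("config: violates TB >= 0")
    return findings


def _require_valid(instance: Instance) -> Instance:
    findings = validate_instance(instance)
    if findings:
        raise InstanceValidationError("; ".join(findings[:20]))
    return instance


# ---------------------------------------------------------------------------
# CSV I/O

def _read_csv(path: Path, name: str) -> pd.DataFrame:
    f = path / name
    if not f.exists():
        raise InstanceFormatError(f"missing file {name} in {path}")
    try:
        df = pd.read_csv(f)
    except Exception as exc:  # noqa: BLE001 - report as a format problem
        raise InstanceFormatError(f"cannot parse {name}: {exc}") from exc
    for col in REQUIRED_FILES[name]:
        if col not in df.columns:
            raise InstanceFormatError(f"{name}: missing column {col!r}")
    return df


def _tables_from_frames(banks_df: pd.DataFrame, costs_df: pd.DataFrame,
                        dist_df: pd.DataFrame, species_df: pd.DataFrame):
    banks = tuple(
        Bank(id=str(r.id), location=str(r.location), F=float(r.F_eur),
             mc=float(r.mc_eur_per_dose), cp=float(r.cp_doses),
             current_doses=float(r.current_doses), d=float(r.d_km),
             tc=float(r.tc_eur_per_km), k=float(r.k_doses_per_trip))
        for r in banks_df.itertuples())
    cf = {(str(r.bank), str(r.species)): float(r.cf_eur_per_animal)
          for r in costs_df.itertuples()}
    cc = {(str(r.bank), str(r.species)): float(r.cc_eur_per_animal)
          for r in costs_df.itertuples()}
    costs = CollectionCostTable(cf=cf, cc=cc)
    ids = [str(x) for x in dist_df["id"]]
    missing = [j for j in ids if j not in dist_df.columns]
    if missing:
        raise InstanceFormatError(f"distances.csv: missing columns {missing}")
    D: dict[tuple[str, str], float] = {}
    for _, row in dist_df.iterrows():
        i = str(row["id"])
        for j in ids:
            D[(i, j)] = float(row[j])
    distances = DistanceMatrix(D=D)
    species = tuple(
        SpeciesParams(species=str(r.species), M=float(r.M_doses),
                      mu_factor=float(r.mu_factor), r=float(r.r_animals))
        for r in species_df.itertuples())
    return banks, costs, distances, species


def inventory_from_frame(df: pd.DataFrame) -> BreedInventory:
    records = tuple(
        InventoryRecord(breed=str(r.breed), species=str(r.species), bank=str(r.bank),
                        A=float(r.A_doses), e=int(r.e_available))
        for r in df.itertuples())
    return BreedInventory(records=records)


def load_instance(path: str | Path) -> Instance:
    """Load and validate an instance from a directory of CSV files.

    Expects banks.csv, collection_costs.csv, distances.csv, species.csv and
    inventory.csv (headers documented in the README), plus an optional
    config.csv with ``T`` and ``TB`` keys (empty TB means unbounded).
    """
    path = Path(path)
    banks_df = _read_csv(path, "banks.csv")
    costs_df = _read_csv(path, "collection_costs.csv")
    dist_df = _read_csv(path, "distances.csv")
    species_df = _read_csv(path, "species.csv")
    inv_df = _read_csv(path, "inventory.csv")
    banks, costs, distances, species = _tables_from_frames(
        banks_df, costs_df, dist_df, species_df)
    inventory = inventory_from_frame(inv_df)

    T, TB = 1.0, None
    cfg = path / "config.csv"
    if cfg.exists():
        with open(cfg, newline="") as fh:
            for row in csv.DictReader(fh):
                key, value = row.get("key"), row.get("value")
                if key == "T":
                    T = float(value)
                elif key == "TB":
                    TB = float(value) if value not in (None, "", "inf") else None
    return _require_valid(Instance(banks=banks, costs=costs, distances=distances,
                                   species=species, inventory=inventory, T=T, TB=TB))


def write_instance(instance: Instance, path: str | Path) -> None:
    """Write the instance as CSV files; ``load_instance`` round-trips it."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(b.id, b.location, b.F, b.mc, b.cp, b.current_doses, b.d, b.tc, b.k)
         for b in instance.banks],
        columns=REQUIRED_FILES["banks.csv"],
    ).to_csv(path / "banks.csv", index=False)
    rows = []
    for b in instance.banks:
        for s in instance.species:
            rows.append((b.id, s.species, instance.costs.cf[(b.id, s.species)],
                         instance.costs.cc[(b.id, s.species)]))
    pd.DataFrame(rows, columns=REQUIRED_FILES["collection_costs.csv"]).to_csv(
        path / "collection_costs.csv", index=False)
    ids = instance.bank_ids
    dist = pd.DataFrame(
        [[i] + [instance.distances.D[(i, j)] for j in ids] for i in ids],
        columns=["id"] + ids)
    dist.to_csv(path / "distances.csv", index=False)
    pd.DataFrame(
        [(s.species, s.M, s.mu_factor, s.r) for s in instance.species],
        columns=REQUIRED_FILES["species.csv"]).to_csv(path / "species.csv", index=False)
    instance.inventory.to_frame().to_csv(path / "inventory.csv", index=False)
    with open(path / "config.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["key", "value"])
        w.writerow(["T", repr(instance.T)])
        w.writerow(["TB", "" if instance.TB is None else repr(instance.TB)])


# ---------------------------------------------------------------------------
# Packaged network tables (11 European banks, 6 species)

def packaged_tables():
    """The packaged 11-bank network: banks, collection costs, distances and
    species parameters (EUR, km, doses). Returned as domain objects."""
    def read(name: str) -> pd.DataFrame:
        data = resources.files("genebankopt.data").joinpath(name).read_text()
        return pd.read_csv(io.StringIO(data))

    return _tables_from_frames(read("banks.csv"), read("collection_costs.csv"),
                               read("distances.csv"), read("species.csv"))


def fixture_instance(inventory: BreedInventory, T: float = 1.0,
                     TB: float | None = None) -> Instance:
    """Build a validated instance from the packaged 11-bank tables and the
    given breed inventory."""
    banks, costs, distances, species = packaged_tables()
    return _require_valid(Instance(banks=banks, costs=costs, distances=distances,
                                   species=species, inventory=inventory, T=T, TB=TB))
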