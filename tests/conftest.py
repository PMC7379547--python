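import numpy as np
import pytest

from genebankopt.instance import (
    Bank, BreedInventory, CollectionCostTable, DistanceMatrix, Instance,
    InventoryRecord, SpeciesParams, fixture_instance,
)
from genebankopt.synth import default_generator_config, generate_inventory


@pytest.fixture(scope="session")
def default_inventory():
    return generate_inventory(default_generator_config(seed=42))


@pytest.fixture(scope="session")
def network_instance(default_inventory):
    """The packaged 11-bank network with the seed-42 synthetic inventory."""
    return fixture_instance(default_inventory)


@pytest.fixture(scope="session")
def small_instance():
    """A 40-breed instance on the packaged network (fast MIP solves)."""
    from dataclasses import replace
    cfg = replace(default_generator_config(seed=7), n_breeds=40)
    return fixture_instance(generate_inventory(cfg))


def make_tiny_instance(seed: int, n_banks: int = 3, n_breeds: int = 4) -> Instance:
    """Random small instance for exhaustive-oracle comparisons."""
    rng = np.random.default_rng(seed)
    banks = tuple(
        Bank(id=f"G{i + 1}", location="synthetic", F=float(rng.integers(1000, 5000)),
             mc=float(rng.uniform(0.05, 2.0)), cp=float(rng.integers(5000, 20000)),
             current_doses=0.0, d=float(rng.integers(50, 500)), tc=2.5, k=400.0)
        for i in range(n_banks))
    ids = [b.id for b in banks]
    species = (SpeciesParams(species="cattle", M=585.0),
               SpeciesParams(species="sheep", M=198.0))
    cf = {(b, s.species): float(rng.integers(10, 500)) for b in ids for s in species}
    cc = {(b, s.species): float(rng.integers(10, 500)) for b in ids for s in species}
    D = {}
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i == j:
                D[(a, b)] = 0.0
            elif (b, a) in D:
                D[(a, b)] = D[(b, a)]
            else:
                D[(a, b)] = float(rng.integers(20, 2000))
    records = []
    for k in range(n_breeds):
        sp = ("cattle", "sheep")[int(rng.integers(0, 2))]
        home = ids[int(rng.integers(0, n_banks))]
        records.append(InventoryRecord(breed=f"b{k}", species=sp, bank=home,
                                       A=float(rng.integers(50, 900)), e=1))
        if rng.random() < 0.3:
            other = ids[int(rng.integers(0, n_banks))]
            if other != home:
                records.append(InventoryRecord(breed=f"b{k}", species=sp, bank=other,
                                               A=float(rng.integers(10, 300)), e=1))
    inventory = BreedInventory(records=tuple(
        sorted(records, key=lambda r: (r.breed, r.bank))))
    return Instance(banks=banks, costs=CollectionCostTable(cf=cf, cc=cc),
                    distances=DistanceMatrix(D=D), species=species,
                    inventory=inventory)
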