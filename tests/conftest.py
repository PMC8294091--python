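import numpy as np
import pytest

import forestblup as fb


@pytest.fixture(scope="session")
def small_sim():
    """Small but realistic partial-diallel simulation shared across tests."""
    cfg = fb.SimulationConfig(
        n_parents=12, n_families=20, n_progeny=160, n_loci=600, seed=42,
        variance_targets={"a": 300.0, "d": 0.0, "aa": 0.0, "ad": 0.0,
                          "dd": 0.0, "e": 1360.0},
    )
    return fb.simulate(cfg)


@pytest.fixture(scope="session")
def small_kernels(small_sim):
    ids = small_sim.traits.individual_ids
    gm = small_sim.genotypes.subset(ids).filter_maf(0.01)
    return fb.build_kernels(
        ["G_A", "G_D", "G_AA", "G_AD", "G_DD"], genotypes=gm
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_pedigree(rng, n_founders=10, n_descendants=50, generations=4):
    """Multi-generation random pedigree (mating within previous layers)."""
    records = [(f"P{i}", None, None) for i in range(n_founders)]
    layers = [[f"P{i}" for i in range(n_founders)]]
    per_layer = max(1, n_descendants // generations)
    count = 0
    for g in range(generations):
        pool = [i for layer in layers for i in layer]
        layer = []
        for _ in range(per_layer):
            if count >= n_descendants:
                break
            a, b = rng.choice(len(pool), size=2, replace=False)
            count += 1
            name = f"I{count}"
            records.append((name, pool[a], pool[b]))
            layer.append(name)
        layers.append(layer)
    return fb.Pedigree.from_records(records)
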