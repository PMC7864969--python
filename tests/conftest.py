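import numpy as np
import pytest

from hzadapt import GenotypeMatrix, PopulationMap, filter_biallelic
from hzadapt.simulate import SimParams, simulate_hybrid_zone
from hzadapt.workflows import hybrid_freq_table


SMALL = dict(
    n_hyb_pops=12,
    trees_per_pop=(6, 6),
    n_parental_pops=3,
    parental_trees_per_pop=6,
    n_loci=1200,
    n_adaptive_introgressed=10,
    n_adaptive_background=10,
    seed=11,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small planted hybrid zone shared by module tests."""
    params = SimParams(**SMALL)
    G, pmap, env, truth = simulate_hybrid_zone(params)
    return {"params": params, "G": G, "pmap": pmap, "env": env, "truth": truth}


@pytest.fixture(scope="session")
def small_filtered(small_sim):
    G_hyb = filter_biallelic(small_sim["G"], small_sim["pmap"], {"HYB"})
    F_hyb = hybrid_freq_table(G_hyb, small_sim["pmap"])
    return {**small_sim, "G_hyb": G_hyb, "F_hyb": F_hyb}


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def two_pop_map(n_per_pop: int = 4) -> tuple[list[str], PopulationMap]:
    inds = [f"a{i}" for i in range(n_per_pop)] + [f"b{i}" for i in range(n_per_pop)]
    pmap = PopulationMap(
        {i: ("A" if i.startswith("a") else "B") for i in inds},
        {"A": "HYB", "B": "HYB"},
        {"A": (35.0, -108.0, 2400.0), "B": (36.0, -108.5, 2500.0)},
    )
    return inds, pmap


def geno(values, inds=None, loci=None) -> GenotypeMatrix:
    values = np.asarray(values, dtype=np.int16)
    inds = inds or [f"i{k}" for k in range(values.shape[0])]
    loci = loci or [f"l{k}:1" for k in range(values.shape[1])]
    return GenotypeMatrix(values, inds, loci)
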