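import numpy as np
import pandas as pd
import pytest

from lethascan import SimConfig, simulate_population
from lethascan.pedigree import Pedigree


@pytest.fixture(scope="session")
def sim_pop():
    """Medium gene-drop population with a planted lethal, shared by tests.

    ~2,700 genotyped animals over 3 generations with 40 sires per
    generation; lethal founder haplotype frequency 8% and a PNM liability
    penalty for calves of two carrier parents.
    """
    cfg = SimConfig(
        n_founders=700,
        n_generations=3,
        n_sires_per_gen=40,
        lethal_founder_frequency=0.08,
        lethal_pnm_penalty=1.0,
        n_contemporary_groups=12,
        seed=5,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def random_pedigree():
    """200-animal random pedigree with founders and some unknown parents."""
    rng = np.random.default_rng(42)
    n = 200
    ids = [f"a{i}" for i in range(n)]
    sires, dams = [], []
    for i in range(n):
        if i < 30:
            sires.append("0")
            dams.append("0")
        else:
            sires.append(ids[rng.integers(0, i)] if rng.random() < 0.85 else "0")
            dams.append(ids[rng.integers(0, i)] if rng.random() < 0.9 else "0")
    return Pedigree(ids, sires, dams)


@pytest.fixture()
def trio_pedigree():
    return Pedigree(["s", "d", "o"], ["0", "0", "s"], ["0", "0", "d"])
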