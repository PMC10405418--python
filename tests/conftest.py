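"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import leakscan as lk
from leakscan.ladder import LadderConfig, SimulationConfig


@pytest.fixture(scope="session")
def tiny_pop():
    """~150 animals, 2 chromosomes x 150 SNPs: fast end-to-end material."""
    cfg = LadderConfig(
        simulation=SimulationConfig(
            n_founders=50, n_generations=2, litter_size=2,
            n_chromosomes=2, snps_per_chromosome=150,
            chromosome_length_bp=30_000_000, n_qtl=6, n_md=60,
            untag_window_bp=2_000_000, n_contemporary_groups=4),
        master_seed=7,
    )
    return lk.simulate_population(cfg), cfg


@pytest.fixture(scope="session")
def medium_pop():
    """~1,000 animals, denser map: used for recovery-type checks."""
    cfg = LadderConfig(
        simulation=SimulationConfig(
            n_founders=250, n_generations=3, litter_size=2,
            n_chromosomes=3, snps_per_chromosome=400,
            chromosome_length_bp=40_000_000, n_qtl=15, n_md=120,
            n_contemporary_groups=9),
        master_seed=11,
    )
    return lk.simulate_population(cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_pedigree(n, seed=0, p_founder=0.2):
    """Arbitrary (non-generational) valid pedigree for kinship stress tests."""
    r = np.random.default_rng(seed)
    animal = np.arange(1, n + 1)
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    gen = np.zeros(n, dtype=np.int64)
    for i in range(1, n):
        if r.random() > p_founder:
            s, d = r.integers(1, i + 1, size=2)
            sire[i], dam[i] = s, d
            gen[i] = 1 + max(gen[s - 1], gen[d - 1])
    return lk.Pedigree(animal, sire, dam, gen, np.arange(1, n + 1))
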