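"""Shared fixtures: small simulated populations, reads, assemblies."""

from __future__ import annotations

import numpy as np
import pytest

from linearends import simulate


@pytest.fixture(scope="session")
def small_replicon():
    """20-kb single-strain replicon with a 2-kb TIR."""
    cfg = simulate.PopulationConfig(n_strains=1, chromosome_length=20_000,
                                    tir_length=2_000, seed=11)
    return simulate.simulate_population(cfg)[0]


@pytest.fixture(scope="session")
def small_reads(small_replicon):
    return simulate.simulate_reads(small_replicon, coverage=50,
                                   read_length=300, error_rate=1e-3, seed=12)


@pytest.fixture(scope="session")
def desk_replicon():
    """Desk-scale default: 200-kb replicon, 20-kb TIR."""
    cfg = simulate.PopulationConfig(n_strains=1, seed=1)
    return simulate.simulate_population(cfg)[0]


def random_dna_str(n: int, seed: int, gc: float = 0.5) -> str:
    rng = np.random.default_rng(seed)
    from linearends._seq import random_dna

    return random_dna(n, gc, rng)
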