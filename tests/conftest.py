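"""Shared fixtures: small seeded synthetic studies and random genomes."""

from __future__ import annotations

import numpy as np
import pytest

from rrhp.genome_io import GenomeSequence
from rrhp.synthetic_data import SimulationConfig, SimulatedStudy, simulate_study


@pytest.fixture(scope="session")
def small_study() -> SimulatedStudy:
    """Default-condition study at desk scale, shared read-only across tests."""
    return simulate_study(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def assoc_study() -> SimulatedStudy:
    """Larger study (500 genes) for association analyses."""
    cfg = SimulationConfig(
        seed=7, n_chroms=4, chrom_length=500_000, n_genes=500, planted_fraction=0.0
    )
    return simulate_study(cfg)


def random_genome(rng: np.random.Generator, name: str, length: int) -> GenomeSequence:
    """Unconstrained random sequence (CCGG occurrences arise by chance)."""
    return GenomeSequence(name, "".join(rng.choice(list("ACGT"), size=length)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
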