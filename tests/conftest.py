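"""Shared fixtures: small simulated datasets, hand-built registries."""

import numpy as np
import pytest

from ohnopipe.genome_model import (
    GeneLocus,
    GenomicInterval,
    HomeologBlockPair,
    TetrasomyRegistry,
)
from ohnopipe.synthetic_data import SimParams, simulate_counts, simulate_ohnolog_sequences


@pytest.fixture(scope="session")
def toy_registry() -> TetrasomyRegistry:
    """Two block pairs: one tetrasomic (chr1 <-> chr2), one disomic
    (chr3 <-> chr4)."""
    return TetrasomyRegistry(
        [
            HomeologBlockPair(
                GenomicInterval("chr1", 0, 1_000_000),
                GenomicInterval("chr2", 0, 1_000_000),
                tetrasomic=True,
                label="tet1",
            ),
            HomeologBlockPair(
                GenomicInterval("chr3", 0, 1_000_000),
                GenomicInterval("chr4", 0, 1_000_000),
                tetrasomic=False,
                label="dis1",
            ),
        ]
    )


def locus(gene_id: str, chrom: str, start: int, end: int, length: int | None = None) -> GeneLocus:
    return GeneLocus(gene_id, GenomicInterval(chrom, start, end), length)


@pytest.fixture(scope="session")
def small_genome():
    """Trout-like preset at 60 pairs (17 tetrasomic)."""
    return simulate_ohnolog_sequences(SimParams(n_pairs=60, seed=42))


@pytest.fixture(scope="session")
def small_expression(small_genome):
    params = SimParams(n_pairs=60, seed=42)
    return simulate_counts(params, small_genome.truth_pairs)


@pytest.fixture(scope="session")
def recoverable_genome():
    """Low-divergence genome where protein identity clears the 85% filter,
    so pair calling should recover essentially every true pair."""
    return simulate_ohnolog_sequences(
        SimParams(n_pairs=60, seed=7, divergence=0.02)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240601)
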