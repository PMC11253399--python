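"""Shared fixtures: fixture genomes, signature matrices, a small cohort."""

from __future__ import annotations

import numpy as np
import pytest

from ithkit.io_formats import ReferenceGenome
from ithkit.synthetic_data import (
    ContextIndex,
    SimConfig,
    make_fixture_genome,
    simulate_cohort,
    synthetic_signature_matrix,
)


@pytest.fixture(scope="session")
def genome(tmp_path_factory) -> ReferenceGenome:
    """A 60 kb seeded random genome shared across tests."""
    path = tmp_path_factory.mktemp("genome") / "fixture.fa"
    make_fixture_genome(60_000, seed=42, path=path)
    return ReferenceGenome(path)


@pytest.fixture(scope="session")
def context_index(genome) -> ContextIndex:
    return ContextIndex(genome)


@pytest.fixture(scope="session")
def signature_matrix():
    return synthetic_signature_matrix()


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A compact multi-timepoint cohort for pipeline-level tests."""
    config = SimConfig(
        n_tumours=4,
        include_post=True,
        clones_per_tumour=(2, 4),
        mutations_per_clone=(60, 150),
        genome_length=150_000,
        seed=7,
    )
    return simulate_cohort(config, tmp_path_factory.mktemp("cohort"))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
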