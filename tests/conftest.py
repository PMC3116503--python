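"""Shared fixtures: one default mock genome, reused read-only across tests."""

import pytest

from genomeskim.simulate import (
    GenomeSpec,
    ReadSimParams,
    build_mock_genome,
    simulate_reads,
)


@pytest.fixture(scope="session")
def mock_genome():
    """Default-condition mock genome with ground truth."""
    records, truth = build_mock_genome(GenomeSpec(seed=11))
    return records, truth


@pytest.fixture(scope="session")
def genome_by_id(mock_genome):
    records, _ = mock_genome
    return {r.id: r for r in records}


@pytest.fixture(scope="session")
def skim_pool(mock_genome):
    """A ~0.5x read pool over the default genome, with provenance."""
    records, truth = mock_genome
    reads, prov = simulate_reads(
        records, truth, ReadSimParams(mean_coverage=0.5, seed=12)
    )
    return reads, prov
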