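import pytest

from tfscreen import SimConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic dataset shared across tests."""
    return simulate(SimConfig(seed=3))


@pytest.fixture()
def tiny_annotation():
    from tfscreen.genome import GeneRecord, GenomeAnnotation

    return GenomeAnnotation(
        [
            GeneRecord("gA", "chr1", 100_000, 110_000, "+", "transcription_regulator"),
            GeneRecord("gB", "chr1", 130_000, 140_000, "-"),
            GeneRecord("gC", "chr1", 400_000, 410_000, "+"),
            GeneRecord("gD", "chr2", 50_000, 60_000, "-"),
        ]
    )
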