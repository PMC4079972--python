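import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_genome():
    """Tiny two-chromosome genome with known structure.

    chrA carries a plus-strand two-intron gene, chrB a minus-strand
    single-intron gene whose intron sequence is hand reverse-complemented
    in the tests.
    """
    return {
        "chrA": (
            "ACGTACGTAC"  # 1-10   exon 1
            "GTATGTTTACTAACTTTTAG"  # 11-30  intron 1 (BP A at offset 13)
            "CCCCCGGGGG"  # 31-40  exon 2
            "GTAAGCCTAG"  # 41-50  intron 2
            "TTTTTAAAAA"  # 51-60  exon 3
        ),
        "chrB": "TTTTTTTTTTGGGGGCTTACGGCATCCCCC",
    }


@pytest.fixture(scope="session")
def toy_transcripts():
    from lariatscan.annotation_io import TranscriptModel

    plus = TranscriptModel(
        "txA.1", "geneA", "chrA", "+", ((1, 10), (31, 40), (51, 60))
    )
    # Minus strand: exons in transcript order have descending genomic starts.
    minus = TranscriptModel("txB.1", "geneB", "chrB", "-", ((26, 30), (11, 15)))
    return [plus, minus]


@pytest.fixture(scope="session")
def toy_introns(toy_transcripts, toy_genome):
    from lariatscan.annotation_io import derive_introns

    return derive_introns(toy_transcripts, toy_genome)


@pytest.fixture(scope="session")
def small_simulation():
    """Small but complete synthetic dataset shared across test modules."""
    from lariatscan.simulate import SimulationConfig, generate_genome, generate_reads

    config = SimulationConfig(n_genes=12, depth=1500, lariat_reads_per_intron=8)
    sim = generate_genome(config, seed=11)
    reads, truth = generate_reads(sim, config, seed=12)
    return config, sim, reads, truth
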