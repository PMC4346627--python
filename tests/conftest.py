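import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mirtail.core import Genome, MatureMirna
from mirtail.simdata import SimConfig, build_toy_reference, simulate_reads


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_mirnas=6, genome_length=4000, mean_abundance=300, seed=11)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return build_toy_reference(small_config)


@pytest.fixture(scope="session")
def small_simulation(small_config, small_reference):
    genome, mirnas = small_reference
    reads, truth = simulate_reads(genome, mirnas, small_config)
    return genome, mirnas, reads, truth


@pytest.fixture()
def toy_genome() -> Genome:
    # handmade two-contig genome for deterministic corner cases
    return Genome(
        {
            "chrA": "ACGTACGTTTGACCTAGGCTAACGGATCCTAGGACTTACGGTAACGTACGT",
            "chrB": "TTTTGGGGCCCCAAAATTTTGGGGCCCCAAAA",
        }
    )


@pytest.fixture()
def plus_mirna(toy_genome) -> MatureMirna:
    seq = toy_genome.fetch("chrA", 8, 30, "+")
    return MatureMirna("mir-plus", "chrA", "+", 8, seq)


@pytest.fixture()
def minus_mirna(toy_genome) -> MatureMirna:
    # span [20, 42) on the minus strand: 5' start is coordinate 41
    seq = toy_genome.fetch("chrA", 20, 42, "-")
    return MatureMirna("mir-minus", "chrA", "-", 41, seq)
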