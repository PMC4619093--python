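import pytest

from gmrsd_context import (
    FamilySimSpec,
    GenomeSimSpec,
    simulate_family,
    simulate_genomes,
)


@pytest.fixture(scope="session")
def family_sim():
    """A fully conserved synthetic family (40 doubles, 5 pairs, 10 orphans)."""
    return simulate_family(FamilySimSpec(seed=11))


@pytest.fixture(scope="session")
def planted_genomes():
    """A small planted-enrichment genome set (domain D005 at 5x odds)."""
    spec = GenomeSimSpec(
        n_genomes=30,
        orfs_per_contig=60,
        domain_vocab_size=20,
        enriched_domains={"D005": 5.0},
        seed=7,
    )
    return simulate_genomes(spec)
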