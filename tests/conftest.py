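"""Shared fixtures: a small fully ground-truthed synthetic world.

The small world (4+4 samples) keeps unit tests fast; acceptance tests
build the full-size study world themselves.
"""
import pytest

from phageome.synthetic_data import WorldConfig, generate_world


SMALL_CONFIG = WorldConfig(
    n_samples_per_group=4,
    n_scaffolds_per_sample=12,
    n_bacterial_genera=6,
    n_phage_genomes=10,
    prophage_rate=0.8,
    crispr_rate=0.25,
    reads_per_sample=800,
    vlp_reads_per_sample=2000,
    n_16s_copies_range=(8, 10),
    n_effect_potus=2,
    rng_seed=42,
)


@pytest.fixture(scope="session")
def small_world():
    """(config, refs, community, reads) for a compact two-group world."""
    refs, community, reads = generate_world(SMALL_CONFIG)
    return SMALL_CONFIG, refs, community, reads


@pytest.fixture(scope="session")
def scaffold_map(small_world):
    _, _, community, _ = small_world
    return community.scaffold_map()
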