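import pytest

from virhost.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_l1_dataset():
    """Strongly separable 3-host-label order: 3 families x 2 genera x 5 genomes."""
    cfg = SimConfig(
        families_per_order=3,
        genera_per_family=2,
        genomes_per_genus=5,
        host_labels=("Chordata", "Invertebrate", "Viridiplantae"),
        bias_strength=1.0,
        mutation_rate=0.02,
        length_range=(1200, 1800),
        seed=11,
    )
    records, sequences = simulate_dataset(cfg)
    return records, sequences


@pytest.fixture(scope="session")
def layer2_dataset():
    """Two-layer order: layer-2 hosts under Chordata plus a plant branch."""
    cfg = SimConfig(
        families_per_order=3,
        genera_per_family=2,
        genomes_per_genus=5,
        host_labels=("Primates", "Fish", "Viridiplantae"),
        bias_strength=1.0,
        mutation_rate=0.02,
        length_range=(1200, 1800),
        seed=23,
    )
    records, sequences = simulate_dataset(cfg)
    return records, sequences
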