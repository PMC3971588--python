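import pytest

from paleodup.synthetic import (
    SimulationDesign,
    simulate_counts,
    simulate_synteny_fixture,
)


@pytest.fixture(scope="session")
def default_sim():
    """A moderate default-mix simulation shared across read-only tests."""
    design = SimulationDesign(n_pairs=200, seed=42)
    counts, samples, truth = simulate_counts(design)
    return design, counts, samples, truth


@pytest.fixture(scope="session")
def null_sim():
    """Complete-null simulation (no planted effects)."""
    design = SimulationDesign(n_pairs=400, scenario_mix={"null": 1.0}, seed=7)
    counts, samples, truth = simulate_counts(design)
    return design, counts, samples, truth


@pytest.fixture(scope="session")
def synteny_fixture():
    return simulate_synteny_fixture(
        n_blocks=5, genes_per_block=10, fraction_strict=0.6, seed=3
    )
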