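"""Shared fixtures: synthetic datasets reused across test modules."""

import pytest

from glyconodule import default_glycan_panel, make_record, simulate_dataset


@pytest.fixture(scope="session")
def panel_database():
    """GlycanRecords for the 12-glycan study panel."""
    return [make_record(g.composition) for g in default_glycan_panel()]


@pytest.fixture(scope="session")
def planted_dataset():
    """Full-size study dataset: 2 genotypes x 3 sections, 120x120 px, seed 17."""
    dataset, truth = simulate_dataset(seed=17)
    return dataset, truth


@pytest.fixture(scope="session")
def small_dataset():
    """A fast 50x50, one-section-per-genotype dataset for unit tests."""
    dataset, truth = simulate_dataset(
        n_sections_per_genotype=1, width=50, height=50, seed=3
    )
    return dataset, truth


@pytest.fixture(scope="session")
def null_dataset():
    """Decoy-null dataset: noise and starch interference only, nothing planted."""
    dataset, _ = simulate_dataset(glycans=[], seed=29)
    return dataset
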