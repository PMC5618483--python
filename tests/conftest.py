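"""Shared fixtures: the default synthetic study inputs, built once."""

import pytest

from snrkfam.promoter import load_catalog
from snrkfam.simulate import (GeneratorConfig, family_group_map, gen_genome,
                              gen_promoters, load_placements)


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def placements():
    return load_placements()


@pytest.fixture(scope="session")
def group_map():
    return family_group_map()


@pytest.fixture(scope="session")
def default_genome():
    """The default synthetic genome (22-member family, 6/4/8/4, 5 decoys)."""
    return gen_genome(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def reconstructed_promoters(catalog, placements, group_map):
    """All 22 promoters rebuilt from the published placements."""
    windows, truth = gen_promoters(catalog, placements, genes=list(group_map),
                                   seed=7, on_conflict="skip")
    return windows, truth
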