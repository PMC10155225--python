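import pytest
from hypothesis import HealthCheck, settings

import euryalida as eu

settings.register_profile(
    "default", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_tree():
    return eu.load_tree()


@pytest.fixture(scope="session")
def fixture_chars():
    return eu.load_characters()


@pytest.fixture(scope="session")
def multiarm_chars():
    return eu.load_multiarm()


@pytest.fixture(scope="session")
def branched_states(fixture_chars):
    return eu.states_from_matrix(fixture_chars, "branched")


@pytest.fixture(scope="session")
def pedicellariae_states(fixture_chars):
    return eu.states_from_matrix(fixture_chars, "pedicellariae")


@pytest.fixture(scope="session")
def family_scopes(fixture_tree, fixture_chars):
    scopes = {}
    for family in ("Euryalidae", "Gorgonocephalidae"):
        placed = [r.taxon_name for r in fixture_chars.family(family, placed=True)]
        scopes[family] = fixture_tree.mrca(placed)
    return scopes
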