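import pytest

from oculodx import (
    EntityCatalog,
    EntityKind,
    KnowledgeBase,
    SymptomCatalog,
    load_example_disease_kb,
    load_example_zone_kb,
    load_example_zone_map,
)


@pytest.fixture(scope="session")
def disease_kb():
    return load_example_disease_kb()


@pytest.fixture(scope="session")
def zone_kb():
    return load_example_zone_kb()


@pytest.fixture(scope="session")
def zone_map():
    return load_example_zone_map()


@pytest.fixture
def toy_disease_kb():
    """Small hand-sized disease KB for exact-value tests."""
    symptoms = ("vertical saccade palsy", "paresis", "ataxia", "resting tremor")
    entities = ("NPC", "GD3", "TS", "MS")
    weights = {
        ("NPC", "vertical saccade palsy"): 2,
        ("NPC", "paresis"): -2,
        ("GD3", "paresis"): -2,
        ("TS", "paresis"): 1,
        ("MS", "ataxia"): 1,
        ("MS", "paresis"): 1,
    }
    return KnowledgeBase(
        symptom_catalog=SymptomCatalog(symptoms=symptoms),
        entity_catalog=EntityCatalog(entities=entities, entity_kind=EntityKind.DISEASE),
        weights=weights,
    )
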