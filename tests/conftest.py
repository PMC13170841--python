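import pytest

from cmkg.kg_core import EntityRecord, KnowledgeGraphStore, TripleRecord
from cmkg.paths import IngredientFrequencyIndex, ScoringConfig
from cmkg.synth import SynthesisParams, generate_cmkg


def make_store(entities, triples, strict=True):
    """entities: (id, type) pairs; triples: (h, r, t) with source 'fx'."""
    ents = [EntityRecord(e, f"name {e}", t, "fx") for e, t in entities]
    trips = [TripleRecord(h, r, t, "fx") for h, r, t in triples]
    return KnowledgeGraphStore(ents, trips, strict=strict)


@pytest.fixture(scope="session")
def synth():
    """One shared synthetic CMKG with its ground-truth manifest."""
    return generate_cmkg(SynthesisParams(seed=11))


@pytest.fixture(scope="session")
def synth_store(synth):
    return synth[0]


@pytest.fixture(scope="session")
def synth_manifest(synth):
    return synth[1]


@pytest.fixture(scope="session")
def synth_index(synth_store):
    return IngredientFrequencyIndex.from_store(synth_store)


@pytest.fixture
def config():
    return ScoringConfig()


@pytest.fixture
def chain4_store():
    """The hand-checkable 4-hop herb -> gene -> gene -> gene -> disease chain."""
    return make_store(
        [("H1", "Herb"), ("G1", "Gene"), ("G2", "Gene"), ("G3", "Gene"), ("D1", "DiseaseMM")],
        [
            ("H1", "act_on", "G1"),
            ("G1", "synergizewith", "G2"),
            ("G2", "synergizewith", "G3"),
            ("G3", "act in pathway", "D1"),
        ],
    )
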