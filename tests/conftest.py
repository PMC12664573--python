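import numpy as np
import pytest

from phoskg.dataset import ClassificationSample
from phoskg.kg import KnowledgeGraph, Triple
from phoskg.synthetic import preset, simulate_world


@pytest.fixture
def tiny_kg() -> KnowledgeGraph:
    return KnowledgeGraph(
        [
            Triple("P61981", "participating_pathway", "R-HSA-111447"),
            Triple("P08603", "part_of_complex", "R-HSA-1006173"),
            Triple("R-HSA-73943", "pathway_event_of", "R-HSA-73942"),
            Triple("Q05513", "belongs_to_family", "PKC"),
            Triple("Q9BWU1", "k_specific_motif", "LDLFSPSVT"),
            Triple("Q9Y4B6", "has_motif", "YDIQTGNKL"),
        ]
    )


@pytest.fixture
def tiny_samples() -> list[ClassificationSample]:
    return [
        ClassificationSample("K1", "S1", "AAAASAAAA", 1),
        ClassificationSample("K1", "S2", "CCCCTCCCC", 1),
        ClassificationSample("K2", "S1", "AAAASAAAA", 0),
        ClassificationSample("K2", "S2", "CCCCTCCCC", 0),
    ]


@pytest.fixture(scope="session")
def small_world():
    """One shared small world for the expensive structural tests."""
    return simulate_world(preset("small", seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
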