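import numpy as np
import pytest

from probkg.graph import (
    CooccurrenceMatrix,
    EntityCatalog,
    ProbAdjacency,
    ProbKG,
    RelationSpec,
)
from probkg.model import TrainConfig
from probkg.synthetic import SyntheticSpec, generate_prob_kg


@pytest.fixture
def catalog():
    return EntityCatalog(
        {
            "drug": ["d1", "d2", "d3"],
            "protein": ["p1", "p2", "p3", "p4"],
            "disease": ["z1", "z2"],
            "side_effect": ["s1", "s2"],
        },
        synonyms={
            "drug": {"d1": ["aspirin"], "d2": ["ibuprofen"], "d3": ["warfarin"]},
            "protein": {
                "p1": ["kinase alpha"],
                "p2": ["kinase beta"],
                "p3": ["phosphatase"],
                "p4": ["receptor gamma"],
            },
            "disease": {"z1": ["fever"], "z2": ["thrombosis"]},
            "side_effect": {"s1": ["nausea"], "s2": ["rash"]},
        },
    )


@pytest.fixture
def specs():
    return {
        "ppi": RelationSpec("ppi", "protein", "protein", symmetric=True),
        "dpi": RelationSpec("dpi", "drug", "protein", in_literature_set=True),
        "tda": RelationSpec("tda", "protein", "disease", in_literature_set=True),
        "dse": RelationSpec("dse", "drug", "side_effect"),
        "psim": RelationSpec(
            "psim", "protein", "protein", in_similarity_set=True, symmetric=True
        ),
    }


@pytest.fixture
def toy_kg(catalog, specs):
    """Hand-built 4-protein / 3-drug / 2-disease graph with counts."""
    rng = np.random.default_rng(7)
    spec_list = list(specs.values())
    adjacency = {}
    cooc = {}
    for s in spec_list:
        shape = (catalog.size(s.source_type), catalog.size(s.target_type))
        if s.in_similarity_set:
            sim = rng.uniform(0.1, 0.9, size=shape)
            sim = (sim + sim.T) / 2
            np.fill_diagonal(sim, 1.0)
            adjacency[s.name] = ProbAdjacency(s, sim, np.ones(shape, dtype=bool))
            continue
        observed = rng.random(shape) < 0.5
        if s.symmetric:
            observed |= observed.T
        probs = observed.astype(float)
        adjacency[s.name] = ProbAdjacency(s, probs, observed)
        if s.in_literature_set:
            cooc[s.name] = CooccurrenceMatrix(s, rng.poisson(2.0, size=shape))
    kg = ProbKG(
        catalog=catalog, specs=spec_list, adjacency=adjacency, alpha=0.0, beta=0.0
    )
    from probkg.graph import assign_edge_probabilities

    return assign_edge_probabilities(kg, cooc)


@pytest.fixture
def tiny_synthetic():
    """Small planted synthetic graph, fast to train on."""
    spec = SyntheticSpec(
        n_entities={"drug": 12, "protein": 14, "disease": 10, "side_effect": 8},
        rank=2,
        density=0.2,
        seed=11,
    )
    kg, truth, holdout = generate_prob_kg(spec)
    return kg, truth, holdout


@pytest.fixture
def tiny_config():
    return TrainConfig(d0=8, d1=6, k=6, epochs=30, learning_rate=1e-2, seed=5)
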