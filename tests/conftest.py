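import numpy as np
import pytest

import netmoa as nm


@pytest.fixture
def chain_net():
    """A -> B -> C, all activating, weight 1."""
    return nm.Interactome.from_edges(
        [nm.Edge("A", "B", 1, 1.0), nm.Edge("B", "C", 1, 1.0)]
    )


@pytest.fixture
def toy_two_drug():
    """Tiny network where drug A's target reaches the effector and drug B's does not.

        TA -> M -> E      TB -> X (dead end away from E)
    """
    net = nm.Interactome.from_edges(
        [
            nm.Edge("TA", "M", 1, 1.0),
            nm.Edge("M", "E", 1, 1.0),
            nm.Edge("TB", "X", 1, 1.0),
        ]
    )
    drugA = nm.DrugTargetProfile("drugA", {"TA": -1})
    drugB = nm.DrugTargetProfile("drugB", {"TB": -1})
    disease = nm.DiseaseCharacterization(
        motives={"m1": (nm.Effector("E", 1),)}
    )
    return net, drugA, drugB, disease


def random_interactome(rng: np.random.Generator, n: int = 8,
                       p_edge: float = 0.3, dag: bool = False) -> nm.Interactome:
    """Small random signed network for property tests."""
    nodes = [f"N{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(n):
            if i == j or (dag and j <= i):
                continue
            if rng.random() < p_edge:
                sign = -1 if rng.random() < 0.4 else 1
                edges.append(nm.Edge(nodes[i], nodes[j], sign, float(rng.uniform(0, 1))))
    return nm.Interactome(nodes=tuple(nodes), edges=tuple(edges))


@pytest.fixture(scope="session")
def mimic_bundle():
    return nm.paper_mimic(seed=1)


@pytest.fixture(scope="session")
def mimic_ensembles(mimic_bundle):
    b = mimic_bundle
    ensA = nm.fit_ensemble(b.net, [], M=100, seed=2, drug=b.broad)
    ensB = nm.fit_ensemble(b.net, [], M=100, seed=3, drug=b.narrow)
    return ensA, ensB
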