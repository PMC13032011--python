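import numpy as np
import pytest

from unitcause.cohort import default_myopia_scm, generate_cohort
from unitcause.graph import CausalGraph
from unitcause.nn import train_fnn

#: the published causal structure over the 16 features: six variables are
#: direct causes of both AL and CR, HEIGHT and REDM drive AL only, and AL
#: drives CR; six variables carry no edges at all.
PUBLISHED_EDGES = (
    [(s, "AL") for s in ("PWG", "GENDER", "NAR", "DAR", "K1", "K2")]
    + [(s, "CR") for s in ("PWG", "GENDER", "NAR", "DAR", "K1", "K2")]
    + [("HEIGHT", "AL"), ("REDM", "AL"), ("AL", "CR")]
)

ALL_FEATURES = (
    "CR", "AL", "NW", "DTO", "NAR", "DAR", "HEIGHT", "PULSE", "GENDER",
    "CB", "EGG", "REDM", "WHIM", "PWG", "K1", "K2",
)


@pytest.fixture(scope="session")
def paper_graph() -> CausalGraph:
    return CausalGraph(nodes=ALL_FEATURES, directed_edges=PUBLISHED_EDGES)


@pytest.fixture(scope="session")
def scm():
    return default_myopia_scm()


@pytest.fixture(scope="session")
def cohort(scm):
    return generate_cohort(scm, 3000, seed=42)


@pytest.fixture(scope="session")
def trained_model(cohort):
    return train_fnn(cohort, seed=0)


def random_dag(rng: np.random.Generator, n_nodes: int,
               p_edge: float = 0.4) -> CausalGraph:
    """Random DAG over letter-named nodes (edges respect a random order)."""
    names = [f"n{i}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    g = CausalGraph(names)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                g.add_directed(names[order[i]], names[order[j]])
    return g
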