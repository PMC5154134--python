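import networkx as nx
import numpy as np
import pytest

from genokit.fixtures import elim_chain_fixture, generate_fixture, toy_snp_ontology


@pytest.fixture(scope="session")
def small_bundle():
    return generate_fixture(11, "small")


@pytest.fixture(scope="session")
def tiny_bundle():
    return generate_fixture(7, "tiny")


@pytest.fixture(scope="session")
def toy_ontology():
    """Four-SNP trait ontology with a known similarity ordering."""
    return toy_snp_ontology()


@pytest.fixture(scope="session")
def elim_chain():
    """Three-level chain whose leaf fully explains the parent's overlap."""
    return elim_chain_fixture()


def random_dag_edges(rng: np.random.Generator, n_terms: int):
    """Random rooted DAG as (child, parent) pairs, occasionally diamond-shaped."""
    terms = [f"X{i}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        edges.append((terms[i], terms[int(rng.integers(0, i))]))
        if i > 2 and rng.random() < 0.3:
            other = terms[int(rng.integers(0, i))]
            if (terms[i], other) not in edges:
                edges.append((terms[i], other))
    return terms, edges


def ancestors_via_networkx(edges, term):
    """Independent ancestor computation (term included) for oracle checks."""
    g = nx.DiGraph(edges)
    if term not in g:
        return {term}
    return nx.descendants(g, term) | {term}  # edges point child -> parent
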