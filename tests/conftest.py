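import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from sbrgo.ontology import (NEGATIVE, POSITIVE, AnnotationTable, OntologyDAG,
                            propagate)


@pytest.fixture
def chain_dag():
    """root <- a <- b in one namespace."""
    return OntologyDAG(
        {"root": "BP", "a": "BP", "b": "BP"},
        {"root": set(), "a": {"root"}, "b": {"a"}},
    )


@pytest.fixture
def diamond_dag():
    """root <- {a, b} <- c."""
    return OntologyDAG(
        {"root": "BP", "a": "BP", "b": "BP", "c": "BP"},
        {"root": set(), "a": {"root"}, "b": {"root"}, "c": {"a", "b"}},
    )


@pytest.fixture
def two_ns_dag():
    return OntologyDAG(
        {"bp0": "BP", "bp1": "BP", "bp2": "BP",
         "cc0": "CC", "cc1": "CC"},
        {"bp0": set(), "bp1": {"bp0"}, "bp2": {"bp1"},
         "cc0": set(), "cc1": {"cc0"}},
    )


def random_dag(rng, n_terms: int, ns: str = "BP") -> OntologyDAG:
    """Random single-namespace DAG: each non-root picks 1-2 earlier parents."""
    names = [f"{ns}{i}" for i in range(n_terms)]
    namespace = {t: ns for t in names}
    edges = {names[0]: set()}
    for i in range(1, n_terms):
        k = 1 + int(rng.random() < 0.3 and i > 1)
        parents = rng.choice(i, size=min(k, i), replace=False)
        edges[names[i]] = {names[j] for j in parents}
    return OntologyDAG(namespace, edges)


def closed_table(dag: OntologyDAG, proteins, annotations) -> AnnotationTable:
    """Table from (protein, leaf-term) positives, propagated and closed."""
    t = AnnotationTable(list(proteins))
    for p, term in annotations:
        t.set(p, term, POSITIVE)
    return propagate(t, dag)
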