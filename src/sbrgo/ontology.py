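"""Gene Ontology style DAGs and annotation tables.

The three GO namespaces (biological_process, cellular_component,
molecular_function) are handled as disjoint rooted DAGs connected by ``is_a``
edges only.  Annotations obey the true-path rule: a protein annotated with a
term is annotated with every ancestor of that term, up to the namespace root.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

NAMESPACES = ("BP", "CC", "MF")

_OBO_NAMESPACE = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
    "BP": "BP",
    "CC": "CC",
    "MF": "MF",
}


class OntologyError(ValueError):
    """Raised for structurally invalid ontology input."""


@dataclass
class OntologyDAG:
    """Indexed is_a DAG over one or more GO namespaces.

    Parameters
    ----------
    namespace : mapping term-id -> one of {"BP", "CC", "MF"}
    isa_edges : mapping child term-id -> set of parent term-ids
    depth_mode : "shortest" or "longest"
        How term depth is measured from the namespace root.  Depth of a root
        is 0; a child is strictly deeper than its shallowest (or deepest)
        parent.  Default is shortest-path depth.
    """

    namespace: dict[str, str]
    isa_edges: dict[str, set[str]]
    depth_mode: str = "shortest"
    roots: dict[str, str] = field(init=False)
    depth: dict[str, int] = field(init=False)
    children: dict[str, set[str]] = field(init=False)

    def __post_init__(self) -> None:
        if self.depth_mode not in ("shortest", "longest"):
            raise OntologyError(f"unknown depth_mode {self.depth_mode!r}")
        for t in self.namespace:
            self.isa_edges.setdefault(t, set())
        self._validate()
        self._index()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        for child, parents in self.isa_edges.items():
            if child not in self.namespace:
                raise OntologyError(f"edge from unknown term {child!r}")
            for p in parents:
                if p not in self.namespace:
                    raise OntologyError(f"unknown parent term {p!r} of {child!r}")
                if self.namespace[p] != self.namespace[child]:
                    raise OntologyError(
                        f"cross-namespace is_a edge {child!r} -> {p!r}"
                    )
        g = nx.DiGraph()
        g.add_nodes_from(self.namespace)
        for child, parents in self.isa_edges.items():
            g.add_edges_from((child, p) for p in parents)
        if not nx.is_directed_acyclic_graph(g):
            raise OntologyError("is_a graph contains a cycle")
        self._graph = g

    def _index(self) -> None:
        self.children = {t: set() for t in self.namespace}
        for child, parents in self.isa_edges.items():
            for p in parents:
                self.children[p].add(child)
        self.roots = {}
        for t, ns in self.namespace.items():
            if not self.isa_edges[t]:
                if ns in self.roots:
                    raise OntologyError(
                        f"namespace {ns} has multiple roots "
                        f"({self.roots[ns]!r}, {t!r})"
                    )
                self.roots[ns] = t
        self.depth = {}
        agg = min if self.depth_mode == "shortest" else max
        for t in nx.topological_sort(self._graph.reverse(copy=False)):
            parents = self.isa_edges[t]
            if not parents:
                self.depth[t] = 0
            else:
                self.depth[t] = 1 + agg(self.depth[p] for p in parents)

    # -- queries --------------------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self.namespace)

    def parents(self, term: str) -> set[str]:
        return self.isa_edges[term]

    def ancestors(self, term: str) -> set[str]:
        """All strict ancestors of *term* (transitive is_a closure)."""
        out: set[str] = set()
        stack = list(self.isa_edges[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.isa_edges[t])
        return out

    def descendants(self, term: str) -> set[str]:
        out: set[str] = set()
        stack = list(self.children[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.children[t])
        return out

    def terms_in(self, ns: str) -> set[str]:
        return {t for t, n in self.namespace.items() if n == ns}

    def namespaces(self) -> list[str]:
        return [ns for ns in NAMESPACES if ns in self.roots]

    def subgraph(self, keep: Iterable[str]) -> "OntologyDAG":
        keep = set(keep)
        ns = {t: self.namespace[t] for t in keep}
        edges = {t: self.isa_edges[t] & keep for t in keep}
        return OntologyDAG(ns, edges, depth_mode=self.depth_mode)


def terms_at_depth(dag: OntologyDAG, ns: str, l: int) -> set[str]:
    """The set of terms of namespace *ns* at depth *l* (``Domain_l``)."""
    if l < 0:
        raise ValueError("depth must be non-negative")
    return {t for t in dag.terms_in(ns) if dag.depth[t] == l}


def load_ontology(obo_text: str, depth_mode: str = "shortest") -> OntologyDAG:
    """Parse an OBO 1.2-subset document into an :class:`OntologyDAG`.

    Obsolete terms are removed; only ``is_a`` edges are retained.  Edges
    pointing at obsolete or missing terms are dropped.
    """
    graph = obonet.read_obo(io.StringIO(obo_text))
    namespace: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        ns_raw = data.get("namespace")
        if ns_raw is None:
            raise OntologyError(f"term {node!r} has no namespace")
        try:
            namespace[node] = _OBO_NAMESPACE[ns_raw]
        except KeyError:
            raise OntologyError(f"unknown namespace {ns_raw!r} for {node!r}")
    # obonet edges run child -> parent with the relation as the key
    isa: dict[str, set[str]] = {t: set() for t in namespace}
    for child, parent, rel in graph.edges(keys=True):
        if rel != "is_a":
            continue
        if parent in namespace:
            isa[child].add(parent)
    return OntologyDAG(namespace, isa, depth_mode=depth_mode)


def write_obo(dag: OntologyDAG) -> str:
    """Serialize a DAG back to the OBO subset accepted by :func:`load_ontology`."""
    inv = {"BP": "biological_process", "CC": "cellular_component",
           "MF": "molecular_function"}
    chunks = ["format-version: 1.2\n"]
    for term in sorted(dag.terms):
        lines = [f"[Term]", f"id: {term}", f"name: {term}",
                 f"namespace: {inv[dag.namespace[term]]}"]
        lines += [f"is_a: {p} ! {p}" for p in sorted(dag.isa_edges[term])]
        chunks.append("\n".join(lines) + "\n")
    return "\n".join(chunks)


# ---------------------------------------------------------------------------
# Annotation tables


POSITIVE, NEGATIVE, UNKNOWN = 1, 0, -1


@dataclass
class AnnotationTable:
    """Protein x term truth table with values positive / negative / unknown.

    ``values`` maps ``(protein, term) -> {1, 0, -1}``; pairs absent from the
    mapping take ``default`` (negative by default, mirroring the
    missing-annotations-are-negative policy; pass ``default=UNKNOWN`` for
    transductive settings).
    """

    proteins: list[str]
    values: dict[tuple[str, str], int] = field(default_factory=dict)
    default: int = NEGATIVE

    def get(self, protein: str, term: str) -> int:
        return self.values.get((protein, term), self.default)

    def set(self, protein: str, term: str, value: int) -> None:
        self.values[(protein, term)] = value

    def positives_for_term(self, term: str) -> set[str]:
        return {p for (p, t), v in self.values.items()
                if t == term and v == POSITIVE}

    def positive_terms(self, protein: str) -> set[str]:
        return {t for (p, t), v in self.values.items()
                if p == protein and v == POSITIVE}

    def annotated_terms(self) -> set[str]:
        return {t for (_, t) in self.values}

    def copy(self) -> "AnnotationTable":
        return AnnotationTable(list(self.proteins), dict(self.values),
                               self.default)

    def is_closed(self, dag: OntologyDAG) -> bool:
        """True iff the table satisfies the propagation-closure invariant."""
        for (p, t), v in self.values.items():
            if v != POSITIVE or t not in dag.terms:
                continue
            if any(self.get(p, a) != POSITIVE for a in dag.ancestors(t)):
                return False
        return True


def propagate(table: AnnotationTable, dag: OntologyDAG) -> AnnotationTable:
    """Propagate positive annotations up to the namespace roots.

    Annotations to terms absent from *dag* are dropped with a warning
    (mismatching annotations).  Positives are only ever added.
    """
    out = AnnotationTable(list(table.proteins), default=table.default)
    for (p, t), v in table.values.items():
        if t not in dag.terms:
            warnings.warn(f"dropping annotation of {p!r} to unknown term {t!r}")
            continue
        out.values[(p, t)] = v
    for (p, t), v in list(out.values.items()):
        if v == POSITIVE:
            for anc in dag.ancestors(t):
                out.values[(p, anc)] = POSITIVE
    return out


def filter_terms(
    table: AnnotationTable,
    dag: OntologyDAG,
    max_depth: Mapping[str, int] | None = None,
    min_annotations: int = 1,
) -> tuple[AnnotationTable, OntologyDAG]:
    """Apply the depth and support filters used when assembling a dataset.

    Terms deeper than ``max_depth[namespace]`` are removed, then terms with
    fewer than ``min_annotations`` positive proteins are removed.  The input
    must be propagation-closed; the output is re-checked for closure (ancestors
    of any retained positive are necessarily retained, because propagation
    makes ancestor counts >= descendant counts and ancestor depths smaller).
    """
    if min_annotations < 1:
        raise ValueError("min_annotations must be >= 1")
    if not table.is_closed(dag):
        raise ValueError("annotation table is not propagation-closed")
    max_depth = dict(max_depth or {})
    keep = set()
    for t in dag.terms:
        if dag.depth[t] > max_depth.get(dag.namespace[t], float("inf")):
            continue
        if len(table.positives_for_term(t)) < min_annotations:
            continue
        keep.add(t)
    sub = dag.subgraph(keep)
    out = AnnotationTable(list(table.proteins), default=table.default)
    for (p, t), v in table.values.items():
        if t in keep:
            out.values[(p, t)] = v
    assert out.is_closed(sub), "filtering orphaned a positive annotation"
    return out, sub
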