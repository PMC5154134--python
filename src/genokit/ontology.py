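"""Ontology DAG handling: true-path-rule propagation, information content, MICA.

An ontology is modelled as a rooted directed acyclic graph of terms joined by
``is_a`` edges (child -> parent).  Flat term collections (pathway libraries and
other non-structured ontologies) are lifted into the same representation by
inserting an artificial root that links all terms, so that every downstream
operation — annotation propagation, information content, most-informative
common ancestors — works uniformly on structured and non-structured knowledge.

Information content (IC) of a term is ``-log10`` of the fraction of annotated
entities carrying the term after propagation; the root always has IC 0 and IC
never decreases walking from the root towards the leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from graphlib import TopologicalSorter
from typing import Iterable, Mapping

import math

import networkx as nx
import obonet

ARTIFICIAL_ROOT = "GK:ROOT"


class OntologyError(Exception):
    """Structural or lookup problem with an ontology or its annotations."""


@dataclass
class OntologyDAG:
    """Rooted DAG of ontology terms connected by is_a (child -> parent) edges."""

    terms: set[str]
    names: dict[str, str]
    parents: dict[str, set[str]]  # child -> parents
    root: str
    _children: dict[str, set[str]] = field(default_factory=dict, repr=False)
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._children = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                self._children[p].add(child)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        names: Mapping[str, str] | None = None,
        extra_terms: Iterable[str] = (),
    ) -> "OntologyDAG":
        """Build and validate a DAG from (child, parent) is_a pairs.

        Disconnected or multi-source graphs get an artificial root inserted,
        so the result is always single-rooted.
        """
        g = nx.DiGraph()
        g.add_nodes_from(extra_terms)
        g.add_edges_from(edges)
        if g.number_of_nodes() == 0:
            raise OntologyError("ontology is empty: no terms found")
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            pass
        else:
            raise OntologyError(
                f"ontology is not acyclic: cycle through edge {cycle[0][0]} -> {cycle[0][1]}"
            )
        sources = sorted(t for t in g.nodes if g.out_degree(t) == 0)
        names = dict(names or {})
        if len(sources) == 1:
            root = sources[0]
        else:
            root = ARTIFICIAL_ROOT
            names[root] = "artificial root"
            for s in sources:
                g.add_edge(s, root)
        parents = {t: set(g.successors(t)) for t in g.nodes}
        terms = set(g.nodes)
        for t in terms:
            names.setdefault(t, t)
        return cls(terms=terms, names={t: names[t] for t in terms}, parents=parents, root=root)

    # -- traversal --------------------------------------------------------

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including the term itself (memoised)."""
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        if term not in self.terms:
            raise OntologyError(f"unknown term: {term}")
        anc = {term}
        for p in self.parents[term]:
            anc |= self.ancestors(p)
        result = frozenset(anc)
        self._ancestors[term] = result
        return result

    def descendants(self, term: str) -> set[str]:
        """All descendants of ``term`` including the term itself."""
        out: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in out:
                continue
            out.add(t)
            stack.extend(self._children[t])
        return out

    def children(self, term: str) -> set[str]:
        return set(self._children[term])

    def topological_order(self) -> list[str]:
        """Terms ordered so every parent precedes its children (root first)."""
        ts = TopologicalSorter({t: self.parents[t] for t in self.terms})
        order = list(ts.static_order())  # parents (ancestors) first
        return order


def load_obo(path) -> OntologyDAG:
    """Read an OBO 1.2 file (id, name, is_a honoured; obsolete terms skipped)."""
    try:
        g = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # malformed stanzas surface as a format error
        raise OntologyError(f"cannot parse OBO file {path}: {exc}") from exc
    if g.number_of_nodes() == 0:
        raise OntologyError(f"OBO file {path} contains no usable [Term] stanzas")
    edges = [(c, p) for c, p, key in g.edges(keys=True) if key == "is_a"]
    names = {t: data.get("name", t) for t, data in g.nodes(data=True)}
    return OntologyDAG.from_edges(edges, names=names, extra_terms=g.nodes)


@dataclass
class AnnotationSet:
    """Term -> entity annotations in two layers: as asserted and propagated.

    ``propagated[t]`` is the union of direct annotations over the whole
    subtree below ``t`` (true-path rule); ``universe`` is every annotatable
    entity, i.e. ``propagated[root]`` unless an explicit background widened it.
    """

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]
    universe: frozenset[str]


def propagate(dag: OntologyDAG, direct: Mapping[str, Iterable[str]]) -> AnnotationSet:
    """Apply the true-path rule: every ancestor inherits its descendants' entities."""
    unknown = sorted(t for t in direct if t not in dag.terms)
    if unknown:
        raise OntologyError(f"annotations reference unknown terms: {', '.join(unknown)}")
    direct_sets = {t: frozenset(es) for t, es in direct.items()}
    acc: dict[str, set[str]] = {t: set(direct_sets.get(t, ())) for t in dag.terms}
    # children before parents: reversed topological order pushes unions rootward
    for t in reversed(dag.topological_order()):
        for p in dag.parents[t]:
            acc[p] |= acc[t]
    propagated = {t: frozenset(es) for t, es in acc.items() if es}
    universe = frozenset(acc[dag.root])
    return AnnotationSet(direct=direct_sets, propagated=propagated, universe=universe)


def compute_ic(ann: AnnotationSet, universe: Iterable[str] | None = None) -> dict[str, float]:
    """IC per term: ``-log10(|propagated[t]| / |universe|)``.

    Terms without propagated annotations carry no IC.  An explicit
    ``universe`` (background) may widen or restrict the denominator.
    """
    uni = frozenset(universe) if universe is not None else ann.universe
    if not uni:
        raise ValueError("annotation universe is empty; cannot compute information content")
    n = len(uni)
    ic: dict[str, float] = {}
    for t, entities in ann.propagated.items():
        m = len(entities & uni) if universe is not None else len(entities)
        if m:
            ic[t] = -math.log10(m / n) + 0.0  # +0.0 normalises -0.0 at the root
    return ic


def mica(dag: OntologyDAG, ic: Mapping[str, float], t1: str, t2: str) -> tuple[str, float]:
    """Most informative common ancestor of two terms and its IC.

    Ancestor sets include the terms themselves; ties on IC break
    lexicographically on term id so results are deterministic.
    """
    common = dag.ancestors(t1) & dag.ancestors(t2)
    scored = [(t, ic[t]) for t in common if t in ic]
    if not scored:
        raise OntologyError(
            f"no IC-bearing common ancestor for {t1} and {t2}; is the DAG rooted?"
        )
    best = min(scored, key=lambda pair: (-pair[1], pair[0]))
    return best
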