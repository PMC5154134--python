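"""Best-matching semantic similarity between annotated entities.

Each annotated entity (gene or SNP) carries an ontology annotation profile:
the terms directly asserted for it plus everything inherited rootwards by the
true-path rule.  Similarity between two entities is built from term-term
similarity — the information content of the most informative common ancestor
(MICA) — combined by one of three best-matching rules over the directly
asserted term sets T1 (size n1) and T2 (size n2):

* ``average`` — mean of the two directional best-match averages,
* ``maximum`` — the larger of the two directional averages,
* ``complete`` — minimum over all best-match values in either direction.

The complete rule is the default: averages grow with the number of asserted
terms, whereas a minimum does not, so complete is the least sensitive to
annotation density.  The direct term sets drive the formulas (inherited terms
enter through the MICA machinery); feeding the full ancestor closure in would
pin every best-match list at the root's IC of zero and flatten the complete
score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Mapping

from .ontology import AnnotationSet, OntologyDAG, OntologyError, mica

Method = Literal["average", "maximum", "complete"]


@dataclass(frozen=True)
class AnnotationProfile:
    """An entity's ontology profile: direct terms plus the ancestor closure."""

    entity: str
    direct: frozenset[str]
    terms: frozenset[str]  # ancestor-closed

    @property
    def inherited(self) -> frozenset[str]:
        return self.terms - self.direct


@dataclass
class SimilarityNetwork:
    """Weighted undirected similarity graph; edges keyed by sorted entity pair."""

    nodes: list[str]
    edges: dict[tuple[str, str], float]


def profile(entity: str, ann: AnnotationSet, dag: OntologyDAG) -> AnnotationProfile:
    """Annotation profile of one entity (direct terms + inherited ancestors)."""
    direct = frozenset(t for t, es in ann.direct.items() if entity in es)
    if not direct:
        raise OntologyError(f"entity {entity!r} has no direct annotations")
    closed: set[str] = set()
    for t in direct:
        closed |= dag.ancestors(t)
    return AnnotationProfile(entity=entity, direct=direct, terms=frozenset(closed))


def _best_matches(
    source: Iterable[str], target: list[str], dag: OntologyDAG, ic: Mapping[str, float]
) -> list[float]:
    return [max(mica(dag, ic, t1, t2)[1] for t2 in target) for t1 in source]


def pair_similarity(
    p1: AnnotationProfile,
    p2: AnnotationProfile,
    ic: Mapping[str, float],
    dag: OntologyDAG,
    method: Method = "complete",
) -> float:
    """Best-matching similarity between two profiles (symmetric, >= 0)."""
    t1 = sorted(t for t in p1.direct if t in ic)
    t2 = sorted(t for t in p2.direct if t in ic)
    if len(t1) < len(p1.direct) or len(t2) < len(p2.direct):
        warnings.warn(
            "terms without information content were excluded from a profile", stacklevel=2
        )
    if not t1 or not t2:
        raise ValueError("cannot compare profiles with no IC-bearing terms")
    bm12 = _best_matches(t1, t2, dag, ic)
    bm21 = _best_matches(t2, t1, dag, ic)
    avg12 = sum(bm12) / len(bm12)
    avg21 = sum(bm21) / len(bm21)
    if method == "average":
        return 0.5 * (avg12 + avg21)
    if method == "maximum":
        return max(avg12, avg21)
    if method == "complete":
        return min(bm12 + bm21)
    raise ValueError(f"unknown similarity method: {method!r}")


def similarity_network(
    entities: Iterable[str],
    ann: AnnotationSet,
    dag: OntologyDAG,
    ic: Mapping[str, float],
    method: Method = "complete",
    top_k: int | None = None,
) -> SimilarityNetwork:
    """All-pairs similarity network over the annotated subset of ``entities``.

    With ``top_k`` only the strongest ``top_k`` edges are retained (ties
    broken by entity pair so the cut is deterministic).  Self-similarity is
    defined but never emitted as an edge.
    """
    profiles = []
    for e in sorted(set(entities)):
        try:
            profiles.append(profile(e, ann, dag))
        except OntologyError:
            continue
    if len(profiles) < 2:
        raise ValueError("similarity network needs at least two annotated entities")
    edges: dict[tuple[str, str], float] = {}
    for pa, pb in combinations(profiles, 2):
        edges[(pa.entity, pb.entity)] = pair_similarity(pa, pb, ic, dag, method)
    if top_k is not None and top_k < len(edges):
        kept = sorted(edges.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
        edges = dict(sorted(kept))
    return SimilarityNetwork(nodes=[p.entity for p in profiles], edges=edges)
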