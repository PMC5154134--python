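"""GWAS summary statistics to SNP scores, gene scores, and a gene subnetwork.

The pipeline has three steps:

1. SNP scoring.  A SNP with association p-value P and LD strength R^2 to a
   lead SNP (R^2 = 1 for the lead itself) scores

       Score_SNP = R^2 * (log10((1-P)/P) - log10((1-P_thresh)/P_thresh)),

   with P_thresh the genome-wide significance threshold (5e-8 by default).
   The formula is zero at the threshold and negative below it; sub-threshold
   SNPs are truncated to zero so they contribute no prize downstream.

2. Gene scoring.  Each gene takes the maximum, over SNPs within a window D of
   its span, of Score_SNP * (1 - d/D)^lambda where d is the SNP-to-span
   distance (0 inside the span).  The max keeps only the most informative SNP
   per gene, so stacks of interdependent SNPs in one LD block do not inflate
   a gene's score.

3. Subnetwork search.  Gene scores become node prizes on an interaction
   network and a maximum-scoring connected subnetwork is extracted by a
   prize-collecting Steiner-tree heuristic: scores are shifted by a baseline
   so weak genes turn negative, positive nodes are connected through a
   cost-weighted Steiner/spanning tree, and an exact dynamic program on that
   tree keeps the best-scoring connected subtree.  A desired subnetwork size
   is met by bisecting the baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from networkx.algorithms.approximation import steiner_tree


class EmptyResultError(Exception):
    """The search space contains nothing to report (no positive signal)."""


@dataclass(frozen=True)
class SnpRecord:
    snp: str
    chrom: str
    pos: int  # 1-based base coordinate
    p: float

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError(f"SNP {self.snp}: p-value must be in (0, 1], got {self.p}")
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp}: position must be >= 1")


@dataclass(frozen=True)
class LdPair:
    lead: str
    proxy: str
    r2: float

    def __post_init__(self) -> None:
        if not (0 <= self.r2 <= 1):
            raise ValueError(f"LD pair {self.lead}-{self.proxy}: R^2 must be in [0, 1]")


@dataclass(frozen=True)
class ScoredSnp:
    snp: str
    chrom: str
    pos: int
    p: float
    r2: float  # 1 for lead SNPs


@dataclass(frozen=True)
class GeneModel:
    gene: str
    chrom: str
    start: int  # half-open 0-based span
    end: int


@dataclass(frozen=True)
class ScoreParams:
    """Tunable knobs of the SNP->gene scoring scheme."""

    p_thresh: float = 5e-8
    D: int = 50_000  # bases
    lam: float = 2.0
    p_floor: float = 1e-300
    r2_min: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.p_thresh < 1):
            raise ValueError("p_thresh must be in (0, 1)")
        if self.D <= 0:
            raise ValueError("distance window D must be positive")
        if self.lam < 0:
            raise ValueError("decay exponent lambda must be >= 0")


@dataclass
class ScoredGraph:
    """Simple undirected gene network with per-node real-valued scores."""

    graph: nx.Graph
    scores: dict[str, float] = field(default_factory=dict)

    def total_score(self) -> float:
        return sum(self.scores.get(v, 0.0) for v in self.graph.nodes)


def _logit10(p: float) -> float:
    return math.log10((1.0 - p) / p)


def score_snp(p: float, r2: float, params: ScoreParams = ScoreParams()) -> float:
    """Prize of one SNP; zero at/above the significance threshold."""
    if not (0 < p <= 1):
        raise ValueError(f"p-value must be in (0, 1], got {p}")
    p = max(p, params.p_floor)
    raw = r2 * (_logit10(p) - _logit10(params.p_thresh))
    return max(raw, 0.0)


def expand_ld(
    leads: Sequence[SnpRecord],
    ld: Sequence[LdPair],
    snp_positions: Mapping[str, tuple[str, int]] | None = None,
    r2_min: float = 0.8,
) -> list[ScoredSnp]:
    """Augment lead SNPs with LD proxies at R^2 strictly above ``r2_min``.

    Proxies inherit the p-value of their lead; a proxy linked to several
    leads keeps the pair with the most significant lead, breaking ties on
    the larger R^2.  Proxies whose genomic position is unknown are dropped
    (with one summary warning).
    """
    snp_positions = snp_positions or {}
    by_id = {s.snp: s for s in leads}
    out: dict[str, ScoredSnp] = {
        s.snp: ScoredSnp(s.snp, s.chrom, s.pos, s.p, 1.0) for s in leads
    }
    candidates: dict[str, tuple[float, float, str]] = {}  # proxy -> (lead_p, -r2, lead)
    for pair in ld:
        lead = by_id.get(pair.lead)
        if lead is None or pair.r2 <= r2_min or pair.proxy in by_id:
            continue
        key = (lead.p, -pair.r2, lead.snp)
        if pair.proxy not in candidates or key < candidates[pair.proxy]:
            candidates[pair.proxy] = key
    dropped = 0
    for proxy, (lead_p, neg_r2, _lead_id) in sorted(candidates.items()):
        loc = snp_positions.get(proxy)
        if loc is None:
            dropped += 1
            continue
        out[proxy] = ScoredSnp(proxy, loc[0], loc[1], lead_p, -neg_r2)
    if dropped:
        warnings.warn(f"dropped {dropped} LD proxies with unknown positions", stacklevel=2)
    return [out[s] for s in sorted(out)]


def _span_distance(pos: int, gene: GeneModel) -> int:
    """Distance from a 1-based SNP coordinate to a half-open gene span."""
    point = pos - 1
    if gene.start <= point < gene.end:
        return 0
    if point < gene.start:
        return gene.start - point
    return point - (gene.end - 1)


def score_genes(
    snps: Sequence[ScoredSnp],
    genes: Sequence[GeneModel],
    params: ScoreParams = ScoreParams(),
) -> dict[str, float]:
    """Gene scores under the distance-decayed maximum scheme.

    Genes with no SNP within the window ``D`` are absent from the map.
    """
    snp_scores = [(s, score_snp(s.p, s.r2, params)) for s in snps]
    out: dict[str, float] = {}
    for gene in genes:
        best = None
        for s, sc in snp_scores:
            if s.chrom != gene.chrom:
                continue
            d = _span_distance(s.pos, gene)
            if d > params.D:
                continue
            candidate = sc * (1.0 - d / params.D) ** params.lam
            if best is None or candidate > best:
                best = candidate
        if best is not None:
            out[gene.gene] = best
    return out


# -- maximum-scoring subnetwork ------------------------------------------


def _best_subtree(tree: nx.Graph, weights: Mapping[str, float]) -> set[str]:
    """Exact maximum-weight connected subtree of a tree (node weights)."""
    root = min(tree.nodes)
    down: dict[str, float] = {}
    order = list(nx.dfs_postorder_nodes(tree, root))
    parent = dict(nx.dfs_predecessors(tree, root))
    children: dict[str, list[str]] = {v: [] for v in tree.nodes}
    for v, par in parent.items():
        children[par].append(v)
    for v in order:
        down[v] = weights[v] + sum(max(0.0, down[c]) for c in children[v])
    best_root = max(sorted(down), key=lambda v: down[v])
    keep = set()
    stack = [best_root]
    while stack:
        v = stack.pop()
        keep.add(v)
        stack.extend(c for c in children[v] if down[c] > 0)
    return keep


def _search_component(g: nx.Graph, shifted: Mapping[str, float]) -> set[str] | None:
    positive = [v for v in g.nodes if shifted[v] > 0]
    if not positive:
        return None
    if len(positive) == 1:
        return {positive[0]}
    cost = {v: max(0.0, -shifted[v]) for v in g.nodes}
    weighted = g.copy()
    # tiny per-hop cost so zero-cost ties resolve to the fewest linkers
    for u, v in weighted.edges:
        weighted[u][v]["pcst_cost"] = 0.5 * (cost[u] + cost[v]) + 1e-9
    st = steiner_tree(weighted, positive, weight="pcst_cost", method="mehlhorn")
    if st.number_of_nodes() == 0:
        return {max(sorted(positive), key=lambda v: shifted[v])}
    tree = nx.minimum_spanning_tree(weighted.subgraph(st.nodes), weight="pcst_cost")
    keep = _best_subtree(tree, shifted)
    # a lone strong component may still beat the pruned tree
    best_single = max(
        (c for c in nx.connected_components(g.subgraph(positive))),
        key=lambda c: sum(shifted[v] for v in c),
    )
    if sum(shifted[v] for v in best_single) > sum(shifted[v] for v in keep):
        return set(best_single)
    return keep


def _solve(sg: ScoredGraph, baseline: float) -> set[str] | None:
    shifted = {v: sg.scores.get(v, 0.0) - baseline for v in sg.graph.nodes}
    best: set[str] | None = None
    best_score = -math.inf
    for comp in nx.connected_components(sg.graph):
        keep = _search_component(sg.graph.subgraph(comp), shifted)
        if keep is None:
            continue
        score = sum(shifted[v] for v in keep)
        if score > best_score:
            best, best_score = keep, score
    return best


def find_subnetwork(
    sg: ScoredGraph,
    target_n: int | None = None,
    baseline: float = 0.0,
    max_iter: int = 20,
) -> ScoredGraph:
    """Maximum-scoring connected subnetwork (prize-collecting heuristic).

    Node scores are shifted by ``baseline`` so that weak nodes carry negative
    prizes; the returned subgraph is connected, its shifted score is at least
    that of the best single positive node, and no strictly-negative node ever
    sits at a leaf.  With ``target_n`` the baseline is bisected until the
    subnetwork reaches the requested size; if the exact size is unreachable
    within ``max_iter`` halvings the closest achieved size is returned with a
    warning.
    """
    if target_n is None:
        keep = _solve(sg, baseline)
        if keep is None:
            raise EmptyResultError(
                "no node scores above the baseline; lower the baseline or "
                "check that any SNP passes the significance threshold"
            )
        return ScoredGraph(
            graph=sg.graph.subgraph(keep).copy(),
            scores={v: sg.scores.get(v, 0.0) for v in keep},
        )
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    values = [sg.scores.get(v, 0.0) for v in sg.graph.nodes]
    lo, hi = min(values) - 1e-9, max(values)
    best_keep: set[str] | None = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        keep = _solve(sg, mid)
        size = len(keep) if keep else 0
        if keep is not None and (
            best_keep is None or abs(size - target_n) < abs(len(best_keep) - target_n)
        ):
            best_keep = keep
        if size == target_n:
            best_keep = keep
            break
        if size > target_n:
            lo = mid  # raise the bar -> smaller subnetwork
        else:
            hi = mid
    if best_keep is None:
        raise EmptyResultError("no positive nodes at any admissible baseline")
    if len(best_keep) != target_n:
        warnings.warn(
            f"requested {target_n} nodes, best achievable was {len(best_keep)}",
            stacklevel=2,
        )
    return ScoredGraph(
        graph=sg.graph.subgraph(best_keep).copy(),
        scores={v: sg.scores.get(v, 0.0) for v in best_keep},
    )


def subnet_from_snps(
    snps: Sequence[SnpRecord],
    ld: Sequence[LdPair],
    genes: Sequence[GeneModel],
    network: nx.Graph,
    params: ScoreParams = ScoreParams(),
    target_n: int | None = None,
    snp_positions: Mapping[str, tuple[str, int]] | None = None,
) -> ScoredGraph:
    """Full pipeline: LD expansion -> SNP scores -> gene scores -> subnetwork."""
    expanded = expand_ld(snps, ld, snp_positions, r2_min=params.r2_min)
    gene_scores = score_genes(expanded, genes, params)
    in_net = {g: s for g, s in gene_scores.items() if g in network}
    missing = len(gene_scores) - len(in_net)
    if missing:
        warnings.warn(
            f"{missing} scored genes are absent from the interaction network", stacklevel=2
        )
    sg = ScoredGraph(graph=network, scores={v: in_net.get(v, 0.0) for v in network.nodes})
    return find_subnetwork(sg, target_n=target_n)
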