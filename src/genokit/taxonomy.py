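"""Cross-trait gene-score matrix, trait distances, and consensus NJ tree.

Each trait (e.g. one disease's GWAS) yields a gene -> score map from the
SNP-to-gene scoring pipeline.  Stacking traits over the union of scored genes
gives a trait x gene matrix; the distance between two traits is the cumulative
difference of their gene scores (an L1 metric over the gene union, missing
genes scoring 0).  A neighbour-joining tree over that distance matrix groups
traits by their shared genetic architecture, and bootstrap resampling of gene
columns puts majority-rule support values on its internal edges.

The NJ agglomeration is the classic Saitou-Nei procedure with two
deterministic conventions: ties in the Q criterion break on the
lexicographically smallest label pair, and a negative limb length is clamped
to zero with the deficit transferred to its sibling limb so path lengths are
preserved.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist
from skbio import TreeNode


@dataclass
class ScoreMatrix:
    """Trait x gene non-negative score matrix (genes sorted by label)."""

    traits: list[str]
    genes: list[str]
    scores: np.ndarray  # shape (n_traits, n_genes)


@dataclass
class TraitTree:
    """Unrooted trait tree (trifurcating root) with optional edge supports."""

    tree: TreeNode
    supports: dict[frozenset[str], float]

    def newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf)
        return buf.getvalue().strip()


def build_score_matrix(per_trait: Mapping[str, Mapping[str, float]]) -> ScoreMatrix:
    """Assemble per-trait gene-score maps into one matrix (missing genes -> 0)."""
    traits = list(per_trait)
    if len(traits) != len(set(traits)):
        raise ValueError("duplicate trait labels")
    if len(traits) < 3:
        raise ValueError("need at least three traits to build a trait tree")
    genes = sorted({g for m in per_trait.values() for g in m})
    mat = np.zeros((len(traits), len(genes)))
    for i, t in enumerate(traits):
        for j, g in enumerate(genes):
            mat[i, j] = per_trait[t].get(g, 0.0)
    if not np.all(np.isfinite(mat)):
        raise ValueError("gene scores must be finite")
    return ScoreMatrix(traits=traits, genes=genes, scores=mat)


def trait_distance(m: ScoreMatrix) -> np.ndarray:
    """Cumulative gene-score difference between traits: pairwise L1 distances."""
    return squareform(pdist(m.scores, metric="cityblock"))


def nj_tree(d: np.ndarray, labels: Sequence[str]) -> TraitTree:
    """Saitou-Nei neighbour joining; exact on additive distances."""
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if n < 3:
        raise ValueError("neighbour joining needs at least three taxa")
    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    dist: dict[tuple[str, str], float] = {}
    active = sorted(labels)
    for i, a in enumerate(active):
        for b in active[i + 1 :]:
            dist[(a, b)] = d[labels.index(a), labels.index(b)]

    def dd(a: str, b: str) -> float:
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    counter = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(dd(a, b) for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (m - 2) * dd(a, b) - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        la = 0.5 * dd(a, b) + (r[a] - r[b]) / (2 * (m - 2))
        lb = dd(a, b) - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        new = f"\x00internal{counter}"
        counter += 1
        nodes[a].length = max(la, 0.0)
        nodes[b].length = max(lb, 0.0)
        parent = TreeNode(children=[nodes[a], nodes[b]])
        nodes[new] = parent
        for c in active:
            if c in (a, b):
                continue
            dist[(new, c)] = 0.5 * (dd(a, c) + dd(b, c) - dd(a, b))
        active = sorted([c for c in active if c not in (a, b)] + [new])
    a, b, c = active
    la = 0.5 * (dd(a, b) + dd(a, c) - dd(b, c))
    lb = 0.5 * (dd(a, b) + dd(b, c) - dd(a, c))
    lc = 0.5 * (dd(a, c) + dd(b, c) - dd(a, b))
    for lab, length in ((a, la), (b, lb), (c, lc)):
        nodes[lab].length = max(length, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return TraitTree(tree=root, supports={})


def _splits(tree: TreeNode, ref: str, leaves: frozenset[str]) -> dict[frozenset[str], float]:
    """Internal-edge bipartitions, keyed by the side NOT containing ``ref``."""
    out: dict[frozenset[str], float] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = leaves - side
        if 1 < len(side) < len(leaves) - 1:
            out[side] = node.length if node.length is not None else 0.0
    return out


def _leafset(node: TreeNode) -> frozenset[str]:
    if node.is_tip():
        return frozenset([node.name])
    return frozenset(t.name for t in node.tips())


def consensus_tree(
    m: ScoreMatrix,
    B: int = 100,
    seed: int | np.random.Generator = 0,
) -> TraitTree:
    """Majority-rule consensus NJ tree from gene-column bootstrap resampling.

    Gene columns are resampled with replacement ``B`` times; each replicate's
    L1 distances feed neighbour joining.  Splits appearing in more than half
    of the replicates form the consensus topology; internal-edge lengths are
    averaged over the replicates containing the split, leaf-edge lengths over
    all replicates, and each internal edge carries its support fraction.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    leaves = frozenset(m.traits)
    ref = min(m.traits)
    split_count: dict[frozenset[str], int] = {}
    split_lensum: dict[frozenset[str], float] = {}
    leaf_lensum = {t: 0.0 for t in m.traits}
    n_genes = m.scores.shape[1]
    for _ in range(B):
        cols = rng.integers(0, n_genes, size=n_genes) if B > 1 else np.arange(n_genes)
        boot = ScoreMatrix(traits=m.traits, genes=m.genes, scores=m.scores[:, cols])
        t = nj_tree(trait_distance(boot), m.traits)
        for split, length in _splits(t.tree, ref, leaves).items():
            split_count[split] = split_count.get(split, 0) + 1
            split_lensum[split] = split_lensum.get(split, 0.0) + length
        for tip in t.tree.tips():
            leaf_lensum[tip.name] += tip.length or 0.0
    majority = [
        (s, split_count[s] / B, split_lensum[s] / split_count[s])
        for s in split_count
        if split_count[s] / B > 0.5
    ]
    majority.sort(key=lambda item: (-len(item[0]), sorted(item[0])))
    root = TreeNode(
        children=[TreeNode(name=t, length=leaf_lensum[t] / B) for t in sorted(m.traits)]
    )
    supports: dict[frozenset[str], float] = {}
    for split, support, length in majority:
        host = root
        while True:
            inner = [c for c in host.children if _leafset(c) >= split]
            if inner and _leafset(inner[0]) > split:
                host = inner[0]
                continue
            break
        grouped = [c for c in host.children if _leafset(c) <= split]
        if frozenset().union(*(_leafset(c) for c in grouped)) != split:
            continue  # incompatible with an earlier (better-supported) split
        for c in grouped:
            host.remove(c)
        newnode = TreeNode(name=f"{support:.2f}", length=length, children=grouped)
        host.append(newnode)
        supports[split] = support
    return TraitTree(tree=root, supports=supports)
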