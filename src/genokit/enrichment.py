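"""Term-enrichment testing with ontology-tree-aware significance.

Three counting tests are offered for a 2x2 overlap table (background size N,
term size M, input size k, overlap x):

* ``fisher`` — one-sided enrichment tail of the hypergeometric law,
  P(X >= x): sampling without replacement.
* ``hypergeometric`` — the strict tail P(X > x).
* ``binomial`` — P(Bin(k, M/N) >= x): sampling with replacement.

For an enriched table (x/k > M/N) with nonzero point mass, the strict tail is
always below the inclusive one (p_hypergeometric < p_fisher) — the reason the
strict-tail reading of the "hypergeometric test" is the right one.  Sampling
without replacement also thins the deep upper tail, so throughout the
significance regime (Fisher p below ~0.1, at least two draws) the full
ordering p_hypergeometric < p_fisher < p_binomial holds; close to the null
mean the binomial can dip below Fisher, but no term is reported significant
there.

Tree-aware mode re-tests each term after discounting input entities already
explained by a significant descendant (leaf-to-root elimination), so parents
that merely aggregate their children's signal drop out.  For flat collections
a redundancy filter flags terms whose overlap is subsumed by a more
significant term of comparable granularity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ontology import AnnotationSet, OntologyDAG

TestName = Literal["fisher", "hypergeometric", "binomial"]


@dataclass(frozen=True)
class ContingencyCounts:
    """Overlap table: N background, M term entities, k input entities, x overlap."""

    N: int
    M: int
    k: int
    x: int

    def __post_init__(self) -> None:
        if not (0 <= self.x <= min(self.M, self.k) and self.M <= self.N and self.k <= self.N):
            raise ValueError(f"inconsistent contingency counts: {self}")


@dataclass
class EnrichmentRecord:
    """One tested term: counts, fold change, raw/adjusted p, overlapping members."""

    term: str
    name: str
    counts: ContingencyCounts
    fold_change: float
    p: float
    adj_p: float
    members: list[str]
    flagged_redundant: bool = False


def run_test(counts: ContingencyCounts, test: TestName = "fisher") -> float:
    """One-sided enrichment p-value for a single overlap table."""
    N, M, k, x = counts.N, counts.M, counts.k, counts.x
    if M == 0:
        raise ValueError("term annotates no background entities; no p-value defined")
    if test == "fisher":
        return float(stats.hypergeom.sf(x - 1, N, M, k))
    if test == "hypergeometric":
        return float(stats.hypergeom.sf(x, N, M, k))
    if test == "binomial":
        return float(stats.binom.sf(x - 1, k, M / N))
    raise ValueError(f"unknown test: {test!r}")


def adjust_pvalues(p: Sequence[float], method: Literal["fdr", "fwer"] = "fdr") -> np.ndarray:
    """Multiple-testing adjustment: BH step-up for FDR, Bonferroni for FWER."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"fdr": "fdr_bh", "fwer": "bonferroni"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown adjustment method: {method!r}")
    return multipletests(arr, method=sm_method)[1]


def _effective_sets(
    input_entities: Iterable[str],
    ann: AnnotationSet,
    background: Iterable[str] | None,
) -> tuple[frozenset[str], frozenset[str]]:
    bg = frozenset(background) & ann.universe if background is not None else ann.universe
    raw = frozenset(input_entities)
    eff = raw & bg
    if not eff:
        raise ValueError(
            f"no usable input: {len(raw)} entities supplied, 0 matched the "
            f"{len(bg)}-entity background universe"
        )
    return eff, bg


def _finish_records(
    rows: list[tuple[str, ContingencyCounts, frozenset[str]]],
    ann_names: dict[str, str],
    test: TestName,
    adjust: Literal["fdr", "fwer"],
) -> list[EnrichmentRecord]:
    pvals = [run_test(c, test) for _, c, _ in rows]
    adj = adjust_pvalues(pvals, adjust)
    records = []
    for (term, c, members), p, ap in zip(rows, pvals, adj):
        expected = c.M / c.N
        observed = c.x / c.k if c.k else 0.0
        fc = observed / expected if expected > 0 else float("nan")
        records.append(
            EnrichmentRecord(
                term=term,
                name=ann_names.get(term, term),
                counts=c,
                fold_change=fc,
                p=float(p),
                adj_p=float(ap),
                members=sorted(members),
            )
        )
    records.sort(key=lambda r: (r.p, r.term))
    return records


def enrich(
    input_entities: Iterable[str],
    ann: AnnotationSet,
    *,
    names: dict[str, str] | None = None,
    background: Iterable[str] | None = None,
    test: TestName = "fisher",
    min_size: int = 10,
    max_size: int = 2000,
    adjust: Literal["fdr", "fwer"] = "fdr",
) -> list[EnrichmentRecord]:
    """Flat enrichment of an entity list against propagated term annotations.

    One record per term whose propagated annotation size within the
    background lies in ``[min_size, max_size]``, sorted by ascending p then
    term id.
    """
    eff, bg = _effective_sets(input_entities, ann, background)
    N, k = len(bg), len(eff)
    rows = []
    for term in sorted(ann.propagated):
        term_bg = ann.propagated[term] & bg
        M = len(term_bg)
        if not (min_size <= M <= max_size):
            continue
        members = eff & term_bg
        rows.append((term, ContingencyCounts(N=N, M=M, k=k, x=len(members)), members))
    return _finish_records(rows, names or {}, test, adjust)


def tree_aware_enrich(
    input_entities: Iterable[str],
    dag: OntologyDAG,
    ann: AnnotationSet,
    *,
    names: dict[str, str] | None = None,
    background: Iterable[str] | None = None,
    test: TestName = "fisher",
    alpha_elim: float = 0.05,
    min_size: int = 10,
    max_size: int = 2000,
    adjust: Literal["fdr", "fwer"] = "fdr",
) -> list[EnrichmentRecord]:
    """Leaf-to-root elimination enrichment over a structured ontology.

    Terms are tested leaves first.  When a term's raw p-value falls below
    ``alpha_elim`` its input-overlapping entities are claimed: every ancestor
    is subsequently tested with those entities removed from both its overlap
    (x) and its annotation count (M), so a parent whose signal is wholly
    carried by one significant child reports x = 0 and p = 1.  Reported
    counts, fold changes and member lists are the post-elimination ones.
    """
    eff, bg = _effective_sets(input_entities, ann, background)
    N, k = len(bg), len(eff)
    claimed: dict[str, set[str]] = {t: set() for t in dag.terms}
    rows = []
    for term in reversed(dag.topological_order()):  # leaves -> root
        term_bg = ann.propagated.get(term, frozenset()) & bg
        if not term_bg:
            continue
        M_full = len(term_bg)
        removed = claimed[term] & term_bg
        adj_ann = term_bg - removed
        members = eff & adj_ann
        p_elim = 1.0
        if adj_ann:
            counts = ContingencyCounts(N=N, M=len(adj_ann), k=k, x=len(members))
            p_elim = run_test(counts, test)
        if p_elim < alpha_elim:
            newly = eff & term_bg
            for anc in dag.ancestors(term) - {term}:
                claimed[anc] |= newly
        if min_size <= M_full <= max_size and adj_ann:
            rows.append((term, counts, members))
    return _finish_records(rows, names or {}, test, adjust)


def filter_redundant(
    records: Sequence[EnrichmentRecord],
    c1: float = 0.90,
    c2: float = 0.50,
) -> list[EnrichmentRecord]:
    """Flag terms whose input overlap is subsumed by a retained better term.

    Records must arrive sorted by ascending p.  Scanning less significant
    terms B against every already-retained more significant term A, B is
    flagged redundant iff

    * more than ``c1`` of B's overlapping members are also members of A, and
    * more than ``c2`` of A's overlapping members are also members of B.

    The second criterion keeps small specific terms under broad ones
    (different granularity is information, not redundancy).  Flagged records
    never serve as A for later comparisons.
    """
    retained: list[EnrichmentRecord] = []
    out = []
    for rec in records:
        members_b = set(rec.members)
        if not members_b:
            warnings.warn(f"term {rec.term} has no overlapping members; skipped", stacklevel=2)
            out.append(rec)
            continue
        flagged = False
        for a in retained:
            members_a = set(a.members)
            shared = len(members_a & members_b)
            if shared / len(members_b) > c1 and shared / len(members_a) > c2:
                flagged = True
                break
        rec.flagged_redundant = flagged
        if not flagged:
            retained.append(rec)
        out.append(rec)
    return out
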