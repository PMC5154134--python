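"""Plain-text readers and writers: GMT, OBO subset, BED3, TSV tables, DOT, Newick.

All writers emit sorted, deterministic output so that identical inputs give
byte-identical files; all readers raise :class:`FormatError` with file and
line context on malformed content.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .enrichment import EnrichmentRecord
from .netscore import GeneModel, LdPair, ScoredGraph, SnpRecord
from .ontology import OntologyDAG, load_obo  # noqa: F401  (load_obo re-exported here)
from .regions import RegionEnrichmentRecord, RegionSet
from .similarity import SimilarityNetwork
from .taxonomy import TraitTree


class FormatError(Exception):
    """Malformed input file; message carries file:line context."""


def _fail(path, lineno: int, msg: str):
    raise FormatError(f"{path}:{lineno}: {msg}")


def _lines(path):
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line and not line.startswith("#"):
                yield i, line


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


# -- GMT ------------------------------------------------------------------


def read_gmt(path) -> dict[str, tuple[str, frozenset[str]]]:
    """Gene sets, one per line: name TAB description TAB member..."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for i, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            _fail(path, i, "GMT line needs name, description, and >=1 member")
        name, desc, members = parts[0], parts[1], frozenset(parts[2:])
        sets[name] = (desc, members)
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: Mapping[str, tuple[str, Iterable[str]]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            desc, members = sets[name]
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# -- OBO subset -----------------------------------------------------------


def write_obo(dag: OntologyDAG, path) -> None:
    """Minimal OBO 1.2 serialisation (id, name, is_a)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {dag.names[term]}\n")
            for parent in sorted(dag.parents[term]):
                fh.write(f"is_a: {parent}\n")


# -- entity lists and TSV tables -----------------------------------------


def read_entity_list(path) -> list[str]:
    """One entity id per line; an optional second column is carried nowhere."""
    out = []
    for _, line in _lines(path):
        out.append(line.split("\t")[0])
    if not out:
        raise FormatError(f"{path}: empty entity list")
    return out


def read_bed(path) -> RegionSet:
    intervals = []
    for i, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            _fail(path, i, "BED line needs chrom, start, end")
        try:
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
        except ValueError:
            _fail(path, i, f"non-integer coordinates: {parts[1]!r}, {parts[2]!r}")
    if not intervals:
        raise FormatError(f"{path}: no intervals found")
    return RegionSet.from_intervals(intervals)


def write_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in regions.intervals():
            fh.write(f"{chrom}\t{s}\t{e}\n")


def read_snps(path) -> list[SnpRecord]:
    """SNP summary table: snp TAB chrom TAB pos TAB p."""
    out = []
    for i, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 4:
            _fail(path, i, "SNP line needs snp, chrom, pos, p")
        try:
            out.append(SnpRecord(parts[0], parts[1], int(parts[2]), float(parts[3])))
        except ValueError as exc:
            _fail(path, i, str(exc))
    return out


def write_snps(snps: Sequence[SnpRecord], path) -> None:
    with open(path, "w") as fh:
        for s in sorted(snps, key=lambda r: r.snp):
            fh.write(f"{s.snp}\t{s.chrom}\t{s.pos}\t{s.p:.6g}\n")


def read_ld(path) -> list[LdPair]:
    out = []
    for i, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            _fail(path, i, "LD line needs lead, proxy, r2")
        try:
            out.append(LdPair(parts[0], parts[1], float(parts[2])))
        except ValueError as exc:
            _fail(path, i, str(exc))
    return out


def write_ld(pairs: Sequence[LdPair], path) -> None:
    with open(path, "w") as fh:
        for p in sorted(pairs, key=lambda q: (q.lead, q.proxy)):
            fh.write(f"{p.lead}\t{p.proxy}\t{p.r2:.4g}\n")


def read_gene_models(path) -> list[GeneModel]:
    """Gene spans: gene TAB chrom TAB start TAB end (half-open 0-based)."""
    out = []
    for i, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 4:
            _fail(path, i, "gene-model line needs gene, chrom, start, end")
        try:
            out.append(GeneModel(parts[0], parts[1], int(parts[2]), int(parts[3])))
        except ValueError as exc:
            _fail(path, i, str(exc))
    return out


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda x: x.gene):
            fh.write(f"{g.gene}\t{g.chrom}\t{g.start}\t{g.end}\n")


def read_network(path) -> nx.Graph:
    """Weighted edge list: geneA TAB geneB [TAB weight]."""
    g = nx.Graph()
    for i, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 2:
            _fail(path, i, "network line needs two gene ids")
        w = 1.0
        if len(parts) >= 3:
            try:
                w = float(parts[2])
            except ValueError:
                _fail(path, i, f"non-numeric edge weight: {parts[2]!r}")
        g.add_edge(parts[0], parts[1], weight=w)
    if g.number_of_edges() == 0:
        raise FormatError(f"{path}: no edges found")
    return g


def write_network(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(g.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
            a, b = sorted((u, v))
            fh.write(f"{a}\t{b}\t{data.get('weight', 1.0):.4g}\n")


def read_node_scores(path) -> dict[str, float]:
    out = {}
    for i, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 2:
            _fail(path, i, "node-score line needs id and score")
        try:
            out[parts[0]] = float(parts[1])
        except ValueError:
            _fail(path, i, f"non-numeric score: {parts[1]!r}")
    return out


def write_node_scores(scores: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        for k in sorted(scores):
            fh.write(f"{k}\t{scores[k]:.6g}\n")


# -- result writers -------------------------------------------------------

ENRICH_COLUMNS = "term_id\tname\tnAnno\tnOverlap\tfc\tp\tadj_p\tflagged_redundant\tmembers"


def write_enrichment(records: Sequence[EnrichmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(ENRICH_COLUMNS + "\n")
        for r in records:
            fh.write(
                f"{r.term}\t{r.name}\t{r.counts.M}\t{r.counts.x}\t{r.fold_change:.4g}\t"
                f"{r.p:.4g}\t{r.adj_p:.4g}\t{int(r.flagged_redundant)}\t"
                f"{','.join(r.members)}\n"
            )


def write_region_enrichment(records: Sequence[RegionEnrichmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tobserved\texpected\tfc\tp\tadj_p\tnull_mean\tnull_sd\tz\n")
        for r in records:
            extra = (
                f"{r.null_mean:.4g}\t{r.null_sd:.4g}\t{r.z:.4g}"
                if r.null_mean is not None
                else "NA\tNA\tNA"
            )
            fh.write(
                f"{r.name}\t{r.observed}\t{r.expected:.4g}\t{r.fold_change:.4g}\t"
                f"{r.p:.4g}\t{r.adj_p:.4g}\t{extra}\n"
            )


def write_similarity_edges(net: SimilarityNetwork, path) -> None:
    with open(path, "w") as fh:
        for (a, b), w in sorted(net.edges.items()):
            fh.write(f"{a}\t{b}\t{w:.6g}\n")


def write_similarity_matrix(net: SimilarityNetwork, path) -> None:
    nodes = sorted(net.nodes)
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(nodes) + "\n")
        for a in nodes:
            row = []
            for b in nodes:
                if a == b:
                    row.append("0")
                else:
                    key = (min(a, b), max(a, b))
                    row.append(f"{net.edges.get(key, 0.0):.6g}")
            fh.write(a + "\t" + "\t".join(row) + "\n")


def write_dot(sg: ScoredGraph, path) -> None:
    """GraphViz DOT export of a scored (sub)network."""
    with open(path, "w") as fh:
        fh.write("graph subnetwork {\n")
        for v in sorted(sg.graph.nodes):
            fh.write(f'  "{v}" [score="{sg.scores.get(v, 0.0):.4g}"];\n')
        for u, v in sorted(tuple(sorted(e)) for e in sg.graph.edges):
            fh.write(f'  "{u}" -- "{v}";\n')
        fh.write("}\n")


def dag_to_dot(dag: OntologyDAG, terms: Iterable[str] | None = None) -> str:
    """DOT text of the ontology (optionally restricted to an ancestor-closed set)."""
    keep = set(terms) if terms is not None else set(dag.terms)
    lines = ["digraph ontology {"]
    for t in sorted(keep):
        lines.append(f'  "{t}" [label="{dag.names[t]}"];')
    for t in sorted(keep):
        for p in sorted(dag.parents[t]):
            if p in keep:
                lines.append(f'  "{t}" -> "{p}" [label="is_a"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_newick(tree: TraitTree, path) -> None:
    Path(path).write_text(tree.newick() + "\n")
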