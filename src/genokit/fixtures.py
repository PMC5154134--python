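"""Synthetic knowledge and summary-data generator.

Every analysis in this package consumes user-supplied knowledge files
(ontologies, annotation sets, interaction networks, genomic tracks) plus
summary data (gene lists, GWAS SNPs, regions).  This module fabricates an
internally consistent bundle of all of them from a single seed, with known
planted structure recorded in a truth ledger, so that each method can be
exercised — and its recovery of the planted signal measured — without any
external download.

What the bundle emulates, statistically:

* a rooted ontology DAG with occasional multiple parents (diamonds) and
  annotation sizes growing rootwards under the true-path rule;
* a scale-free (preferential-attachment) gene interaction network;
* a two-chromosome genome with evenly spaced gene spans, GWAS SNPs whose
  p-values are uniform under the null, a handful of planted genome-wide
  significant loci inside one connected network module, and LD proxies for
  the planted leads;
* genomic annotation tracks, one of which the input regions preferentially
  overlap.

Three scales are provided: ``tiny`` is small enough for exhaustive oracles
(every subgraph, every contingency table), ``small`` is the default test
scale, ``medium`` approximates a realistic workload.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import json

import networkx as nx
import numpy as np

from .netscore import GeneModel, LdPair, SnpRecord
from .ontology import AnnotationSet, OntologyDAG, propagate
from .regions import RegionSet

SCALES: dict[str, dict[str, int]] = {
    "tiny": dict(
        n_terms=10, n_genes=10, n_snps=20, direct_lo=1, direct_hi=3,
        planted_size=4, gene_spacing=100_000, gene_len=20_000, n_pathways=6,
    ),
    "small": dict(
        n_terms=50, n_genes=200, n_snps=500, direct_lo=3, direct_hi=12,
        planted_size=20, gene_spacing=100_000, gene_len=20_000, n_pathways=20,
    ),
    "medium": dict(
        n_terms=200, n_genes=2000, n_snps=5000, direct_lo=5, direct_hi=40,
        planted_size=50, gene_spacing=100_000, gene_len=20_000, n_pathways=60,
    ),
}


@dataclass
class FixtureBundle:
    """Complete synthetic inputs for one seed, plus the planted truth."""

    dag: OntologyDAG
    annotations: AnnotationSet
    flat_sets: dict[str, tuple[str, frozenset[str]]]
    network: nx.Graph
    genes: list[GeneModel]
    snps: list[SnpRecord]
    ld: list[LdPair]
    snp_positions: dict[str, tuple[str, int]]
    input_regions: RegionSet
    tracks: dict[str, RegionSet]
    background: RegionSet
    truth: dict[str, Any] = field(default_factory=dict)


def _build_dag(rng: np.random.Generator, n_terms: int) -> OntologyDAG:
    terms = [f"T{i:03d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        parent = terms[int(rng.integers(0, i))]
        edges.append((terms[i], parent))
        if i > 2 and rng.random() < 0.10:  # diamond: a second parent
            second = terms[int(rng.integers(0, i))]
            if second != parent:
                edges.append((terms[i], second))
    names = {t: f"synthetic term {t}" for t in terms}
    return OntologyDAG.from_edges(edges, names=names)


def generate_fixture(seed: int, scale: str = "small") -> FixtureBundle:
    """Deterministic synthetic bundle; see module docstring for its contents."""
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; choose from {sorted(SCALES)}")
    cfg = SCALES[scale]
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(cfg["n_genes"])]

    # ontology + annotations, with one planted enriched leaf term
    dag = _build_dag(rng, cfg["n_terms"])
    direct: dict[str, set[str]] = {}
    for term in sorted(dag.terms):
        if term == dag.root:
            continue
        size = int(rng.integers(cfg["direct_lo"], cfg["direct_hi"] + 1))
        direct[term] = set(rng.choice(genes, size=min(size, len(genes)), replace=False))
    leaves = sorted(t for t in dag.terms if not dag.children(t))
    planted_term = leaves[int(rng.integers(0, len(leaves)))]
    planted_genes = frozenset(
        rng.choice(genes, size=min(cfg["planted_size"], len(genes)), replace=False)
    )
    direct[planted_term] = set(planted_genes)
    # every gene annotated somewhere (leaf level), so the universe is complete
    covered = set().union(*direct.values())
    assignable = sorted(t for t in dag.terms if t != dag.root)
    for g in genes:
        if g not in covered:
            direct[assignable[int(rng.integers(0, len(assignable)))]].add(g)
    ann = propagate(dag, direct)

    # flat pathway collection with one planted redundant pair (B inside A,
    # similar size) and one planted specific-subset pair (D inside broad C)
    flat: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(cfg["n_pathways"]):
        size = int(rng.integers(max(4, cfg["direct_lo"]), max(8, cfg["direct_hi"] * 3)))
        members = frozenset(rng.choice(genes, size=min(size, len(genes)), replace=False))
        flat[f"PW{i + 1:03d}"] = ("synthetic pathway", members)
    a_members = frozenset(rng.choice(genes, size=min(20, len(genes)), replace=False))
    b_members = frozenset(sorted(a_members)[: max(2, int(0.8 * len(a_members)))])
    c_members = frozenset(rng.choice(genes, size=min(40, len(genes)), replace=False))
    d_members = frozenset(sorted(c_members)[: max(2, len(c_members) // 7)])
    flat["PW_A"] = ("broad planted pathway A", a_members)
    flat["PW_B"] = ("planted near-duplicate of A", b_members)
    flat["PW_C"] = ("broad planted pathway C", c_members)
    flat["PW_D"] = ("specific subset of C", d_members)

    # scale-free interaction network with a planted hub module
    net = nx.barabasi_albert_graph(len(genes), 3, seed=int(rng.integers(2**31)))
    net = nx.relabel_nodes(net, {i: genes[i] for i in range(len(genes))})
    for u, v in net.edges:
        net[u][v]["weight"] = round(float(rng.uniform(0.5, 1.0)), 3)
    hub = max(sorted(net.nodes), key=lambda v: net.degree(v))
    module = [hub] + sorted(net.neighbors(hub))[:4]

    # genome: two chromosomes, evenly spaced spans; spacing exceeds the
    # default scoring window so a SNP can score only its own gene
    spacing, glen = cfg["gene_spacing"], cfg["gene_len"]
    half = len(genes) // 2
    gene_models = []
    locus: dict[str, GeneModel] = {}
    for i, g in enumerate(genes):
        chrom = "chr1" if i < half else "chr2"
        start = (i if i < half else i - half) * spacing + 10_000
        gm = GeneModel(g, chrom, start, start + glen)
        gene_models.append(gm)
        locus[g] = gm
    chrom_len = (max(half, len(genes) - half)) * spacing + 50_000
    background = RegionSet.from_intervals(
        [("chr1", 0, chrom_len), ("chr2", 0, chrom_len)]
    )

    # GWAS SNPs: planted genome-wide hits inside the module genes, noise elsewhere
    snps: list[SnpRecord] = []
    ld: list[LdPair] = []
    snp_positions: dict[str, tuple[str, int]] = {}
    idx = 0
    lead_of: dict[str, str] = {}
    for g in module:
        gm = locus[g]
        pos = int(rng.integers(gm.start + 1, gm.end))
        p = 10.0 ** -float(rng.uniform(9, 15))
        idx += 1
        name = f"rs{idx:05d}"
        snps.append(SnpRecord(name, gm.chrom, pos, p))
        snp_positions[name] = (gm.chrom, pos)
        lead_of[g] = name
        proxy = f"rsP{idx:04d}"
        ppos = int(rng.integers(gm.start + 1, gm.end))
        snp_positions[proxy] = (gm.chrom, ppos)
        ld.append(LdPair(name, proxy, round(float(rng.uniform(0.82, 0.98)), 3)))
        weak = f"rsW{idx:04d}"
        snp_positions[weak] = (gm.chrom, ppos)
        ld.append(LdPair(name, weak, round(float(rng.uniform(0.2, 0.7)), 3)))
    while idx < cfg["n_snps"]:
        idx += 1
        name = f"rs{idx:05d}"
        chrom = "chr1" if rng.random() < 0.5 else "chr2"
        pos = int(rng.integers(1, chrom_len))
        p = float(rng.uniform(1e-4, 1.0))
        snps.append(SnpRecord(name, chrom, pos, p))
        snp_positions[name] = (chrom, pos)

    # annotation tracks + input regions that preferentially hit track A
    track_a = RegionSet.from_intervals(
        [("chr1", k * spacing, k * spacing + 5_000) for k in range(0, half, 2)]
    )
    track_b = RegionSet.from_intervals(
        sorted(
            ("chr2", int(s), int(s) + 4_000)
            for s in rng.integers(0, chrom_len - 4_000, size=max(4, half // 3))
        )
    )
    inputs = []
    for _ in range(max(6, half // 4)):
        if rng.random() < 0.7:
            k = int(rng.integers(0, max(1, half // 2))) * 2
            s = k * spacing + int(rng.integers(0, 4_000))
        else:
            s = int(rng.integers(0, chrom_len - 1_000))
        inputs.append(("chr1", s, s + 1_000))
    input_regions = RegionSet.from_intervals(inputs)

    truth = {
        "enriched_term": planted_term,
        "enriched_genes": sorted(planted_genes),
        "module_genes": sorted(module),
        "module_leads": {g: lead_of[g] for g in module},
        "redundant_pair": ("PW_A", "PW_B"),
        "specific_pair": ("PW_C", "PW_D"),
        "enriched_track": "trackA",
        "seed": seed,
        "scale": scale,
    }
    return FixtureBundle(
        dag=dag,
        annotations=ann,
        flat_sets=flat,
        network=net,
        genes=gene_models,
        snps=snps,
        ld=ld,
        snp_positions=snp_positions,
        input_regions=input_regions,
        tracks={"trackA": track_a, "trackB": track_b},
        background=background,
        truth=truth,
    )


def write_fixture(bundle: FixtureBundle, outdir) -> None:
    """Dump the bundle to plain-text files (deterministic, byte-stable)."""
    from . import io as gio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_obo(bundle.dag, out / "ontology.obo")
    gio.write_gmt(
        {t: ("direct annotation", es) for t, es in bundle.annotations.direct.items() if es},
        out / "annotations.gmt",
    )
    gio.write_gmt(bundle.flat_sets, out / "pathways.gmt")
    gio.write_network(bundle.network, out / "network.tsv")
    gio.write_gene_models(bundle.genes, out / "genes.tsv")
    gio.write_snps(bundle.snps, out / "snps.tsv")
    gio.write_ld(bundle.ld, out / "ld.tsv")
    with open(out / "snp_positions.tsv", "w") as fh:
        for snp in sorted(bundle.snp_positions):
            chrom, pos = bundle.snp_positions[snp]
            fh.write(f"{snp}\t{chrom}\t{pos}\n")
    gio.write_bed(bundle.input_regions, out / "input_regions.bed")
    gio.write_bed(bundle.background, out / "background.bed")
    for name, track in bundle.tracks.items():
        gio.write_bed(track, out / f"track_{name}.bed")
    (out / "truth.json").write_text(json.dumps(bundle.truth, indent=2, sort_keys=True) + "\n")


# -- hand-built toy fixtures ---------------------------------------------


def toy_snp_ontology():
    """Four SNPs on a small trait ontology with a graded similarity structure.

    SNP ``s1`` and ``sC`` share the same two direct terms including the very
    informative leaf ``T:1.1.1.1``; ``sA`` is annotated to that leaf's sibling,
    so its most informative shared ancestor with ``s1`` is ``T:1.1.1``; ``sB``
    lives on the other branch and shares only the root.  Three filler SNPs
    spread the annotation frequencies so the ICs are strictly graded.

    Returns ``(dag, ann, expected_order)`` with ``expected_order`` the entity
    ids in decreasing similarity to ``s1``.
    """
    edges = [
        ("T:1.1", "T:1"),
        ("T:1.2", "T:1"),
        ("T:1.1.1", "T:1.1"),
        ("T:1.1.2", "T:1.1"),
        ("T:1.1.1.1", "T:1.1.1"),
        ("T:1.1.1.2", "T:1.1.1"),
        ("T:1.2.1", "T:1.2"),
    ]
    dag = OntologyDAG.from_edges(edges)
    direct = {
        "T:1.1.1.1": {"s1", "sC"},
        "T:1.1.1.2": {"sA"},
        "T:1.1.2": {"s1", "sC", "sA", "e3"},
        "T:1.1.1": {"e1", "e2"},
        "T:1.2.1": {"sB"},
        "T:1.2": {"sB"},
    }
    ann = propagate(dag, direct)
    return dag, ann, ["sC", "sA", "sB"]


def elim_chain_fixture():
    """Three-level chain where the leaf fully explains the parent's overlap.

    Leaf ``A`` is annotated with exactly the five input genes; parent ``B``
    adds two genes of its own; root ``C`` holds the 20-gene universe.  After
    leaf-to-root elimination the parent's overlap must drop to zero.

    Returns ``(dag, ann, input_genes)``.
    """
    genes = [f"g{i}" for i in range(1, 21)]
    dag = OntologyDAG.from_edges([("A", "B"), ("B", "C")])
    direct = {
        "A": set(genes[:5]),
        "B": set(genes[5:7]),
        "C": set(genes),
    }
    ann = propagate(dag, direct)
    return dag, ann, genes[:5]
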