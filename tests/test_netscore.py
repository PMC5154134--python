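"""SNP scoring, LD expansion, gene scoring, and subnetwork extraction."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from genokit.netscore import (
    EmptyResultError,
    GeneModel,
    LdPair,
    ScoredGraph,
    ScoredSnp,
    ScoreParams,
    SnpRecord,
    expand_ld,
    find_subnetwork,
    score_genes,
    score_snp,
    subnet_from_snps,
)


def brute_force_best_subgraph(g, scores):
    """Exhaustive optimum over all connected induced subgraphs."""
    best = -math.inf
    for r in range(1, g.number_of_nodes() + 1):
        for sub in itertools.combinations(g.nodes, r):
            sg = g.subgraph(sub)
            if nx.is_connected(sg):
                best = max(best, sum(scores[v] for v in sub))
    return best


class TestScoreSnp:
    def test_zero_at_threshold(self):
        assert score_snp(5e-8, 1.0) == 0.0

    def test_hand_evaluated_strong_hit(self):
        # log10((1-1e-10)/1e-10) - log10((1-5e-8)/5e-8) ~ 2.699
        assert score_snp(1e-10, 1.0) == pytest.approx(2.69897, abs=1e-4)

    def test_linear_in_r2(self):
        full = score_snp(1e-12, 1.0)
        assert score_snp(1e-12, 0.5) == pytest.approx(full / 2)

    def test_strictly_decreasing_in_p_then_zero(self):
        params = ScoreParams()
        ps = np.logspace(-20, -8, 30)
        scores = [score_snp(p, 1.0, params) for p in ps]
        assert all(a > b for a, b in zip(scores, scores[1:]))
        assert score_snp(1e-4, 1.0, params) == 0.0
        assert score_snp(0.5, 1.0, params) == 0.0

    def test_floor_keeps_score_finite(self):
        assert math.isfinite(score_snp(1e-320, 1.0))

    def test_invalid_p_rejected(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                score_snp(bad, 1.0)


class TestExpandLd:
    LEAD = SnpRecord("rs1", "chr1", 1000, 1e-10)

    def test_empty_ld_returns_leads_only(self):
        out = expand_ld([self.LEAD], [])
        assert [(s.snp, s.r2) for s in out] == [("rs1", 1.0)]

    def test_r2_cutoff_is_strict(self):
        ld = [LdPair("rs1", "p_hi", 0.9), LdPair("rs1", "p_lo", 0.7)]
        pos = {"p_hi": ("chr1", 1100), "p_lo": ("chr1", 1200)}
        out = expand_ld([self.LEAD], ld, pos)
        assert {s.snp for s in out} == {"rs1", "p_hi"}
        proxy = next(s for s in out if s.snp == "p_hi")
        assert proxy.p == self.LEAD.p and proxy.r2 == 0.9

    def test_proxy_tied_to_two_leads_keeps_best(self):
        lead2 = SnpRecord("rs2", "chr1", 5000, 1e-10)
        ld = [LdPair("rs1", "px", 0.85), LdPair("rs2", "px", 0.95)]
        out = expand_ld([self.LEAD, lead2], ld, {"px": ("chr1", 3000)})
        proxy = next(s for s in out if s.snp == "px")
        assert proxy.r2 == 0.95

    def test_positionless_proxy_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped 1 LD prox"):
            out = expand_ld([self.LEAD], [LdPair("rs1", "px", 0.9)], {})
        assert {s.snp for s in out} == {"rs1"}


class TestScoreGenes:
    GENE = GeneModel("G1", "chr1", 10_000, 30_000)

    def test_snp_inside_span_scores_undecayed(self):
        snp = ScoredSnp("rs1", "chr1", 20_000, 1e-10, 1.0)
        got = score_genes([snp], [self.GENE])
        assert got["G1"] == pytest.approx(score_snp(1e-10, 1.0))

    def test_zero_contribution_at_window_edge(self):
        params = ScoreParams(D=5_000, lam=2.0)
        snp = ScoredSnp("rs1", "chr1", 35_000, 1e-10, 1.0)  # d = D exactly
        assert score_genes([snp], [self.GENE], params) == {"G1": 0.0}
        beyond = ScoredSnp("rs1", "chr1", 35_001, 1e-10, 1.0)
        assert score_genes([beyond], [self.GENE], params) == {}

    def test_max_scheme_keeps_most_informative(self):
        params = ScoreParams(D=10_000, lam=1.0)
        inside = ScoredSnp("a", "chr1", 15_000, 10 ** -(7.30103 + 3.0), 1.0)  # score 3
        # score 5 at 60% decay -> contributes 2
        away = ScoredSnp("b", "chr1", 36_000, 10 ** -(7.30103 + 5.0), 1.0)
        got = score_genes([inside, away], [self.GENE], params)
        assert got["G1"] == pytest.approx(3.0, abs=1e-3)

    def test_invariant_under_snp_reordering(self):
        rng = np.random.default_rng(1)
        snps = [
            ScoredSnp(f"rs{i}", "chr1", int(rng.integers(1, 60_000)),
                      float(10 ** -rng.uniform(8, 12)), 1.0)
            for i in range(10)
        ]
        a = score_genes(snps, [self.GENE])
        b = score_genes(list(reversed(snps)), [self.GENE])
        assert a == b

    def test_monotone_in_distance(self):
        params = ScoreParams(D=10_000, lam=2.0)
        scores = [
            score_genes(
                [ScoredSnp("s", "chr1", 30_000 + d, 1e-10, 1.0)], [self.GENE], params
            )["G1"]
            for d in (1_000, 3_000, 6_000, 9_000)
        ]
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestFindSubnetwork:
    def test_star_with_negative_leaves_returns_centre(self):
        g = nx.star_graph(4)
        scores = {0: 5.0, 1: -1.0, 2: -1.0, 3: -1.0, 4: -1.0}
        res = find_subnetwork(ScoredGraph(g, scores))
        assert set(res.graph.nodes) == {0}

    def test_negative_hub_recruited_as_linker(self):
        # two strong genes joined only through a mildly negative hub
        g = nx.Graph([("a", "h"), ("h", "b"), ("h", "c"), ("c", "d")])
        scores = {"a": 3.0, "b": 3.0, "h": -1.0, "c": -5.0, "d": 0.5}
        res = find_subnetwork(ScoredGraph(g, scores))
        assert set(res.graph.nodes) == {"a", "h", "b"}
        assert brute_force_best_subgraph(g, scores) == pytest.approx(5.0)

    def test_matches_exhaustive_on_random_graphs(self):
        rng = np.random.default_rng(8)
        hits = total = 0
        for _ in range(60):
            n = int(rng.integers(4, 11))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
            scores = {v: float(rng.normal(0, 1.5)) for v in g.nodes}
            if not any(s > 0 for s in scores.values()):
                continue
            opt = max(
                brute_force_best_subgraph(g.subgraph(c), scores)
                for c in nx.connected_components(g)
                if any(scores[v] > 0 for v in c)
            )
            res = find_subnetwork(ScoredGraph(g, scores))
            got = sum(res.scores.values())
            assert got <= opt + 1e-9  # heuristic never beats the optimum
            assert nx.is_connected(res.graph)
            total += 1
            hits += math.isclose(got, opt)
        assert hits / total >= 0.9

    def test_output_never_keeps_negative_leaf(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
            scores = {v: float(rng.normal(0, 1)) for v in g.nodes}
            if not any(s > 0 for s in scores.values()):
                continue
            res = find_subnetwork(ScoredGraph(g, scores))
            for v in res.graph.nodes:
                if res.graph.degree(v) <= 1 and res.graph.number_of_nodes() > 1:
                    assert res.scores[v] >= 0

    def test_no_positive_nodes_raises(self):
        g = nx.path_graph(3)
        with pytest.raises(EmptyResultError):
            find_subnetwork(ScoredGraph(g, {v: -1.0 for v in g.nodes}))


class TestSubnetFromSnps:
    def test_planted_module_recovered(self, small_bundle):
        b = small_bundle
        res = subnet_from_snps(
            b.snps, b.ld, b.genes, b.network, snp_positions=b.snp_positions
        )
        assert set(res.graph.nodes) == set(b.truth["module_genes"])

    def test_zero_signal_is_empty_result(self, small_bundle):
        b = small_bundle
        flat = [SnpRecord(s.snp, s.chrom, s.pos, 5e-8) for s in b.snps]
        with pytest.raises(EmptyResultError):
            subnet_from_snps(flat, [], b.genes, b.network)

    def test_target_n_reaches_requested_size(self, small_bundle):
        b = small_bundle
        res = subnet_from_snps(
            b.snps, b.ld, b.genes, b.network,
            snp_positions=b.snp_positions, target_n=5,
        )
        assert res.graph.number_of_nodes() == 5
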