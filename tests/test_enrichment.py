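"""Counting tests, tree-aware elimination, redundancy filter, p adjustment."""

import numpy as np
import pytest
from scipy import stats

from genokit.enrichment import (
    ContingencyCounts,
    EnrichmentRecord,
    adjust_pvalues,
    enrich,
    filter_redundant,
    run_test,
    tree_aware_enrich,
)
from genokit.ontology import OntologyDAG, propagate


def _record(term, p, members):
    counts = ContingencyCounts(N=100, M=len(members), k=20, x=len(members))
    return EnrichmentRecord(
        term=term, name=term, counts=counts, fold_change=1.0, p=p, adj_p=p,
        members=sorted(members),
    )


class TestRunTest:
    def test_zero_overlap_gives_one(self):
        c = ContingencyCounts(N=50, M=10, k=5, x=0)
        assert run_test(c, "fisher") == 1.0
        assert run_test(c, "binomial") == 1.0

    def test_exact_hypergeometric_value(self):
        # all five drawn annotated: C(5,5)C(15,0)/C(20,5) = 1/15504
        c = ContingencyCounts(N=20, M=5, k=5, x=5)
        assert run_test(c, "fisher") == pytest.approx(1 / 15504, rel=1e-10)

    def test_strict_tail_below_inclusive_tail(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            N = int(rng.integers(5, 60))
            M = int(rng.integers(1, N))
            k = int(rng.integers(1, N))
            x = int(rng.integers(1, min(M, k) + 1))
            if stats.hypergeom.pmf(x, N, M, k) <= 0:
                continue
            c = ContingencyCounts(N=N, M=M, k=k, x=x)
            assert run_test(c, "hypergeometric") < run_test(c, "fisher")

    def test_fisher_equals_pointmass_sum(self):
        # brute-force oracle: sum hypergeometric point probabilities x..min(M,k)
        rng = np.random.default_rng(6)
        for _ in range(100):
            N = int(rng.integers(5, 40))
            M = int(rng.integers(1, N))
            k = int(rng.integers(1, N))
            x = int(rng.integers(0, min(M, k) + 1))
            expected = sum(
                stats.hypergeom.pmf(i, N, M, k) for i in range(x, min(M, k) + 1)
            )
            got = run_test(ContingencyCounts(N=N, M=M, k=k, x=x), "fisher")
            assert got == pytest.approx(expected, abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyCounts(N=10, M=12, k=5, x=1)
        with pytest.raises(ValueError):
            run_test(ContingencyCounts(N=10, M=0, k=5, x=0))


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        for method in ("fdr", "fwer"):
            assert adjust_pvalues([0.03], method)[0] == pytest.approx(0.03)

    def test_bh_step_up_by_hand(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03], "fdr"), [0.03, 0.03, 0.03]
        )

    def test_bonferroni_clipped(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.5], "fwer"), [0.02, 1.0])

    def test_fdr_never_above_fwer(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=30)
        assert np.all(adjust_pvalues(p, "fdr") <= adjust_pvalues(p, "fwer") + 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])


class TestEnrich:
    @pytest.fixture()
    def nested(self):
        # 20-gene universe, term B nested in term A
        dag = OntologyDAG.from_edges([("B", "A"), ("A", "R")])
        genes = [f"g{i}" for i in range(20)]
        direct = {"B": set(genes[:4]), "A": set(genes[4:10]), "R": set(genes)}
        return dag, propagate(dag, direct), genes

    def test_perfect_overlap_is_top_hit(self, nested):
        _, ann, genes = nested
        records = enrich(genes[:4], ann, min_size=1)
        assert records[0].term == "B"
        assert records[0].counts.x == 4

    def test_counts_and_p_match_bruteforce(self, nested):
        _, ann, genes = nested
        input_set = set(genes[:6])
        records = enrich(input_set, ann, min_size=1)
        for rec in records:
            members = ann.propagated[rec.term] & input_set
            M = len(ann.propagated[rec.term])
            assert rec.counts == ContingencyCounts(N=20, M=M, k=6, x=len(members))
            expected = sum(
                stats.hypergeom.pmf(i, 20, M, 6) for i in range(len(members), min(M, 6) + 1)
            )
            assert rec.p == pytest.approx(expected, abs=1e-12)
            assert rec.fold_change == pytest.approx((rec.counts.x / 6) / (M / 20))

    def test_empty_effective_input_names_count(self, nested):
        _, ann, _ = nested
        with pytest.raises(ValueError, match="2 entities supplied, 0 matched"):
            enrich(["nope1", "nope2"], ann)

    def test_size_bounds_filter_terms(self, nested):
        _, ann, genes = nested
        records = enrich(genes[:4], ann, min_size=5, max_size=15)
        assert {r.term for r in records} == {"A"}  # B too small, R too big


class TestTreeAwareEnrich:
    def test_parent_fully_claimed_by_significant_child(self, elim_chain):
        dag, ann, input_genes = elim_chain
        records = {r.term: r for r in tree_aware_enrich(input_genes, dag, ann, min_size=1)}
        assert records["A"].p < 0.05
        assert records["B"].counts.x == 0
        assert records["B"].p == 1.0
        assert records["B"].counts.M == 2  # the two genes B adds itself

    def test_no_significant_children_matches_flat(self, small_bundle):
        dag, ann = small_bundle.dag, small_bundle.annotations
        rng = np.random.default_rng(0)
        input_set = list(rng.choice(sorted(ann.universe), size=15, replace=False))
        flat = enrich(input_set, ann, min_size=1)
        tree = tree_aware_enrich(input_set, dag, ann, alpha_elim=1e-300, min_size=1)
        assert {(r.term, r.p, r.counts) for r in flat} == {
            (r.term, r.p, r.counts) for r in tree
        }

    def test_hand_worked_elimination_counts(self):
        # chain R <- M <- L over 10 entities; signal split between L and M
        dag = OntologyDAG.from_edges([("L", "M"), ("M", "R")])
        genes = [f"g{i}" for i in range(10)]
        ann = propagate(
            dag, {"L": set(genes[:3]), "M": set(genes[3:5]), "R": set(genes)}
        )
        records = {
            r.term: r
            for r in tree_aware_enrich(genes[:4], dag, ann, alpha_elim=0.05, min_size=1)
        }
        # L: x=3, M=3, p = 1/C(10,4) choose-wise = hypergeom tail
        assert records["L"].counts.x == 3
        # L significant (p = C(7,1)/C(10,4) ~ 0.033) -> claims g0..g2 from M:
        # M keeps g3,g4 of its own, overlap {g3}
        assert records["M"].counts == ContingencyCounts(N=10, M=2, k=4, x=1)


class TestFilterRedundant:
    def test_three_overlap_scenarios(self):
        pool = [f"m{i}" for i in range(10)]
        a = _record("A", 1e-6, pool)  # most significant, 10 members
        partial = _record("B_partial", 1e-4, pool[:5] + ["x1", "x2", "x3", "x4", "x5"])
        nested_similar = _record("B_nested", 1e-3, pool[:8])
        small_subset = _record("B_small", 1e-2, pool[:3])
        out = {
            r.term: r.flagged_redundant
            for r in filter_redundant([a, partial, nested_similar, small_subset])
        }
        assert out == {
            "A": False,
            "B_partial": False,  # shares only half its members with A
            "B_nested": True,  # inside A and of comparable size
            "B_small": False,  # inside A but far smaller: different granularity
        }

    def test_raising_c1_only_unflags(self):
        rng = np.random.default_rng(9)
        pool = [f"m{i}" for i in range(30)]
        records = []
        for i in range(12):
            size = int(rng.integers(3, 20))
            members = list(rng.choice(pool, size=size, replace=False))
            records.append(_record(f"T{i:02d}", (i + 1) * 1e-4, members))
        flagged_prev = None
        for c1 in (0.5, 0.7, 0.9, 1.01):
            flagged = sum(
                r.flagged_redundant
                for r in filter_redundant([_record(r.term, r.p, r.members) for r in records], c1=c1)
            )
            if flagged_prev is not None:
                assert flagged <= flagged_prev
            flagged_prev = flagged
        assert flagged_prev == 0  # c1 > 1 can never flag

    def test_flagged_records_cannot_absorb_later_ones(self):
        pool = [f"m{i}" for i in range(10)]
        a = _record("A", 1e-6, pool)
        b = _record("B", 1e-5, pool[:8])  # flagged against A
        c = _record("C", 1e-4, pool[:8] + ["y1", "y2"])
        out = {r.term: r.flagged_redundant for r in filter_redundant([a, b, c])}
        # C overlaps B almost fully but B is flagged, so C is judged against A only
        assert out["B"] is True
        assert out["C"] == (8 / 10 > 0.9)  # False: A-overlap fraction too low
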