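import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metahub.enrichment import (GeneSetCollection, bh_adjust, cohen_kappa,
                                enrichment_frequency, fisher_enrich,
                                hypergeom_tail, kappa_group, read_gmt)
from metahub.synthetic_data import SyntheticSpec, gen_gene_set_collection


def exhaustive_tail(k, N, m, n):
    """P(X ≥ k) by direct enumeration of C(m,i)·C(N−m,n−i)/C(N,n)."""
    total = math.comb(N, n)
    return sum(math.comb(m, i) * math.comb(N - m, n - i)
               for i in range(k, min(m, n) + 1)) / total


class TestHypergeomTail:
    def test_perfect_overlap_closed_form(self):
        assert hypergeom_tail(5, 20, 5, 5) == pytest.approx(1 / 15504, rel=1e-9)

    def test_zero_overlap_is_certain(self):
        assert hypergeom_tail(0, 20, 5, 5) == 1.0

    def test_matches_exhaustive_enumeration_small_universes(self):
        for N in range(2, 16):
            for m in range(0, N + 1, 3):
                for n in range(0, N + 1, 2):
                    for k in range(0, min(m, n) + 1):
                        assert hypergeom_tail(k, N, m, n) == pytest.approx(
                            exhaustive_tail(k, N, m, n), abs=1e-12), (k, N, m, n)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_singleton(self):
        assert bh_adjust([1.0]) == [1.0]

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_q_dominates_p_and_is_order_free(self, ps):
        qs = bh_adjust(ps)
        assert all(q >= p - 1e-12 for p, q in zip(ps, qs))
        perm = list(reversed(range(len(ps))))
        qs_perm = bh_adjust([ps[i] for i in perm])
        assert [qs[i] for i in perm] == pytest.approx(qs_perm)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        ps = rng.random(50).tolist()
        ours = bh_adjust(ps)
        theirs = multipletests(ps, method="fdr_bh")[1]
        assert ours == pytest.approx(theirs.tolist())


class TestFisherEnrich:
    def _collection(self):
        universe = {f"G{i}" for i in range(20)}
        terms = {"HIT": ("", {f"G{i}" for i in range(5)}),
                 "MISS": ("", {f"G{i}" for i in range(10, 15)})}
        return GeneSetCollection(terms, universe=universe)

    def test_full_overlap_term_is_most_significant(self):
        recs = fisher_enrich({f"G{i}" for i in range(5)}, self._collection())
        assert recs[0].term == "HIT"
        assert recs[0].p_value == pytest.approx(1 / 15504, rel=1e-9)
        assert recs[0].q_value >= recs[0].p_value

    def test_genes_outside_universe_dropped_empty_query_errors(self):
        coll = self._collection()
        with pytest.raises(ValueError, match="universe"):
            fisher_enrich({"ZZ1", "ZZ2"}, coll)

    def test_planted_terms_significant_decoys_not(self):
        bad_planted, decoy_fp = 0, 0
        n_decoys = 0
        for seed in range(20):
            spec = SyntheticSpec(rng_seed=seed)
            query = {f"G{i:04d}" for i in range(25)}
            terms, truth = gen_gene_set_collection(spec, query)
            coll = GeneSetCollection(
                {t: ("", set(m)) for t, m in terms.items()},
                universe={f"G{i:04d}" for i in range(spec.universe_size)})
            recs = fisher_enrich(query, coll, alpha=0.05)
            sig = {r.term for r in recs if r.significant}
            if not set(truth.planted_terms) <= sig:
                bad_planted += 1
            decoys = set(terms) - set(truth.planted_terms)
            n_decoys += len(decoys)
            decoy_fp += len(sig & decoys)
        assert bad_planted == 0
        assert decoy_fp <= 0.05 * n_decoys

    def test_enrichment_frequency_counts_significant_terms(self):
        recs = fisher_enrich({f"G{i}" for i in range(5)}, self._collection())
        freq = enrichment_frequency(recs, {"G0", "G10"})
        assert freq["G0"] >= 1 and freq["G10"] == 0


class TestKappa:
    def test_identical_memberships_have_kappa_one_single_group(self):
        q = {f"G{i}" for i in range(10)}
        a = {f"G{i}" for i in range(5)}
        assert cohen_kappa(a, set(a), q) == 1.0

    def test_disjoint_halves_negative_kappa(self):
        q = {f"G{i}" for i in range(10)}
        a = {f"G{i}" for i in range(5)}
        b = q - a
        assert cohen_kappa(a, b, q) == pytest.approx(-1.0)

    def test_symmetry(self):
        q = {f"G{i}" for i in range(12)}
        a, b = {"G0", "G1", "G2"}, {"G2", "G3"}
        assert cohen_kappa(a, b, q) == pytest.approx(cohen_kappa(b, a, q))

    def _records_and_collection(self):
        universe = {f"G{i}" for i in range(20)}
        q = {f"G{i}" for i in range(8)}
        terms = {
            "T1": ("", {f"G{i}" for i in range(4)}),
            "T2": ("", {f"G{i}" for i in range(4)} | {"G15"}),  # same query face
            "T3": ("", {f"G{i}" for i in range(4, 8)}),
        }
        coll = GeneSetCollection(terms, universe=universe)
        recs = fisher_enrich(q, coll, alpha=0.9)
        return recs, coll, q

    def test_groups_join_matching_terms_and_split_disjoint(self):
        recs, coll, q = self._records_and_collection()
        groups = kappa_group(recs, coll, q, kappa_threshold=0.4)
        member_sets = sorted(sorted(g.members) for g in groups)
        assert member_sets == [["T1", "T2"], ["T3"]]
        for g in groups:
            assert g.representative in g.members

    def test_threshold_above_one_isolates_every_term(self):
        recs, coll, q = self._records_and_collection()
        groups = kappa_group(recs, coll, q, kappa_threshold=1.01)
        assert all(len(g.members) == 1 for g in groups)

    def test_no_significant_records_errors(self):
        recs, coll, q = self._records_and_collection()
        for r in recs:
            r.significant = False
        with pytest.raises(ValueError):
            kappa_group(recs, coll, q)


class TestGMT:
    def test_round_trip_with_generator(self, tmp_path):
        spec = SyntheticSpec(rng_seed=2)
        query = {f"G{i:04d}" for i in range(20)}
        path = tmp_path / "c.gmt"
        terms, _ = gen_gene_set_collection(spec, query, path)
        coll = read_gmt(path)
        assert {t: sorted(m) for t, (_, m) in coll.terms.items()} == \
               {t: sorted(m) for t, m in terms.items()}

    def test_short_line_errors(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("TERM\tdesc\n")
        with pytest.raises(ValueError):
            read_gmt(p)

    def test_default_universe_is_union_of_terms(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("A\t.\tX\tY\nB\t.\tY\tZ\n")
        assert read_gmt(p).universe == {"X", "Y", "Z"}
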