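"""Concordance statistics: Pearson, running-sum ES, permutation null, FDR."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from tcauc import (
    RankedList,
    enrichment_score,
    fdr_across_sets,
    pearson_r,
    permutation_test,
    rank_genes,
    run_gsea,
)
from tcauc.io import GeneSet, GeneSetCollection
from conftest import make_contrast


def brute_es(genes, scores, members, p):
    """Exhaustive scalar running-sum oracle for the weighted KS statistic."""
    members = set(members)
    n = len(genes)
    n_hit = sum(g in members for g in genes)
    n_r = sum(abs(s) ** p for g, s in zip(genes, scores) if g in members)
    uniform = n_r == 0
    best_max, best_min = -np.inf, np.inf
    p_hit = p_miss = 0.0
    for g, s in zip(genes, scores):
        if g in members:
            p_hit += (1.0 / n_hit) if uniform else abs(s) ** p / n_r
        else:
            p_miss += 1.0 / (n - n_hit)
        dev = p_hit - p_miss
        best_max = max(best_max, dev)
        best_min = min(best_min, dev)
    # positive on (numerical) ties, mirroring the documented tie rule
    return best_max if best_max >= -best_min - 1e-12 else best_min


def random_fixture(rng, n_max=50):
    n = int(rng.integers(4, n_max + 1))
    genes = np.array([f"g{i}" for i in range(n)], dtype=object)
    scores = np.sort(rng.normal(0, 2, n))[::-1]
    k = int(rng.integers(1, n))
    members = list(rng.choice(genes, size=k, replace=False))
    return RankedList(genes=genes, scores=scores), members


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (6, 4, 2), -1.0),
            ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),
        ],
    )
    def test_examples(self, x, y, expected):
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestRankGenes:
    def test_descending_with_lexicographic_ties(self):
        ranked = rank_genes(make_contrast({"a": 1.0, "b": 3.0, "c": -2.0}))
        assert list(ranked.genes) == ["b", "a", "c"]
        tied = rank_genes(make_contrast({"b": 1.0, "a": 1.0}))
        assert list(tied.genes) == ["a", "b"]

    def test_empty_contrast(self):
        assert len(rank_genes(make_contrast({}))) == 0


class TestEnrichmentScore:
    def test_uniform_weight_running_sum(self):
        ranked = RankedList(
            genes=np.array(["g1", "g2", "g3", "g4"], dtype=object),
            scores=np.array([4.0, 3.0, 2.0, 1.0]),
        )
        prof = enrichment_score(ranked, {"g1", "g3"}, weight_p=0.0)
        np.testing.assert_allclose(prof.running, [0.5, 0.0, 0.5, 0.0])
        assert prof.es == pytest.approx(0.5)

    def test_single_member_at_top(self):
        ranked = RankedList(
            genes=np.array(["g1", "g2", "g3"], dtype=object),
            scores=np.array([5.0, 1.0, 0.5]),
        )
        for p in (0.0, 1.0, 2.0):
            assert enrichment_score(ranked, {"g1"}, p).es == pytest.approx(1.0)

    def test_sign_tie_resolves_positive(self):
        ranked = RankedList(
            genes=np.array(["g1", "g2", "g3", "g4"], dtype=object),
            scores=np.array([4.0, 2.0, 1.0, 1.0]),
        )
        prof = enrichment_score(ranked, {"g2", "g3"}, weight_p=1.0)
        np.testing.assert_allclose(prof.running, [-0.5, 1 / 6, 0.5, 0.0])
        assert prof.es == pytest.approx(0.5)  # |max| == |min| -> positive

    def test_profile_ends_at_zero_and_bounded(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            ranked, members = random_fixture(rng)
            prof = enrichment_score(ranked, members)
            assert abs(prof.es) <= 1.0 + 1e-12
            assert prof.running[-1] == pytest.approx(0.0, abs=1e-12)
            assert set(prof.leading_edge) <= set(members)

    @pytest.mark.parametrize("weight_p", [0.0, 1.0, 2.0])
    def test_matches_brute_force_oracle(self, weight_p):
        rng = np.random.default_rng(23)
        for _ in range(100):
            ranked, members = random_fixture(rng)
            got = enrichment_score(ranked, members, weight_p).es
            want = brute_es(ranked.genes, ranked.scores, members, weight_p)
            assert got == pytest.approx(want, abs=1e-12)

    def test_p0_equals_signed_two_sample_ks(self):
        rng = np.random.default_rng(29)
        for _ in range(100):
            ranked, members = random_fixture(rng)
            es = enrichment_score(ranked, members, weight_p=0.0).es
            hit = np.isin(ranked.genes, members)
            ranks = np.arange(len(ranked))
            d_plus = scipy.stats.ks_2samp(
                ranks[hit], ranks[~hit], alternative="greater"
            ).statistic
            d_minus = scipy.stats.ks_2samp(
                ranks[hit], ranks[~hit], alternative="less"
            ).statistic
            want = d_plus if d_plus >= d_minus else -d_minus
            assert es == pytest.approx(want, abs=1e-12)

    def test_reversing_ranking_negates_es(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            ranked, members = random_fixture(rng)
            rev = RankedList(genes=ranked.genes[::-1], scores=ranked.scores[::-1])
            assert enrichment_score(rev, members).es == pytest.approx(
                -enrichment_score(ranked, members).es, abs=1e-12
            )

    def test_degenerate_sets_rejected(self):
        ranked = RankedList(
            genes=np.array(["a", "b"], dtype=object), scores=np.array([1.0, 0.5])
        )
        with pytest.raises(ValueError, match="empty"):
            enrichment_score(ranked, {"zzz"})
        with pytest.raises(ValueError, match="universe"):
            enrichment_score(ranked, {"a", "b"})

    def test_members_outside_universe_warn(self):
        ranked = RankedList(
            genes=np.array(["a", "b", "c"], dtype=object),
            scores=np.array([2.0, 1.0, 0.5]),
        )
        with pytest.warns(UserWarning, match="outside"):
            enrichment_score(ranked, {"a", "zzz"})


class TestPermutationTest:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(37)
        ranked, members = random_fixture(rng)
        r1 = permutation_test(ranked, members, n_perm=50, seed=123)
        r2 = permutation_test(ranked, members, n_perm=50, seed=123)
        assert (r1.es, r1.nes, r1.p_nominal) == (r2.es, r2.nes, r2.p_nominal)
        assert r1.leading_edge == r2.leading_edge
        np.testing.assert_array_equal(r1.null_es, r2.null_es)

    def test_p_respects_add_one_floor_and_formula(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            ranked, members = random_fixture(rng, n_max=30)
            res = permutation_test(ranked, members, n_perm=99, seed=7)
            assert res.p_nominal >= 1 / 100
            null = res.null_es
            same = null[null > 0] if res.es > 0 else null[null < 0]
            if same.size:
                expect = (1 + np.sum(np.abs(same) >= abs(res.es))) / (1 + same.size)
                assert res.p_nominal == pytest.approx(expect)
                assert res.nes == pytest.approx(res.es / np.abs(same).mean())
            else:
                assert res.degenerate and res.p_nominal == 1.0

    def test_extreme_observed_hits_floor(self):
        # set at the very top of a strongly graded ranking: ES ~ 1 beats
        # every same-sign permutation draw
        n = 60
        genes = np.array([f"g{i:02d}" for i in range(n)], dtype=object)
        scores = np.linspace(10, 0.1, n)
        ranked = RankedList(genes=genes, scores=scores)
        res = permutation_test(ranked, set(genes[:2]), n_perm=99, seed=3)
        same = res.null_es[res.null_es > 0]
        assert res.p_nominal == pytest.approx(1 / (1 + same.size))


class TestFdr:
    def test_single_set_beyond_null_gets_zero(self):
        rng = np.random.default_rng(43)
        ranked, _ = random_fixture(rng, n_max=40)
        res = permutation_test(ranked, list(ranked.genes[:3]), n_perm=99, seed=1)
        pooled = np.concatenate([res.null_nes(), [0.1, -0.1]])
        res.nes = 50.0  # beyond everything pooled
        q = fdr_across_sets([res], pooled)
        assert q == [0.0]

    def test_null_median_nes_clips_to_one(self):
        # constructed 100-value pooled null, observed NES deep inside it
        pooled = np.concatenate([np.linspace(0.5, 3.0, 50), -np.linspace(0.5, 3.0, 50)])
        rng = np.random.default_rng(47)
        ranked, members = random_fixture(rng, n_max=40)
        res = permutation_test(ranked, members, n_perm=49, seed=2)
        res.nes = 0.5 if res.nes >= 0 else -0.5  # weakest pooled value
        q = fdr_across_sets([res], pooled)
        # numerator fraction 1.0, denominator 1.0 -> exactly 1 after clipping
        assert q == [1.0]

    def test_identical_results_identical_q_and_monotone(self):
        rng = np.random.default_rng(53)
        ranked, members = random_fixture(rng, n_max=40)
        a = permutation_test(ranked, members, n_perm=99, seed=5, set_name="a")
        b = permutation_test(ranked, members, n_perm=99, seed=5, set_name="b")
        qs = fdr_across_sets([a, b])
        assert qs[0] == qs[1]

    def test_q_monotone_in_abs_nes(self):
        rng = np.random.default_rng(59)
        genes = np.array([f"g{i:03d}" for i in range(120)], dtype=object)
        scores = np.sort(rng.normal(0, 2, 120))[::-1]
        ranked = RankedList(genes=genes, scores=scores)
        results = [
            permutation_test(
                ranked, list(rng.choice(genes, size=10, replace=False)),
                n_perm=99, seed=i, set_name=f"s{i}",
            )
            for i in range(6)
        ]
        fdr_across_sets(results)
        pos = sorted(
            (r for r in results if np.isfinite(r.nes) and r.nes >= 0),
            key=lambda r: -abs(r.nes),
        )
        for prev, nxt in zip(pos, pos[1:]):
            assert prev.fdr_q <= nxt.fdr_q + 1e-12

    def test_empty_pooled_null_rejected(self):
        rng = np.random.default_rng(61)
        ranked, members = random_fixture(rng)
        res = permutation_test(ranked, members, n_perm=9, seed=0)
        with pytest.raises(ValueError, match="empty pooled null"):
            fdr_across_sets([res], np.array([]))


class TestRunGsea:
    def test_batch_is_order_independent(self):
        rng = np.random.default_rng(67)
        contrast = make_contrast(
            {f"g{i:03d}": float(v) for i, v in enumerate(rng.normal(0, 2, 80))}
        )
        s1 = GeneSet("up", "d", [f"g{i:03d}" for i in range(5)])
        s2 = GeneSet("down", "d", [f"g{i:03d}" for i in range(70, 78)])
        r_ab = run_gsea(contrast, GeneSetCollection([s1, s2]), n_perm=50, seed=9)
        r_ba = run_gsea(contrast, GeneSetCollection([s2, s1]), n_perm=50, seed=9)
        by_name = {r.set_name: r for r in r_ba}
        for r in r_ab:
            assert r.p_nominal == by_name[r.set_name].p_nominal
            assert r.nes == pytest.approx(by_name[r.set_name].nes, nan_ok=True)
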