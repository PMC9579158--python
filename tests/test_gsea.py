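"""Enrichment engine: GMT I/O, running-sum statistic, permutation inference."""

import numpy as np
import pandas as pd
import pytest

from dyscore.gsea import (
    GeneSet,
    GeneSetCollection,
    enrichment_score,
    label_permutation_control,
    preranked_gsea,
    read_gmt,
    restrict_and_filter,
    write_gmt,
)


def brute_force_es(ranked: pd.Series, members, weight: float = 1.0):
    """Independent prefix-enumeration oracle for the running-sum statistic."""
    scores = ranked.to_numpy(dtype=float)
    hit = np.array([g in set(members) for g in ranked.index])
    n, nh = len(scores), int(hit.sum())
    nr = np.sum(np.abs(scores[hit]) ** weight)
    running = []
    s = 0.0
    for i in range(n):
        if hit[i]:
            s += abs(scores[i]) ** weight / nr
        else:
            s -= 1.0 / (n - nh)
        running.append(s)
    running = np.array(running)
    best = running[np.argmax(np.abs(running))]
    return best, running


@pytest.fixture
def three_sets(tmp_path):
    coll = GeneSetCollection({
        "S1": GeneSet("S1", "first", ("G1", "G2")),
        "S2": GeneSet("S2", "second", ("G3", "G4", "G5")),
        "S3": GeneSet("S3", "third", ("G1", "G5")),
    })
    return coll, tmp_path


class TestGMT:
    def test_line_parses_name_description_members(self, tmp_path):
        path = tmp_path / "a.gmt"
        path.write_text("S1\tdesc\tG1\tG2\n")
        coll = read_gmt(str(path))
        assert coll["S1"].genes == ("G1", "G2")
        assert coll["S1"].description == "desc"

    def test_write_read_identity(self, three_sets):
        coll, tmp_path = three_sets
        path = tmp_path / "b.gmt"
        write_gmt(coll, str(path))
        back = read_gmt(str(path))
        assert back.names() == coll.names()
        for name in coll.names():
            assert back[name].genes == coll[name].genes

    def test_duplicate_members_deduplicated_with_warning(self, tmp_path, caplog):
        path = tmp_path / "c.gmt"
        path.write_text("S1\tdesc\tG1\tG2\tG1\n")
        import logging
        with caplog.at_level(logging.WARNING):
            coll = read_gmt(str(path))
        assert coll["S1"].genes == ("G1", "G2")
        assert any("duplicate" in r.message for r in caplog.records)

    def test_malformed_line_raises_with_line_number(self, tmp_path):
        path = tmp_path / "d.gmt"
        path.write_text("S1\tdesc\tG1\nonlyname\tdesc\n")
        with pytest.raises(ValueError, match=":2"):
            read_gmt(str(path))

    def test_trailing_blank_fields_dropped(self, tmp_path):
        path = tmp_path / "e.gmt"
        path.write_text("S1\tdesc\tG1\tG2\t\t\n")
        assert read_gmt(str(path))["S1"].genes == ("G1", "G2")


class TestRestrict:
    universe = [f"G{i}" for i in range(1, 101)]

    def test_set_outside_universe_dropped(self):
        coll = GeneSetCollection({"S": GeneSet("S", "", ("X1", "X2"))})
        assert len(restrict_and_filter(coll, self.universe, 1, 100)) == 0

    def test_min_size_boundary(self):
        small = GeneSetCollection({
            "S14": GeneSet("S14", "", tuple(self.universe[:14])),
            "S15": GeneSet("S15", "", tuple(self.universe[:15])),
        })
        kept = restrict_and_filter(small, self.universe, min_size=15, max_size=500)
        assert kept.names() == ["S15"]

    def test_members_intersected_with_universe(self):
        coll = GeneSetCollection({
            "S": GeneSet("S", "", tuple(self.universe[:20]) + ("ABSENT",))
        })
        kept = restrict_and_filter(coll, self.universe, 1, 100)
        assert "ABSENT" not in kept["S"].genes
        assert len(kept["S"].genes) == 20

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            restrict_and_filter(GeneSetCollection({}), [], 1, 10)


class TestEnrichmentScore:
    def test_single_member_at_top_gives_es_one(self):
        ranked = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0],
                           index=["a", "b", "c", "d", "e"])
        es, _, leading = enrichment_score(ranked, ["a"])
        assert es == pytest.approx(1.0)
        assert leading == ["a"]

    def test_set_equal_to_universe_gives_es_one(self):
        ranked = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        es, _, _ = enrichment_score(ranked, ["a", "b", "c"])
        assert es == pytest.approx(1.0)

    def test_matches_brute_force_on_fixed_instance(self):
        ranked = pd.Series(np.arange(10, 0, -1, dtype=float),
                           index=[f"g{i}" for i in range(10)])
        members = ["g0", "g1", "g2"]
        es, running, _ = enrichment_score(ranked, members)
        ref, ref_running = brute_force_es(ranked, members)
        assert es == pytest.approx(ref, abs=1e-12)
        np.testing.assert_allclose(running, ref_running, atol=1e-12)

    def test_matches_brute_force_on_random_instances(self):
        """100 random small instances (universe <= 50, sets <= 20), 1e-12."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = rng.integers(5, 51)
            scores = rng.normal(size=n) * rng.uniform(0.5, 3)
            ranked = pd.Series(np.sort(scores)[::-1],
                               index=[f"g{i}" for i in range(n)])
            m = rng.integers(1, min(21, n))
            members = list(rng.choice(ranked.index.to_numpy(), size=m, replace=False))
            if np.sum(np.abs(ranked.loc[members])) == 0:
                continue
            es, _, _ = enrichment_score(ranked, members)
            ref, _ = brute_force_es(ranked, members)
            assert es == pytest.approx(ref, abs=1e-12)

    def test_invariant_to_positive_rescaling_of_scores(self):
        ranked = pd.Series([9.0, 5.0, 3.0, 1.0, 0.5],
                           index=["a", "b", "c", "d", "e"])
        es1, _, _ = enrichment_score(ranked, ["b", "d"])
        es2, _, _ = enrichment_score(ranked * 7.3, ["b", "d"])
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_reversing_list_negates_es_at_weight_zero(self):
        # magnitude is always preserved; the sign flips except in the exact
        # tie case |max deviation| == |min deviation|, where the sign choice
        # is at the mercy of floating-point cumsum order
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = 30
            ranked = pd.Series(np.sort(rng.normal(size=n))[::-1],
                               index=[f"g{i}" for i in range(n)])
            members = list(rng.choice(ranked.index.to_numpy(), 8, replace=False))
            es_fwd, run_fwd, _ = enrichment_score(ranked, members, weight_exponent=0)
            rev = ranked.iloc[::-1]
            es_rev, _, _ = enrichment_score(rev, members, weight_exponent=0)
            assert abs(es_rev) == pytest.approx(abs(es_fwd), abs=1e-12)
            if abs(run_fwd.max()) - abs(run_fwd.min()) > 1e-9:
                assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    def test_member_outside_universe_raises(self):
        ranked = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError, match="outside"):
            enrichment_score(ranked, ["zz"])

    def test_all_zero_hit_scores_raise(self):
        ranked = pd.Series([1.0, 0.0, 0.0], index=["a", "b", "c"])
        with pytest.raises(ValueError, match="N_R"):
            enrichment_score(ranked, ["b", "c"])


def _planted_ranking(n=2000, top=50, seed=0):
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.uniform(0.01, 0.5, n))[::-1]
    scores[:top] = np.sort(rng.uniform(0.8, 1.0, top))[::-1]
    ranked = pd.Series(scores, index=[f"g{i}" for i in range(n)])
    planted = list(ranked.index[:top])
    return ranked, planted


class TestPrerankedGSEA:
    def test_planted_top_set_is_significant(self):
        ranked, planted = _planted_ranking()
        coll = GeneSetCollection({"planted": GeneSet("planted", "", tuple(planted))})
        res = preranked_gsea(ranked, coll, n_permutations=200, seed=1)
        assert res.loc["planted", "NES"] > 0
        assert res.loc["planted", "FWER_p"] < 0.05

    def test_no_false_positives_on_exchangeable_null(self):
        rng = np.random.default_rng(7)
        ranked = pd.Series(rng.normal(size=1000),
                           index=[f"g{i}" for i in range(1000)])
        sets = {}
        for i in range(20):
            m = int(rng.integers(15, 60))
            members = rng.choice(ranked.index.to_numpy(), m, replace=False)
            sets[f"r{i:02d}"] = GeneSet(f"r{i:02d}", "", tuple(members))
        res = preranked_gsea(ranked, GeneSetCollection(sets),
                             n_permutations=200, seed=2)
        assert int((res["FDR_q"] < 0.01).sum()) == 0

    def test_deterministic_given_seed(self):
        ranked, planted = _planted_ranking(seed=3)
        coll = GeneSetCollection({
            "planted": GeneSet("planted", "", tuple(planted)),
            "rand": GeneSet("rand", "", tuple(ranked.index[100:160])),
        })
        a = preranked_gsea(ranked, coll, n_permutations=100, seed=5)
        b = preranked_gsea(ranked, coll, n_permutations=100, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_result_independent_of_collection_insertion_order(self):
        ranked, planted = _planted_ranking(seed=4)
        s1 = GeneSet("alpha", "", tuple(planted))
        s2 = GeneSet("beta", "", tuple(ranked.index[200:260]))
        a = preranked_gsea(ranked, GeneSetCollection({"alpha": s1, "beta": s2}),
                           n_permutations=100, seed=6)
        b = preranked_gsea(ranked, GeneSetCollection({"beta": s2, "alpha": s1}),
                           n_permutations=100, seed=6)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_permutations_rejected(self):
        ranked, planted = _planted_ranking()
        coll = GeneSetCollection({"p": GeneSet("p", "", tuple(planted))})
        with pytest.raises(ValueError, match="n_permutations"):
            preranked_gsea(ranked, coll, n_permutations=5, seed=0)

    def test_empty_collection_gives_empty_table(self):
        ranked, _ = _planted_ranking()
        res = preranked_gsea(ranked, GeneSetCollection({}), n_permutations=100, seed=0)
        assert len(res) == 0

    def test_leading_edge_within_set_members(self):
        ranked, planted = _planted_ranking(seed=8)
        coll = GeneSetCollection({"p": GeneSet("p", "", tuple(planted))})
        res = preranked_gsea(ranked, coll, n_permutations=100, seed=0)
        assert set(res.loc["p", "leading_edge"]) <= set(planted)


class TestLabelPermutationControl:
    def test_set_sizes_unchanged(self):
        ranked, planted = _planted_ranking(seed=9)
        coll = GeneSetCollection({"p": GeneSet("p", "", tuple(planted))})
        res = label_permutation_control(ranked, coll, seed=1, n_permutations=100)
        assert int(res.loc["p", "size"]) == len(planted)

    def test_same_seed_reproduces_table(self):
        ranked, planted = _planted_ranking(seed=10)
        coll = GeneSetCollection({"p": GeneSet("p", "", tuple(planted))})
        a = label_permutation_control(ranked, coll, seed=2, n_permutations=100)
        b = label_permutation_control(ranked, coll, seed=2, n_permutations=100)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_signal_destroyed_by_shuffling(self):
        ranked, planted = _planted_ranking(seed=11)
        coll = GeneSetCollection({"p": GeneSet("p", "", tuple(planted))})
        res = label_permutation_control(ranked, coll, seed=3, n_permutations=200)
        assert res.loc["p", "FDR_q"] >= 0.01
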