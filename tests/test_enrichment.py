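import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from complexdep import (
    GeneSetCollection,
    SsgseaParams,
    enrichment_score,
    fisher_exact_2x2,
    gsea_preranked,
    overlap_test,
    rank_genes,
    ssgsea_score,
    two_class,
    zscore_across_samples,
)


def es_bruteforce(genes, scores, members, weight=1.0):
    """Independent running-sum oracle: walk the list, track the extremum."""
    n = len(genes)
    hits = [g in members for g in genes]
    n_hit = sum(hits)
    nr = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    run, best = 0.0, 0.0
    for s, h in zip(scores, hits):
        run += (abs(s) ** weight / nr) if h else (-1.0 / (n - n_hit))
        if abs(run) > abs(best):
            best = run
    return best


TOY = {"g1": 4.0, "g2": 2.0, "g3": 1.0, "g4": 1.0}


class TestEnrichmentScore:
    def test_single_top_gene_carries_all_hit_mass(self):
        es, _ = enrichment_score(rank_genes(TOY), {"g1"})
        assert es == pytest.approx(1.0)

    def test_single_bottom_gene(self):
        es, _ = enrichment_score(rank_genes(TOY), {"g4"})
        assert es == pytest.approx(-1.0)

    def test_printed_two_gene_example(self):
        es, running = enrichment_score(rank_genes(TOY), {"g1", "g3"})
        assert es == pytest.approx(0.8)
        np.testing.assert_allclose(running, [0.8, 0.3, 0.5, 0.0], atol=1e-12)

    @pytest.mark.parametrize("weight", [0.0, 1.0, 2.0])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_on_random_lists(self, weight, seed):
        rng = np.random.default_rng(seed)
        n = 12
        genes = [f"g{i:02d}" for i in range(n)]
        scores = np.sort(rng.normal(size=n))[::-1]
        ranked = rank_genes(dict(zip(genes, scores)))
        for size in (1, 2, 3, 4):
            for members in itertools.combinations(genes, size):
                es, _ = enrichment_score(ranked, members, weight=weight)
                ref = es_bruteforce(ranked.genes, ranked.scores, set(members), weight)
                assert es == pytest.approx(ref, abs=1e-12)

    def test_matches_gseapy_weighted_es(self):
        """Independent software cross-check on the same ranked list."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(3)
        genes = [f"g{i:02d}" for i in range(30)]
        scores = np.sort(rng.normal(size=30))[::-1]
        sets = {"A": genes[2:8], "B": genes[20:28], "C": genes[::5]}
        res = gseapy.prerank(
            rnk=pd.DataFrame({"gene": genes, "score": scores}),
            gene_sets=sets, permutation_num=4, min_size=1, max_size=50,
            seed=1, outdir=None, no_plot=True, weight=1.0,
        ).res2d.set_index("Term")
        ranked = rank_genes(dict(zip(genes, scores)))
        for name, members in sets.items():
            es, _ = enrichment_score(ranked, members)
            assert es == pytest.approx(float(res.loc[name, "ES"]), abs=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_negating_scores_negates_es(self, data):
        from hypothesis import assume

        n = data.draw(st.integers(4, 10))
        scores = data.draw(
            st.lists(st.floats(0.1, 50), min_size=n, max_size=n, unique=True)
        )
        signs = data.draw(st.lists(st.sampled_from([-1.0, 1.0]), min_size=n, max_size=n))
        scores = [s * sg for s, sg in zip(scores, signs)]
        size = data.draw(st.integers(1, n - 1))
        genes = [f"g{i}" for i in range(n)]
        members = set(genes[:size])
        es_fwd, running = enrichment_score(rank_genes(dict(zip(genes, scores))), members)
        # a tied extremum (|max| == |min| of the running sum) is resolved by
        # first occurrence and legitimately breaks the antisymmetry
        assume(abs(running.max() + running.min()) > 1e-9)
        es_rev, _ = enrichment_score(
            rank_genes({g: -s for g, s in zip(genes, scores)}), members
        )
        assert es_rev == pytest.approx(-es_fwd, abs=1e-9)


class TestRankGenes:
    def test_descending_with_lexicographic_ties(self):
        rl = rank_genes({"A": 2.0, "B": 3.0})
        assert rl.genes == ("B", "A")
        rl = rank_genes({"B": 1.0, "A": 1.0})
        assert rl.genes == ("A", "B")

    def test_nan_excluded_and_counted(self):
        rl = rank_genes({"A": 1.0, "B": 2.0, "C": np.nan})
        assert len(rl) == 2 and rl.n_excluded == 1


class TestGseaPreranked:
    def _exact_null(self, ranked, size, weight=1.0):
        return np.array([
            enrichment_score(ranked, m, weight)[0]
            for m in itertools.combinations(ranked.genes, size)
        ])

    def test_nominal_p_converges_to_exhaustive_enumeration(self):
        genes = [f"g{i}" for i in range(6)]
        scores = [5.0, 3.0, 2.0, 1.5, 1.0, 0.5]
        ranked = rank_genes(dict(zip(genes, scores)))
        members = ("g0", "g2")
        coll = GeneSetCollection.from_dict({"S": list(members)})
        es_obs, _ = enrichment_score(ranked, members)
        null = self._exact_null(ranked, 2)
        same = null[null >= 0] if es_obs >= 0 else null[null < 0]
        p_exact = np.mean(np.abs(same) >= abs(es_obs))
        n_perm = 10_000
        res = gsea_preranked(ranked, coll, n_perm=n_perm, seed=17)[0]
        m_eff = n_perm * (same.size / null.size)
        se = np.sqrt(p_exact * (1 - p_exact) / m_eff)
        assert abs(res.p - p_exact) <= 3 * se + 1e-9

    def test_nes_normalizes_by_same_sign_mean(self):
        genes = [f"g{i}" for i in range(8)]
        scores = np.linspace(4, 0.5, 8)
        ranked = rank_genes(dict(zip(genes, scores)))
        coll = GeneSetCollection.from_dict({"S": ["g0", "g1"]})
        res = gsea_preranked(ranked, coll, n_perm=2000, seed=5)[0]
        assert np.sign(res.nes) == np.sign(res.es)
        assert abs(res.nes) > abs(res.es)  # mean |null ES| < 1

    def test_size_filters_reported_as_skipped(self):
        ranked = rank_genes(TOY)
        coll = GeneSetCollection.from_dict({"big": ["g1", "g2", "g3"], "ok": ["g1"]})
        res = gsea_preranked(ranked, coll, n_perm=50, max_size=2, seed=0)
        by_name = {r.name: r for r in res}
        assert by_name["big"].skipped is not None
        assert by_name["ok"].skipped is None

    def test_set_equal_to_universe_rejected(self):
        ranked = rank_genes(TOY)
        coll = GeneSetCollection.from_dict({"all": list(TOY)})
        with pytest.raises(ValueError, match="universe"):
            gsea_preranked(ranked, coll, n_perm=10, seed=0)

    def test_seed_reproducibility(self):
        ranked = rank_genes({f"g{i}": float(10 - i) for i in range(10)})
        coll = GeneSetCollection.from_dict({"S": ["g0", "g3", "g7"]})
        a = gsea_preranked(ranked, coll, n_perm=200, seed=9)[0]
        b = gsea_preranked(ranked, coll, n_perm=200, seed=9)[0]
        assert (a.es, a.nes, a.p, a.fdr) == (b.es, b.nes, b.p, b.fdr)

    def test_leading_edge_contains_top_members_for_positive_es(self):
        ranked = rank_genes({f"g{i}": float(20 - i) for i in range(20)})
        coll = GeneSetCollection.from_dict({"S": ["g0", "g1", "g15"]})
        res = gsea_preranked(ranked, coll, n_perm=50, seed=0)[0]
        assert "g0" in res.leading_edge and "g1" in res.leading_edge

    def test_end_to_end_recovery_of_embedded_complex(self, embedded_bundle):
        sub = embedded_bundle.annotations["subgroup"]
        res = two_class(
            embedded_bundle.dependency, list(sub[sub].index), list(sub[~sub].index)
        )
        ranked = rank_genes(res["t"])
        enr = gsea_preranked(ranked, embedded_bundle.genesets, n_perm=300, seed=1)
        scored = [r for r in enr if not r.skipped]
        best = max(scored, key=lambda r: abs(r.nes))
        assert best.name == "TARGET_COMPLEX"
        assert best.nes < 0  # selective depletion sits at the bottom of the list


class TestSsgsea:
    def test_direct_summation_oracle(self):
        # 5 genes, values 5..1 (so bottom-rank weights are 5..1), set {a, c}
        vals = {"a": 5.0, "b": 4.0, "c": 3.0, "d": 2.0, "e": 1.0}
        alpha = 0.25
        m = pd.DataFrame({"s": vals})
        coll = GeneSetCollection.from_dict({"S": ["a", "c"]})
        got = ssgsea_score(m, coll, SsgseaParams(alpha=alpha, normalize=False)).loc["S", "s"]
        w = {g: v ** alpha for g, v in vals.items()}  # rank from bottom == value here
        wr = w["a"] + w["c"]
        cum_in = np.cumsum([w["a"] / wr, 0, w["c"] / wr, 0, 0])
        cum_out = np.cumsum([0, 1 / 3, 0, 1 / 3, 1 / 3])
        assert got == pytest.approx(float(np.sum(cum_in - cum_out)), abs=1e-12)

    def test_identical_samples_identical_scores(self):
        m = pd.DataFrame({"s1": [3.0, 2.0, 1.0], "s2": [3.0, 2.0, 1.0]},
                         index=["a", "b", "c"])
        coll = GeneSetCollection.from_dict({"S": ["a"]})
        sc = ssgsea_score(m, coll, SsgseaParams(normalize=False))
        assert sc.loc["S", "s1"] == sc.loc["S", "s2"]

    def test_top_gene_set_is_maximal_among_singletons_at_alpha_zero(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(8)]
        m = pd.DataFrame({"s": rng.normal(size=8)}, index=genes)
        coll = GeneSetCollection.from_dict({g: [g] for g in genes})
        sc = ssgsea_score(m, coll, SsgseaParams(alpha=0.0, normalize=False))["s"]
        top_gene = m["s"].idxmax()
        assert sc.idxmax() == top_gene

    def test_missing_set_members_yield_nan(self):
        m = pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"])
        coll = GeneSetCollection.from_dict({"S": ["zz"]})
        assert np.isnan(ssgsea_score(m, coll).loc["S", "s"])

    def test_range_normalization_divides_by_global_span(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(10, 3)),
                         index=[f"g{i}" for i in range(10)],
                         columns=list("xyz"))
        coll = GeneSetCollection.from_dict({"A": ["g0", "g1"], "B": ["g5"]})
        raw = ssgsea_score(m, coll, SsgseaParams(normalize=False))
        norm = ssgsea_score(m, coll, SsgseaParams(normalize=True))
        span = np.nanmax(raw.to_numpy()) - np.nanmin(raw.to_numpy())
        pd.testing.assert_frame_equal(norm, raw / span)


class TestZscore:
    def test_hand_computed_sample_sd(self):
        sc = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [3.0]}, index=["S"])
        z = zscore_across_samples(sc)
        np.testing.assert_allclose(z.loc["S"], [-1.0, 0.0, 1.0])

    def test_output_standardized_per_set(self):
        rng = np.random.default_rng(6)
        sc = pd.DataFrame(rng.normal(size=(4, 20)),
                          index=list("ABCD"), columns=[f"s{i}" for i in range(20)])
        z = zscore_across_samples(sc)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_scores_warn_and_zero(self):
        sc = pd.DataFrame({"s1": [2.0], "s2": [2.0]}, index=["S"])
        with pytest.warns(RuntimeWarning):
            z = zscore_across_samples(sc)
        assert (z.loc["S"] == 0).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            zscore_across_samples(pd.DataFrame({"s1": [1.0]}, index=["S"]))


class TestOverlapTests:
    def test_fisher_five_by_five_diagonal(self):
        assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / 252)

    def test_fisher_rejects_negative_entries(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(1, -1, 0, 2)

    def test_hypergeometric_full_overlap_is_certain(self):
        universe = {f"g{i}" for i in range(10)}
        k, p = overlap_test(universe, universe, universe)
        assert k == 10 and p == pytest.approx(1.0)

    def test_disjoint_overlap_upper_tail_is_one(self):
        universe = [f"g{i}" for i in range(100)]
        k, p = overlap_test(universe[:5], universe[5:10], universe)
        assert k == 0 and p == pytest.approx(1.0)

    def test_hypergeometric_against_direct_enumeration(self):
        # P(X >= 3) drawing 5 from universe 20 with 6 marked
        from scipy.special import comb
        exact = sum(
            comb(6, k, exact=True) * comb(14, 5 - k, exact=True) for k in (3, 4, 5)
        ) / comb(20, 5, exact=True)
        universe = [f"g{i}" for i in range(20)]
        hits = universe[:5]
        marked = universe[2:8]  # overlap with hits = {g2,g3,g4} = 3
        k, p = overlap_test(hits, marked, universe)
        assert k == 3 and p == pytest.approx(float(exact), rel=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_test([], [], [])
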