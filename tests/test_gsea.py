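"""Enrichment scores against hand walks, exhaustive enumeration, and gseapy."""

import itertools

import numpy as np
import pandas as pd
import pytest

from neurogwas import (
    GeneSetCollection,
    ValidationError,
    enrichment_score,
    normalize_and_fdr,
    permutation_null,
    rank_genes,
    run_gsea,
)
from neurogwas.gsea import RankedGeneList


def ranked4():
    return RankedGeneList(
        np.array(["a", "b", "c", "d"], dtype=object),
        np.array([4.0, 3.0, 2.0, 1.0]),
    )


def exhaustive_null(n, set_size):
    """Enumerate ES over all hit-position subsets (exact permutation null)."""
    genes = np.array([f"g{i}" for i in range(n)], dtype=object)
    ranked = RankedGeneList(genes, np.arange(n, 0, -1, dtype=float))
    out = []
    for positions in itertools.combinations(range(n), set_size):
        es, _ = enrichment_score(ranked, [genes[i] for i in positions])
        out.append(es)
    return np.array(out)


class TestRankGenes:
    def test_sorted_input_unchanged(self):
        df = pd.DataFrame({"gene": ["a", "b"], "score": [2.0, 1.0]})
        r = rank_genes(df)
        assert list(r.genes) == ["a", "b"]

    def test_ties_break_lexicographically(self):
        df = pd.DataFrame({"gene": ["z", "m", "a"], "score": [1.0, 1.0, 1.0]})
        assert list(rank_genes(df).genes) == ["a", "m", "z"]

    def test_shuffle_then_rank_is_idempotent(self, rng):
        df = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(30)], "score": rng.random(30)}
        )
        shuffled = df.sample(frac=1, random_state=3)
        assert list(rank_genes(df).genes) == list(rank_genes(shuffled).genes)

    def test_duplicate_genes_rejected(self):
        df = pd.DataFrame({"gene": ["a", "a"], "score": [2.0, 1.0]})
        with pytest.raises(ValidationError):
            rank_genes(df)


class TestEnrichmentScore:
    @pytest.mark.parametrize(
        "members,expected",
        [
            (["a"], 1.0),        # single hit at the top
            (["d"], -1.0),       # hand walk -1/3, -2/3, -1, 0
            (["b"], 2.0 / 3.0),  # hand walk -1/3, +2/3, +1/3, 0
        ],
    )
    def test_hand_walks_on_four_genes(self, members, expected):
        es, _ = enrichment_score(ranked4(), members)
        assert es == pytest.approx(expected)

    def test_trace_returns_to_zero(self, rng):
        genes = np.array([f"g{i}" for i in range(40)], dtype=object)
        ranked = RankedGeneList(genes, np.sort(rng.random(40))[::-1])
        members = list(rng.choice(genes, 7, replace=False))
        _, trace = enrichment_score(ranked, members)
        assert abs(trace[-1]) < 1e-12

    def test_unweighted_es_depends_only_on_ranks(self, rng):
        genes = np.array([f"g{i}" for i in range(25)], dtype=object)
        scores = np.sort(rng.random(25))[::-1]
        members = list(rng.choice(genes, 5, replace=False))
        es1, _ = enrichment_score(RankedGeneList(genes, scores), members)
        # strictly monotone transform preserves the ranking
        es2, _ = enrichment_score(RankedGeneList(genes, np.exp(scores)), members)
        assert es1 == pytest.approx(es2, abs=1e-14)

    def test_degenerate_overlap_rejected(self):
        with pytest.raises(ValidationError):
            enrichment_score(ranked4(), ["x", "y"])
        with pytest.raises(ValidationError):
            enrichment_score(ranked4(), ["a", "b", "c", "d"])

    def test_matches_gseapy_unweighted(self, rng):
        gseapy = pytest.importorskip("gseapy")
        genes = [f"g{i}" for i in range(60)]
        scores = np.sort(rng.random(60))[::-1]
        members = [genes[i] for i in rng.choice(60, 8, replace=False)]
        res = gseapy.prerank(
            rnk=pd.DataFrame({"gene": genes, "score": scores}),
            gene_sets={"S": members},
            permutation_num=4,
            weight=0,
            min_size=1,
            max_size=60,
            seed=1,
            outdir=None,
            no_plot=True,
        )
        ours, _ = enrichment_score(
            RankedGeneList(np.array(genes, dtype=object), scores), members
        )
        assert ours == pytest.approx(float(res.res2d["ES"].iloc[0]), abs=1e-9)


class TestPermutationNull:
    def test_identity_permutation_reproduces_observed(self):
        ranked = ranked4()
        null = permutation_null(ranked, {"s": ["b"]}, n_perm=1, identity=True)
        es, _ = enrichment_score(ranked, ["b"])
        assert null["s"][0] == pytest.approx(es)

    def test_four_placement_null_multiset(self):
        # exact null of a single-gene set on N=4 is {1, 2/3, -2/3, -1}
        exact = sorted(exhaustive_null(4, 1))
        assert np.allclose(exact, [-1.0, -2.0 / 3.0, 2.0 / 3.0, 1.0])
        null = permutation_null(ranked4(), {"s": ["a"]}, n_perm=4000, seed=0)
        values, counts = np.unique(np.round(null["s"], 9), return_counts=True)
        assert np.allclose(values, exact)
        se = 3 * np.sqrt(0.25 * 0.75 * 4000)
        assert np.all(np.abs(counts - 1000) < se)

    def test_null_mean_near_zero(self, rng):
        genes = np.array([f"g{i}" for i in range(50)], dtype=object)
        ranked = RankedGeneList(genes, np.sort(rng.random(50))[::-1])
        members = list(rng.choice(genes, 6, replace=False))
        null = permutation_null(ranked, {"s": members}, n_perm=10_000, seed=5)
        sd = null["s"].std()
        assert abs(null["s"].mean()) < 3 * sd / np.sqrt(10_000)

    def test_reproducible_under_seed(self):
        ranked = ranked4()
        a = permutation_null(ranked, {"s": ["a", "c"]}, n_perm=500, seed=9)
        b = permutation_null(ranked, {"s": ["a", "c"]}, n_perm=500, seed=9)
        assert np.array_equal(a["s"], b["s"])


class TestNormalizeAndFdr:
    def test_nes_from_positive_null_mean(self):
        res = normalize_and_fdr({"s": 1.0}, {"s": np.array([1.0, 2 / 3, -2 / 3, -1.0])})
        assert res.loc[0, "nes"] == pytest.approx(1.2)  # 1 / (5/6)
        assert res.loc[0, "p_perm"] == pytest.approx(0.4)  # (1+1)/(1+4)

    def test_negative_es_reported_without_nes_or_fdr(self):
        res = normalize_and_fdr(
            {"s": -0.8}, {"s": np.array([0.5, -0.5, -0.9, 0.2])}
        )
        assert np.isnan(res.loc[0, "nes"]) and np.isnan(res.loc[0, "fdr"])
        assert 0 < res.loc[0, "p_perm"] <= 1

    def test_all_nonpositive_observed_gives_no_fdr_and_no_error(self):
        res = normalize_and_fdr(
            {"s1": -0.5, "s2": -0.1},
            {"s1": np.array([0.3, -0.3]), "s2": np.array([0.2, -0.6])},
        )
        assert res["fdr"].isna().all()


class TestRunGsea:
    def test_planted_top_set_attains_best_fdr(self, rng):
        genes = [f"g{i:04d}" for i in range(300)]
        scores = pd.DataFrame({"gene": genes, "score": rng.random(300)})
        top = scores.sort_values("score", ascending=False)["gene"].head(12).tolist()
        sets = {"PLANTED": top}
        for s in range(40):
            sets[f"D{s}"] = list(rng.choice(genes, 15, replace=False))
        res = run_gsea(
            scores, GeneSetCollection(sets), n_perm=500, seed=1, min_size=5
        )
        assert res.iloc[0]["set"] == "PLANTED"
        assert res.iloc[0]["fdr"] < 0.05

    def test_deterministic_under_seed(self, rng):
        genes = [f"g{i}" for i in range(80)]
        scores = pd.DataFrame({"gene": genes, "score": rng.random(80)})
        sets = GeneSetCollection(
            {f"S{i}": list(rng.choice(genes, 12, replace=False)) for i in range(5)}
        )
        a = run_gsea(scores, sets, n_perm=300, seed=4)
        b = run_gsea(scores, sets, n_perm=300, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_out_of_universe_genes_dropped(self, rng):
        genes = [f"g{i}" for i in range(50)]
        scores = pd.DataFrame({"gene": genes, "score": rng.random(50)})
        sets = GeneSetCollection({"S": genes[:10] + ["missing1", "missing2"]})
        res = run_gsea(scores, sets, n_perm=100, seed=0, min_size=2)
        assert res.loc[0, "size"] == 10


class TestPerSetFdr:
    def test_per_set_mode_uses_own_null_only(self):
        obs = {"s1": 0.9, "s2": 0.5}
        nulls = {
            "s1": np.array([0.9, 0.3, -0.3, -0.9]),
            "s2": np.array([0.6, 0.6, -0.6, -0.2]),
        }
        pooled = normalize_and_fdr(obs, nulls, pool=True).set_index("set")
        per_set = normalize_and_fdr(obs, nulls, pool=False).set_index("set")
        # s1 own positive null NES: {1.5, 0.5}; NES_obs = 0.9/0.6 = 1.5
        assert per_set.loc["s1", "fdr"] == pytest.approx(0.5)
        # pooled reference additionally includes s2's null NESs {1,1}
        assert pooled.loc["s1", "fdr"] == pytest.approx(1 / 4)
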