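"""Rankings, preranked running-sum enrichment, Top 20+ single-feature
screens, BH/Fisher corrections, granularity traces, essentiality split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import morphoscreen as ms
from morphoscreen.enrichment import enrichment_score, fisher_enrichment
from morphoscreen.synthetic import ScreenConfig, generate_screen


class TestRankBySignal:
    def test_descending_order(self):
        ht = pd.DataFrame({"signal_score": [10.0, 3.0, 0.0]}, index=["A", "B", "C"])
        assert list(ms.rank_by_signal(ht).index) == ["A", "B", "C"]

    def test_ties_broken_lexicographically(self):
        ht = pd.DataFrame({"signal_score": [1.0, 1.0, 1.0]}, index=["C", "A", "B"])
        assert list(ms.rank_by_signal(ht).index) == ["A", "B", "C"]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)]
        scores = rng.uniform(0, 100, size=50)
        ht = pd.DataFrame({"signal_score": scores}, index=genes)
        ranked = ms.rank_by_signal(ht)
        expected = [g for _, g in sorted(zip(-scores, genes))]
        assert list(ranked.index) == expected


@pytest.fixture(scope="module")
def profiles():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(20, 12))
    X[5] = -X[0]  # exact anti-profile of g0
    return pd.DataFrame(
        X, index=[f"g{i}" for i in range(20)], columns=[f"f{j}" for j in range(12)]
    )


class TestRankBySimilarity:

    def test_query_ranks_first_with_similarity_one(self, profiles):
        ranked = ms.rank_by_similarity(profiles, "g0")
        assert ranked.index[0] == "g0"
        assert ranked["value"].iloc[0] == pytest.approx(1.0)

    def test_negated_profile_ranks_last(self, profiles):
        ranked = ms.rank_by_similarity(profiles, "g0")
        assert ranked.index[-1] == "g5"
        assert ranked["value"].iloc[-1] == pytest.approx(-1.0)

    def test_matches_dot_product_oracle(self, profiles):
        ranked = ms.rank_by_similarity(profiles, "g3")
        q = profiles.loc["g3"].to_numpy()
        for g in profiles.index:
            x = profiles.loc[g].to_numpy()
            expected = x @ q / (np.linalg.norm(x) * np.linalg.norm(q))
            assert ranked.loc[g, "value"] == pytest.approx(expected, abs=1e-12)

    def test_zero_norm_profile_placed_last(self, profiles):
        prof = profiles.copy()
        prof.loc["g7"] = 0.0
        with pytest.warns(UserWarning):
            ranked = ms.rank_by_similarity(prof, "g0")
        assert ranked.index[-1] == "g7"
        assert ranked["degenerate"]["g7"]


def _es_oracle(genes, values, gene_set, weight=1.0):
    """Independent O(n) running-sum computation."""
    hits = [g in gene_set for g in genes]
    nh = sum(hits)
    total_w = sum(abs(v) ** weight for g, v, h in zip(genes, values, hits) if h)
    run, best = 0.0, 0.0
    for g, v, h in zip(genes, values, hits):
        if h:
            run += abs(v) ** weight / total_w
        else:
            run -= 1 / (len(genes) - nh)
        if abs(run) > abs(best):
            best = run
    return best


@pytest.fixture(scope="module")
def ranked():
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(60)]
    values = np.sort(rng.uniform(0, 50, size=60))[::-1]
    return genes, values


class TestEnrichmentScore:

    def test_top_ranked_set_scores_positive_and_matches_oracle(self, ranked):
        genes, values = ranked
        gs = set(genes[:6])
        es, _ = enrichment_score(genes, values, gs)
        assert es > 0
        assert es == pytest.approx(_es_oracle(genes, values, gs), abs=1e-12)

    def test_random_sets_match_oracle(self, ranked):
        genes, values = ranked
        rng = np.random.default_rng(3)
        for _ in range(20):
            gs = set(rng.choice(genes, size=8, replace=False))
            es, _ = enrichment_score(genes, values, gs)
            assert es == pytest.approx(_es_oracle(genes, values, gs), abs=1e-12)

    def test_universe_set_scores_zero(self, ranked):
        genes, values = ranked
        es, _ = enrichment_score(genes, values, set(genes))
        assert es == 0.0

    def test_rank_reversal_negates_es(self, ranked):
        genes, values = ranked
        rng = np.random.default_rng(4)
        for _ in range(10):
            gs = set(rng.choice(genes, size=7, replace=False))
            es_fwd, _ = enrichment_score(genes, values, gs)
            es_rev, _ = enrichment_score(genes[::-1], values[::-1], gs)
            assert es_rev == pytest.approx(-es_fwd, abs=1e-9)


class TestPrerankedEnrichment:
    def test_top_set_significant_uniform_set_not(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(80)]
        ht = pd.DataFrame(
            {"signal_score": np.sort(rng.uniform(0, 100, 80))[::-1]}, index=genes
        )
        ranked = ms.rank_by_signal(ht)
        sets = {
            "top": list(ranked.index[:8]),
            "uniform": list(ranked.index[::10]),
        }
        res = ms.preranked_enrichment(ranked, sets, n_perm=500, seed=0).set_index(
            "gene_set"
        )
        assert res.loc["top", "es"] > 0
        assert res.loc["top", "pvalue"] < 0.05

    def test_uniformly_placed_set_rarely_significant(self):
        """Calibration: a set spread evenly through the ranking is
        non-significant in at least 9 of 10 seeded rankings."""
        calm = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(50)]
            ht = pd.DataFrame(
                {"signal_score": np.sort(rng.uniform(0, 100, 50))[::-1]}, index=genes
            )
            ranked = ms.rank_by_signal(ht)
            sets = {"uniform": list(ranked.index[2::10])}
            res = ms.preranked_enrichment(ranked, sets, n_perm=200, seed=seed)
            if res["pvalue"].iloc[0] > 0.05:
                calm += 1
        assert calm >= 9

    def test_q_values_consistent_with_bh(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(60)]
        ht = pd.DataFrame(
            {"signal_score": np.sort(rng.uniform(0, 100, 60))[::-1]}, index=genes
        )
        ranked = ms.rank_by_signal(ht)
        sets = {f"s{k}": list(rng.choice(genes, size=6, replace=False)) for k in range(5)}
        res = ms.preranked_enrichment(ranked, sets, n_perm=100, seed=1)
        np.testing.assert_allclose(
            res["qvalue"], ms.bh_adjust(res["pvalue"]), atol=1e-12
        )


class TestTop20Plus:
    def test_distinct_pvalues_give_exactly_twenty(self):
        rng = np.random.default_rng(7)
        p = pd.Series(rng.permutation(np.linspace(0.01, 0.9, 25)),
                      index=[f"g{i}" for i in range(25)])
        assert len(ms.top20plus(p)) == 20

    def test_ties_at_cutoff_included(self):
        vals = list(np.linspace(0.001, 0.018, 18)) + [0.02] * 4 + [0.5, 0.6, 0.7]
        p = pd.Series(vals, index=[f"g{i}" for i in range(25)])
        assert len(ms.top20plus(p)) == 22

    def test_small_universe_returned_whole(self):
        p = pd.Series(np.linspace(0.1, 0.9, 15), index=[f"g{i}" for i in range(15)])
        assert len(ms.top20plus(p)) == 15

    def test_removing_gene_below_cutoff_leaves_list_unchanged(self):
        rng = np.random.default_rng(8)
        p = pd.Series(rng.uniform(0, 1, size=40), index=[f"g{i}" for i in range(40)])
        full = ms.top20plus(p)
        outsider = [g for g in p.index if g not in set(full)][0]
        reduced = ms.top20plus(p.drop(outsider))
        assert full == reduced


class TestFisherScreen:
    def test_perfect_overlap_matches_hypergeometric_oracle(self):
        universe = [f"g{i}" for i in range(20)]
        gene_list = universe[:10]
        p = fisher_enrichment(gene_list, universe[:10], universe)
        expected = stats.hypergeom.sf(9, 20, 10, 10)  # P(X >= 10)
        assert p == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(1 / 184756, rel=1e-9)

    def test_disjoint_term_close_to_one(self):
        universe = [f"g{i}" for i in range(50)]
        p = fisher_enrichment(universe[:10], universe[45:], universe)
        assert p > 0.5

    def test_compartment_confined_effects_enrich_matching_term(self):
        """Effect genes confined to the Mito channel with a matching term
        set: the term is enriched for at least one Mito feature and no DNA
        feature, in a majority of seeds."""
        wins = 0
        n_seeds = 5
        for seed in range(n_seeds):
            cfg = ScreenConfig(
                n_genes=120,
                n_nontargeting=60,
                cells_per_guide_per_plate=8,
                n_features=150,
                compartment_specificity=1.0,
                cutting_effect_size=0.0,
                seed=100 + seed,
            )
            cells, feats, _, truth = generate_screen(cfg)
            res = ms.profile_pipeline(cells)
            pv = ms.pvalue_matrix(res["guide_screen"], res["features"])
            mito_genes = [
                g
                for g, r in truth.genes.iterrows()
                if r["is_effect"] and r["effect_channel"] == "Mito"
            ]
            if len(mito_genes) < 3:
                n_seeds -= 1
                continue
            meta = feats.loc[[f for f in pv.columns if f in feats.index]]
            mito_feats = [f for f in pv.columns if meta.loc[f, "channel"] == "Mito"]
            dna_feats = [f for f in pv.columns if meta.loc[f, "channel"] == "DNA"]
            tops = {f: ms.top20plus(pv[f]) for f in mito_feats + dna_feats}
            res_enr = ms.feature_screen_enrichment(
                tops,
                {"mito_pathway": mito_genes},
                universe=list(pv.index),
                family_bonferroni=False,
            )
            by_feat = res_enr.set_index("feature")
            mito_hit = any(by_feat.loc[f, "qvalue"] < 0.05 for f in mito_feats)
            dna_hit = any(by_feat.loc[f, "qvalue"] < 0.05 for f in dna_feats)
            if mito_hit and not dna_hit:
                wins += 1
        assert wins > n_seeds / 2

    def test_family_bonferroni_more_conservative(self):
        universe = [f"g{i}" for i in range(40)]
        tops = {"f1": universe[:10], "f2": universe[5:15]}
        res = ms.feature_screen_enrichment(
            tops, {"t": universe[:12]}, universe, family_bonferroni=True
        )
        assert (res["bonferroni_p"] >= res["pvalue"]).all()


class TestBH:
    @staticmethod
    def _bh_oracle(p):
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        prev = 1.0
        for rank_from_top in range(n, 0, -1):
            i = order[rank_from_top - 1]
            val = min(prev, p[i] * n / rank_from_top)
            adj[i] = val
            prev = val
        return adj

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=1e-12, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_matches_step_up_oracle(self, p):
        p = np.asarray(p)
        np.testing.assert_allclose(ms.bh_adjust(p), self._bh_oracle(p), atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=30)
        adj = ms.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


@pytest.fixture(scope="module")
def meta():
    rows = []
    for i in range(1, 5):
        rows.append((f"Granularity_WGA_{i}", "Granularity", "WGA", None, i))
    rows.append(("Intensity_DNA_9", "Intensity", "DNA", None, None))
    return pd.DataFrame(
        rows,
        columns=[
            "feature_name",
            "category",
            "channel",
            "secondary_channel",
            "granularity_index",
        ],
    ).set_index("feature_name")


class TestGranularity:

    def test_single_gene_trace_equals_its_values(self, meta):
        prof = pd.DataFrame(
            [[-2.0, 0.1, 0.0, 0.05, 1.0]],
            index=["geneA"],
            columns=list(meta.index),
        )
        out = ms.granularity_profile(["geneA"], prof, meta, "WGA")
        gene_rows = out[out["gene"] == "geneA"].set_index("granularity_index")
        assert gene_rows.loc[1, "value"] == -2.0
        assert gene_rows.loc[4, "value"] == 0.05

    def test_injected_small_structure_decrease_recovered(self, meta):
        """A group with a negative shift at granularity index 1 of WGA only:
        the group mean is negative there and near zero at indices >= 3."""
        rng = np.random.default_rng(10)
        X = rng.normal(0, 0.05, size=(6, 5))
        X[:, 0] -= 2.0  # Granularity_WGA_1
        prof = pd.DataFrame(
            X, index=[f"v{i}" for i in range(6)], columns=list(meta.index)
        )
        out = ms.granularity_profile(list(prof.index), prof, meta, "WGA")
        mean = out[out["gene"] == "__group_mean__"].set_index("granularity_index")
        assert mean.loc[1, "value"] < -1
        assert abs(mean.loc[3, "value"]) < 0.2
        assert abs(mean.loc[4, "value"]) < 0.2

    def test_group_mean_matches_arithmetic_oracle(self, meta):
        rng = np.random.default_rng(11)
        prof = pd.DataFrame(
            rng.normal(size=(4, 5)), index=list("abcd"), columns=list(meta.index)
        )
        out = ms.granularity_profile(list("abcd"), prof, meta, "WGA")
        mean = out[out["gene"] == "__group_mean__"].set_index("granularity_index")
        for f, idx in meta.loc[meta["category"] == "Granularity", "granularity_index"].items():
            assert mean.loc[idx, "value"] == pytest.approx(prof[f].mean())

    def test_channel_without_granularity_rejected(self, meta):
        prof = pd.DataFrame(
            np.zeros((1, 5)), index=["a"], columns=list(meta.index)
        )
        with pytest.raises(ValueError):
            ms.granularity_profile(["a"], prof, meta, "DNA")


class TestEssentialitySplit:
    def _tables(self, effects):
        genes = [f"g{i}" for i in range(len(effects))]
        ht = pd.DataFrame(
            {
                "signal_score": np.linspace(0, 50, len(genes)),
                "whole_cell_hit": [i % 2 == 0 for i in range(len(genes))],
            },
            index=genes,
        )
        ge = pd.DataFrame({"gene": genes, "gene_effect": effects})
        return ht, ge

    def test_threshold_side_assignment(self):
        ht, ge = self._tables([-1.0, -0.5, -0.4, 0.2])
        out = ms.essentiality_split(ht, ge)
        assert out["labels"]["g0"] == "essential"
        assert out["labels"]["g1"] == "essential"  # boundary counts as essential
        assert out["labels"]["g2"] == "nonessential"
        assert out["labels"]["g3"] == "nonessential"

    def test_missing_genes_counted(self):
        ht, ge = self._tables([-1.0, 0.0, 0.0, 0.0])
        out = ms.essentiality_split(ht, ge.iloc[:3])
        assert out["n_missing"] == 1

    def test_hit_rates_independent_of_essentiality(self, small_screen, small_profiles, small_caller):
        """Essentiality is generated independently of effects, so hit rates
        in the two groups should be close."""
        _, _, _, truth = small_screen
        from morphoscreen.synthetic import generate_annotations

        _, _, _, ge = generate_annotations(truth, seed=0)
        ht = small_caller.hit_table_
        out = ms.essentiality_split(ht, ge)
        diff = (
            out["summary"]["essential"]["hit_rate"]
            - out["summary"]["nonessential"]["hit_rate"]
        )
        assert abs(diff) < 0.35
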