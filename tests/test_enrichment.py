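"""Weighted-KS enrichment scores, permutation calls, and Fisher region tests."""
import itertools

import numpy as np
import pandas as pd
import pytest

from gscproteo.enrichment import (
    RankedList,
    build_ranked_list,
    gsea_es,
    gsea_preranked,
    region_enrichment,
    ssgsea_subtype,
)
from gscproteo.io import ExpressionMatrix, GeneSetCollection
from gscproteo.simulate import SimulationConfig, generate_validation_panel


def es_bruteforce(scores, hit_mask, weight=1.0):
    """Independent running-sum oracle: explicit step-by-step walk."""
    w = [abs(s) ** weight for s in scores]
    total = sum(wi for wi, h in zip(w, hit_mask) if h)
    n_miss = len(scores) - sum(hit_mask)
    running, value = [], 0.0
    for wi, h in zip(w, hit_mask):
        value += wi / total if h else -1.0 / n_miss
        running.append(value)
    return max(running, key=abs), running


def make_ranked(scores, ids=None):
    ids = ids or [f"g{i}" for i in range(len(scores))]
    return RankedList(ids=ids, scores=np.array(scores, dtype=float))


class TestEnrichmentScore:
    def test_top_hit_saturates(self):
        ranked = make_ranked([4.0, 3.0, 2.0, 1.0])
        es, running = gsea_es(ranked, {"g0"})
        assert es == pytest.approx(1.0)
        assert running == pytest.approx([1.0, 2 / 3, 1 / 3, 0.0])

    def test_bottom_hit_gives_minus_one(self):
        ranked = make_ranked([4.0, 3.0, 2.0, 1.0])
        es, running = gsea_es(ranked, {"g3"})
        assert es == pytest.approx(-1.0)
        assert running == pytest.approx([-1 / 3, -2 / 3, -1.0, 0.0])

    def test_matches_exhaustive_oracle_on_short_lists(self):
        grid = [2.5, 1.5, 0.5, -0.5, -1.0, -2.0, -3.0, -4.0]
        for n in range(2, 7):
            scores = grid[:n]
            ranked = make_ranked(scores)
            for r in range(1, n):
                for subset in itertools.combinations(range(n), r):
                    hit_mask = [i in subset for i in range(n)]
                    es, _ = gsea_es(ranked, {f"g{i}" for i in subset})
                    expected, _ = es_bruteforce(scores, hit_mask)
                    assert es == pytest.approx(expected, abs=1e-12)

    def test_antisymmetry_under_score_negation(self):
        # subsets chosen so the running sum has no exact |extremum| tie
        scores = [3.0, 1.5, 0.5, -1.0, -2.5]
        ranked = make_ranked(scores)
        flipped = make_ranked(
            sorted([-s for s in scores], reverse=True),
            ids=[f"g{i}" for i in reversed(range(5))],
        )
        for subset in [{"g0"}, {"g1"}, {"g0", "g4"}]:
            es, _ = gsea_es(ranked, subset)
            es_flipped, _ = gsea_es(flipped, subset)
            assert es_flipped == pytest.approx(-es, abs=1e-12)

    def test_empty_and_full_sets_rejected(self):
        ranked = make_ranked([2.0, 1.0])
        with pytest.raises(ValueError, match="not represented"):
            gsea_es(ranked, {"nope"})
        with pytest.raises(ValueError, match="degenerate"):
            gsea_es(ranked, {"g0", "g1"})


class TestRankedList:
    def test_ties_break_by_feature_id(self):
        values = pd.Series({"b": 1.0, "a": 1.0, "c": 2.0})
        ranked = build_ranked_list(values)
        assert ranked.ids == ["c", "a", "b"]

    def test_total_ties_rejected(self):
        with pytest.raises(ValueError, match="total ties"):
            build_ranked_list(pd.Series({"a": 1.0, "b": 1.0}))

    def test_duplicate_gene_proteins_excluded(self):
        values = pd.Series({"p1": 3.0, "p2": 2.0, "p3": 1.0, "p4": 0.5})
        mapping = {"p1": "gA", "p2": "gA", "p3": "gB", "p4": "gC"}
        ranked = build_ranked_list(values, protein_to_gene=mapping)
        assert ranked.ids == ["gB", "gC"]
        assert ranked.excluded_duplicates == ["p1", "p2"]


class TestPreranked:
    def test_null_sets_uncalibrated_rarely_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            scores = np.sort(rng.normal(size=500))[::-1]
            ranked = make_ranked(list(scores))
            members = [f"g{i}" for i in rng.choice(500, 25, replace=False)]
            coll = GeneSetCollection(sets={"S": members}, descriptions={"S": ""})
            res = gsea_preranked(ranked, coll, n_perm=200, seed=seed)[0]
            hits += res.p_value < 0.05
        assert hits <= 2

    def test_permutation_p_never_zero(self):
        ranked = make_ranked(list(np.linspace(5, -5, 100)))
        coll = GeneSetCollection(sets={"TOP": [f"g{i}" for i in range(10)]},
                                 descriptions={"TOP": ""})
        res = gsea_preranked(ranked, coll, n_perm=200, seed=0)[0]
        assert res.p_value > 0
        assert res.es > 0 and res.nes > 1

    def test_n_perm_floor(self):
        ranked = make_ranked([2.0, 1.0, 0.5])
        coll = GeneSetCollection(sets={"S": ["g0"]}, descriptions={"S": ""})
        with pytest.raises(ValueError):
            gsea_preranked(ranked, coll, n_perm=10)


@pytest.fixture(scope="module")
def validation_panel():
    cfg = SimulationConfig(
        n_proteins=1200, n_gpc_planted=60, n_gm_planted=90, seed=23
    )
    from gscproteo.simulate import generate_discovery_panel

    _, _, truth = generate_discovery_panel(cfg)
    vmat, vann, _ = generate_validation_panel(cfg, truth)
    sets = GeneSetCollection(
        sets={"GPC": list(truth.gpc_true), "GM": list(truth.gm_true)},
        descriptions={"GPC": "", "GM": ""},
    )
    return vmat, vann, sets, truth


class TestPlantedRecovery:
    def test_group_difference_ranking_recovers_both_arms(self, validation_panel):
        vmat, vann, sets, _ = validation_panel
        mes = [a.sample_id for a in vann if a.subtype == "mesenchymal"]
        non = [a.sample_id for a in vann if a.subtype != "mesenchymal"]
        diff = vmat.values[non].mean(axis=1) - vmat.values[mes].mean(axis=1)
        ranked = build_ranked_list(diff, ranking_mode="group_mean_difference")
        results = {r.set_name: r for r in
                   gsea_preranked(ranked, sets, n_perm=1000, seed=1)}
        assert results["GPC"].es > 0 and results["GM"].es < 0
        assert results["GPC"].q_value < 0.01 and results["GM"].q_value < 0.01


class TestSsgsea:
    def test_calls_follow_subtype_and_never_overlap(self, validation_panel):
        vmat, vann, sets, _ = validation_panel
        calls = ssgsea_subtype(vmat, sets, n_perm=300, seed=2)
        piv = calls.pivot(index="sample_id", columns="set_name",
                          values="enriched_call")
        assert not (piv["GPC"] & piv["GM"]).any()
        subtype = {a.sample_id: a.subtype for a in vann}
        for sample, row in piv.iterrows():
            if row["GPC"]:
                assert subtype[sample] in ("proneural", "classical")
            if row["GM"]:
                assert subtype[sample] == "mesenchymal"

    def test_affine_transform_invariance(self, validation_panel):
        vmat, _, sets, _ = validation_panel
        one = ExpressionMatrix(vmat.values.iloc[:, [0]])
        scaled = ExpressionMatrix(vmat.values.iloc[:, [0]] * 3.0 + 7.0)
        a = ssgsea_subtype(one, sets, n_perm=200, seed=3)
        b = ssgsea_subtype(scaled, sets, n_perm=200, seed=3)
        assert np.allclose(a["es"], b["es"])
        assert (a["enriched_call"] == b["enriched_call"]).all()

    def test_constant_sample_rejected(self, two_sets):
        matrix = ExpressionMatrix(
            pd.DataFrame({"S1": [1.0, 1.0, 1.0]}, index=["A", "B", "D"])
        )
        with pytest.raises(ValueError, match="total ties"):
            ssgsea_subtype(matrix, two_sets, n_perm=100)


class TestRegionEnrichment:
    def test_region_without_genes_gives_p_one(self):
        fc = pd.Series({"a": 1.0, "b": -1.0, "c": 0.5})
        sets = GeneSetCollection(
            sets={"R": ["a", "b", "c"], "EMPTYISH": ["zz"]},
            descriptions={"R": "", "EMPTYISH": ""},
        )
        # universe limited to genes in >= 1 set; the region with no
        # overlapping gene yields the degenerate-margin p = 1
        results = {r.region: r for r in region_enrichment(fc, sets)}
        assert results["EMPTYISH"].p_value == 1.0

    def test_zero_fc_genes_excluded(self):
        fc = pd.Series({"a": 1.0, "b": 0.0, "c": -2.0})
        sets = GeneSetCollection(sets={"R": ["a", "b", "c"]},
                                 descriptions={"R": ""})
        result = region_enrichment(fc, sets)[0]
        assert sum(result.table[0]) + sum(result.table[1]) == 2

    def test_constructed_gpc_only_region_is_enriched(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(200)]
        fc = pd.Series(rng.normal(size=200), index=genes)
        up_gpc = list(fc.index[fc > 0])
        sets = GeneSetCollection(
            sets={"GPCREGION": up_gpc[:30], "ALL": genes},
            descriptions={"GPCREGION": "", "ALL": ""},
        )
        result = {r.region: r for r in region_enrichment(fc, sets)}["GPCREGION"]
        assert result.q_value < 0.01
        assert result.odds_ratio > 1
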