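"""Synthetic-data generators: determinism, planted-truth structure, and
parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from mirkey.meta import compute_smd, pool_random
from mirkey.seedscan import seed_sequence
from mirkey.synthetic import (MIR_106B_5P, SyntheticConfig, gen_clinical,
                              gen_expression_studies, gen_gene_studies,
                              gen_pathways, gen_ppi, gen_sequences,
                              gen_target_votes, gen_tumor_normal_matrix,
                              ground_truth)


def _smds(cfg):
    out = []
    for st in gen_expression_studies(cfg):
        st = st.to_log2()
        t, n = st.group_values(st.values.index[0])
        out.append(compute_smd(t, n, st.study_id))
    return out


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sigma": 0.0},
            {"n_tumor": 1},
            {"de_fraction": 1.5},
            {"db_sensitivity": -0.1},
            {"hub_module_size": 200, "graph_nodes": 100},
            {"pathway_size_range": (5, 2)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestDeterminism:
    def test_all_generators_reproducible(self):
        a, b = SyntheticConfig(seed=7), SyntheticConfig(seed=7)
        pd.testing.assert_frame_equal(
            gen_expression_studies(a)[0].values,
            gen_expression_studies(b)[0].values,
        )
        ma, mb = gen_tumor_normal_matrix(a)[0], gen_tumor_normal_matrix(b)[0]
        pd.testing.assert_frame_equal(ma.values, mb.values)
        pd.testing.assert_frame_equal(gen_target_votes(a)[0],
                                      gen_target_votes(b)[0])
        ga, gb = gen_ppi(a)[0], gen_ppi(b)[0]
        assert sorted(ga.edges(data="score")) == sorted(gb.edges(data="score"))
        assert gen_pathways(a)[0].sets == gen_pathways(b)[0].sets
        assert [r.sequence for r in gen_sequences(a)[1]] == [
            r.sequence for r in gen_sequences(b)[1]
        ]

    def test_seed_changes_data_not_shapes(self):
        a = gen_tumor_normal_matrix(SyntheticConfig(seed=0))[0]
        b = gen_tumor_normal_matrix(SyntheticConfig(seed=1))[0]
        assert a.values.shape == b.values.shape
        assert not np.allclose(a.values.to_numpy(), b.values.to_numpy())


class TestGroundTruth:
    def test_planted_de_count_floor_rule(self):
        cfg = SyntheticConfig(seed=0, n_genes=801, de_fraction=0.25)
        truth = ground_truth(cfg)
        assert len(truth.de_genes) == int(0.25 * 801)

    def test_truth_partitions_universe(self):
        truth = ground_truth(SyntheticConfig(seed=3))
        assert set(truth.de_genes) <= set(truth.genes)
        assert set(truth.module_nodes) <= set(truth.de_genes)
        assert set(truth.module_nodes) <= set(truth.true_targets)
        assert set(truth.anchor_genes) <= set(truth.module_nodes)
        assert len(set(truth.de_genes)) == len(truth.de_genes)


class TestExpressionStudies:
    def test_null_effect_near_zero(self):
        cfg = SyntheticConfig(seed=0, planted_smd=0.0, n_tumor=400,
                              n_normal=400, n_studies=2)
        for e in _smds(cfg):
            assert abs(e.g) < 0.25

    def test_mc_recovery_of_planted_smd(self):
        est = [
            pool_random(_smds(SyntheticConfig(seed=s))).pooled
            for s in range(100)
        ]
        assert abs(np.mean(est) - 2.85) < 0.15

    def test_group_sizes_recorded(self):
        st = gen_expression_studies(SyntheticConfig(seed=0))[0]
        assert len(st.tumor_samples) == 20 and len(st.normal_samples) == 20


class TestTumorNormalMatrix:
    def test_raw_scale_output(self):
        st, _ = gen_tumor_normal_matrix(SyntheticConfig(seed=0))
        assert not st.log2
        assert (st.values.to_numpy() > 0).all()

    def test_planted_lfc_visible_after_log2(self):
        st, truth = gen_tumor_normal_matrix(SyntheticConfig(seed=0))
        st = st.to_log2()
        gene = truth.module_nodes[0]  # planted up
        t, n = st.group_values(gene)
        assert t.mean() - n.mean() == pytest.approx(3.0, abs=0.8)


class TestTargetVotes:
    def test_perfect_databases(self):
        cfg = SyntheticConfig(seed=0, db_sensitivity=1.0, db_specificity=1.0)
        votes, truth = gen_target_votes(cfg)
        counts = votes.sum(axis=1)
        targets = set(truth.true_targets)
        assert (counts[[g in targets for g in votes.index]] == 12).all()
        assert (counts[[g not in targets for g in votes.index]] == 0).all()

    def test_recall_matches_binomial_tail(self):
        cfg = SyntheticConfig(seed=0, n_genes=4000, db_sensitivity=0.7)
        votes, truth = gen_target_votes(cfg)
        targets = list(truth.true_targets)
        passed = (votes.loc[targets].sum(axis=1) >= 5).mean()
        assert passed == pytest.approx(binom.sf(4, 12, 0.7), abs=0.02)

    def test_false_pass_rate_matches_binomial_tail(self):
        cfg = SyntheticConfig(seed=1, n_genes=4000, db_specificity=0.9)
        votes, truth = gen_target_votes(cfg)
        non = [g for g in votes.index if g not in set(truth.true_targets)]
        rate = (votes.loc[non].sum(axis=1) >= 5).mean()
        assert rate == pytest.approx(binom.sf(4, 12, 0.1), abs=5e-3)


class TestPPI:
    def test_simple_graph(self):
        g, _ = gen_ppi(SyntheticConfig(seed=0))
        assert not any(u == v for u, v in g.edges())
        assert g.number_of_nodes() == 120

    def test_module_edges_survive_filter(self):
        g, truth = gen_ppi(SyntheticConfig(seed=0))
        module = set(truth.module_nodes)
        for u, v, d in g.edges(data=True):
            assert 0.0 <= d["score"] <= 1.0
            if u in module and v in module:
                assert d["score"] >= 0.7

    def test_module_density(self):
        g, truth = gen_ppi(SyntheticConfig(seed=2))
        sub = g.subgraph(truth.module_nodes)
        n = len(truth.module_nodes)
        density = 2 * sub.number_of_edges() / (n * (n - 1))
        assert density > 0.7


class TestPathways:
    def test_anchors_in_designated_only(self):
        coll, truth = gen_pathways(SyntheticConfig(seed=0))
        anchors = set(truth.anchor_genes)
        for pid, genes in coll.sets.items():
            if pid in truth.designated_pathways:
                assert anchors <= genes
            else:
                assert not anchors <= genes

    def test_sizes_within_range(self):
        cfg = SyntheticConfig(seed=1)
        coll, _ = gen_pathways(cfg)
        lo, hi = cfg.pathway_size_range
        for genes in coll.sets.values():
            assert len(genes) <= hi + cfg.n_anchors  # anchors may extend a set
            assert len(genes) >= min(lo, 3)

    def test_zero_overlap_rate_gives_disjoint_background_pair(self):
        cfg = SyntheticConfig(seed=2, overlap_rate=0.0)
        coll, truth = gen_pathways(cfg)
        bg = [p for p in coll.sets if p not in truth.cluster_pathway_ids]
        a, b = bg[0], bg[1]
        assert not (coll[a] & coll[b])

    def test_overlap_rate_controls_sharing(self):
        cfg = SyntheticConfig(seed=3, overlap_rate=0.5)
        coll, truth = gen_pathways(cfg)
        bg = [p for p in coll.sets if p not in truth.cluster_pathway_ids]
        shared = len(coll[bg[0]] & coll[bg[1]])
        assert shared >= int(0.5 * len(coll[bg[1]])) - 2


class TestSequences:
    def test_planted_sites_recovered_exactly(self):
        mirna, records, truth = gen_sequences(SyntheticConfig(seed=0))
        site = seed_sequence(mirna)
        for rec in records:
            found = [
                i for i in range(len(rec.sequence) - len(site) + 1)
                if rec.sequence[i : i + len(site)] == site
            ]
            assert found == list(rec.planted_offsets)
            assert found == truth.planted_sites[rec.utr_id]

    def test_planted_window_au_rich(self):
        _, records, _ = gen_sequences(SyntheticConfig(seed=1))
        for rec in records:
            for off in rec.planted_offsets:
                window = rec.sequence[max(0, off - 4) : off + 11]
                au = sum(c in "AU" for c in window) / len(window)
                assert au >= 0.6

    def test_negative_utrs_site_free(self):
        _, records, _ = gen_sequences(SyntheticConfig(seed=2))
        negs = [r for r in records if r.utr_id.startswith("NEG")]
        assert len(negs) == 3
        assert all(r.planted_offsets == () for r in negs)

    def test_bad_mirna_rejected(self):
        with pytest.raises(ValueError):
            gen_sequences(SyntheticConfig(seed=0), mirna="NNNNNNNNNN")

    def test_utr_too_short_rejected(self):
        with pytest.raises(ValueError):
            gen_sequences(SyntheticConfig(seed=0, utr_length=30,
                                          n_planted_sites=3))


class TestClinical:
    def test_dependent_covariate_detected(self):
        from scipy.stats import kruskal

        hits = 0
        for seed in range(10):
            expr, clin = gen_clinical(SyntheticConfig(seed=seed))
            groups = [expr[clin["lymph_nodes"] == c] for c in range(4)]
            hits += kruskal(*groups).pvalue < 0.05
        assert hits >= 8

    def test_independent_covariate_null(self):
        from scipy.stats import spearmanr

        ps = []
        for seed in range(20):
            expr, clin = gen_clinical(SyntheticConfig(seed=seed))
            ps.append(spearmanr(expr, clin["tumor_purity"]).pvalue)
        assert 0.3 < np.mean(ps) < 0.7

    def test_survival_independent_of_expression(self):
        from lifelines import CoxPHFitter

        coefs = []
        for seed in range(5):
            expr, clin = gen_clinical(SyntheticConfig(seed=seed))
            df = pd.DataFrame({"expr": expr, "T": clin["os_time"],
                               "E": clin["os_event"]})
            cph = CoxPHFitter().fit(df, duration_col="T", event_col="E")
            coefs.append(cph.params_["expr"])
        assert abs(np.mean(coefs)) < 0.1


class TestGeneStudies:
    def test_only_anchors_shifted(self):
        studies, truth = gen_gene_studies(SyntheticConfig(seed=0))
        assert len(studies) == 9
        st = studies[0].to_log2()
        anchor = truth.anchor_genes[0]
        t, n = st.group_values(anchor)
        assert t.mean() - n.mean() == pytest.approx(2.0, abs=1.0)
        null_gene = next(
            g for g in truth.genes if g not in set(truth.anchor_genes)
        )
        t, n = st.group_values(null_gene)
        assert abs(t.mean() - n.mean()) < 1.5
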