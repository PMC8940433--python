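"""Fixture generators: determinism, threshold-spanning structure, round-trips."""

import math

import pandas as pd
import pytest
from pydantic import ValidationError

from netpharm import synthetic
from netpharm.errors import ConfigurationError
from netpharm.synthetic import FixtureConfig


class TestConfigValidation:
    def test_unordered_range_rejected(self):
        with pytest.raises(ValidationError, match="ob_range"):
            FixtureConfig(ob_range=(50, 10))

    def test_module_larger_than_universe_rejected(self):
        with pytest.raises(ValidationError, match="exceeds gene universe"):
            FixtureConfig(gene_universe_size=10, planted_modules=[(11, 1.0)])

    def test_overlap_above_one_rejected(self):
        with pytest.raises(ValidationError):
            FixtureConfig(disease_source_overlap=1.5)


class TestCompounds:
    def test_no_sharing_forces_distinct_ids(self):
        cfg = FixtureConfig(n_herbs=2, compounds_per_herb=3, shared_compound_fraction=0)
        df = synthetic.gen_compound_table(cfg)
        assert len(df) == 6
        assert df["compound_id"].nunique() == 6

    def test_determinism_under_fixed_seed(self):
        cfg = FixtureConfig(seed=7)
        a = synthetic.gen_compound_table(cfg)
        b = synthetic.gen_compound_table(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_sharing_reduces_distinct_count_to_ground_truth(self):
        cfg = FixtureConfig(n_herbs=3, compounds_per_herb=10, shared_compound_fraction=0.5)
        df = synthetic.gen_compound_table(cfg)
        distinct = df["compound_id"].nunique()
        assert distinct < 30
        assert distinct == synthetic.expected_distinct_compounds(cfg)
        # shared compounds appear under >= 2 herbs
        counts = df.groupby("compound_id")["herb"].nunique()
        assert (counts > 1).sum() == synthetic.shared_pool_size(cfg)

    def test_ob_dl_span_the_adme_cutoffs(self):
        df = synthetic.gen_compound_table(FixtureConfig(seed=0))
        assert (df["OB"] >= 30).any() and (df["OB"] < 30).any()
        assert (df["DL"] >= 0.18).any() and (df["DL"] < 0.18).any()

    def test_shared_compound_has_consistent_properties(self):
        cfg = FixtureConfig(n_herbs=4, compounds_per_herb=5, shared_compound_fraction=0.4)
        df = synthetic.gen_compound_table(cfg)
        assert (df.groupby("compound_id")[["OB", "DL"]].nunique() == 1).all().all()


class TestPredictions:
    def test_only_configured_sources_emitted(self, small_cfg):
        compounds = synthetic.gen_compound_table(small_cfg)
        preds = synthetic.gen_target_predictions(compounds, small_cfg)
        assert set(preds["source"]) == {"swisstarget", "stitch"}

    def test_empty_compound_table_gives_empty_predictions(self, small_cfg):
        empty = synthetic.gen_compound_table(small_cfg).iloc[:0]
        preds = synthetic.gen_target_predictions(empty, small_cfg)
        assert preds.empty

    def test_uniform_scores_span_threshold_at_half(self):
        # Uniform(0, 0.2) against cutoff 0.1: retention ~ 0.5 at large n
        cfg = FixtureConfig(
            seed=3,
            n_herbs=1,
            compounds_per_herb=200,
            gene_universe_size=5000,
            mean_predictions_per_source=25,
            per_source_score_params={
                "swisstarget": synthetic.SourceScoreParams(
                    family="uniform", params=(0.0, 0.2), threshold=0.1
                )
            },
        )
        compounds = synthetic.gen_compound_table(cfg)
        preds = synthetic.gen_target_predictions(compounds, cfg)
        assert len(preds) > 2000
        frac = (preds["score"] >= 0.1).mean()
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / len(preds))


class TestDiseaseSources:
    def test_source_count(self, small_cfg):
        assert len(synthetic.gen_disease_targets(small_cfg)) == 4

    def test_full_overlap_gives_identical_sets(self):
        cfg = FixtureConfig(disease_source_overlap=1.0, genes_per_disease_source=20)
        sets = list(synthetic.gen_disease_targets(cfg).values())
        assert all(s == sets[0] for s in sets)

    def test_zero_overlap_gives_disjoint_sets(self):
        cfg = FixtureConfig(seed=11, disease_source_overlap=0.0, genes_per_disease_source=20)
        sets = synthetic.gen_disease_targets(cfg)
        union = set().union(*sets.values())
        assert len(union) == sum(len(s) for s in sets.values())

    def test_core_fraction_in_all_sources(self):
        cfg = FixtureConfig(disease_source_overlap=0.3, genes_per_disease_source=40)
        sets = list(synthetic.gen_disease_targets(cfg).values())
        core = set.intersection(*sets)
        assert len(core) == round(0.3 * 40)


class TestPPIEdges:
    def test_complete_module_without_background(self):
        cfg = FixtureConfig(
            seed=1, gene_universe_size=50, background_edge_prob=0.0,
            planted_modules=[(8, 1.0)],
        )
        edges, modules = synthetic.gen_ppi_edges(synthetic.gene_universe(cfg), cfg)
        assert len(edges) == 28  # complete graph on 8 nodes
        pairs = set(map(tuple, edges[["protein1", "protein2"]].to_numpy()))
        assert all(a in modules[0] and b in modules[0] for a, b in pairs)

    def test_no_background_no_modules_is_empty(self):
        cfg = FixtureConfig(gene_universe_size=50, background_edge_prob=0.0, planted_modules=[])
        edges, _ = synthetic.gen_ppi_edges(synthetic.gene_universe(cfg), cfg)
        assert edges.empty

    def test_background_edge_count_within_3sd(self):
        cfg = FixtureConfig(
            seed=9, gene_universe_size=100, background_edge_prob=0.05, planted_modules=[]
        )
        edges, _ = synthetic.gen_ppi_edges(synthetic.gene_universe(cfg), cfg)
        mean = 0.05 * math.comb(100, 2)
        sd = math.sqrt(math.comb(100, 2) * 0.05 * 0.95)
        assert abs(len(edges) - mean) < 3 * sd

    def test_planted_edges_survive_the_confidence_cutoff(self, small_cfg):
        edges, modules = synthetic.gen_ppi_edges(synthetic.gene_universe(small_cfg), small_cfg)
        members = set(modules[0])
        planted = edges[
            edges["protein1"].isin(members) & edges["protein2"].isin(members)
        ]
        assert (planted["combined_score"] >= 700).all()

    def test_no_self_loops_or_duplicate_pairs(self, small_cfg):
        edges, _ = synthetic.gen_ppi_edges(synthetic.gene_universe(small_cfg), small_cfg)
        assert (edges["protein1"] != edges["protein2"]).all()
        assert not edges.duplicated(["protein1", "protein2"]).any()

    def test_module_bigger_than_gene_set_rejected(self, small_cfg):
        with pytest.raises(ConfigurationError):
            synthetic.gen_ppi_edges(["G1", "G2", "G3"], small_cfg)

    def test_unit_scale_switch(self):
        cfg = FixtureConfig(
            gene_universe_size=30, background_edge_prob=0.2, planted_modules=[],
            edge_score_scale="unit", edge_score_range=(0.4, 1.0),
        )
        edges, _ = synthetic.gen_ppi_edges(synthetic.gene_universe(cfg), cfg)
        assert (edges["combined_score"] <= 1.0).all()


class TestExpression:
    def test_noiseless_de_gene_shift_exact(self):
        cfg = FixtureConfig(
            gene_universe_size=20, noise_sd=0.0, de_genes=[("G0005", 2.0)],
            n_samples_per_group=3,
        )
        mat = synthetic.gen_expression_matrix(cfg)
        diff = mat.group_columns("case").mean(axis=1) - mat.group_columns("control").mean(axis=1)
        assert diff["G0005"] == pytest.approx(2.0)
        assert abs(diff.drop("G0005")).max() == 0.0

    def test_unknown_de_gene_rejected(self):
        cfg = FixtureConfig(gene_universe_size=20, de_genes=[("NOPE", 1.0)])
        with pytest.raises(ConfigurationError, match="NOPE"):
            synthetic.gen_expression_matrix(cfg)

    def test_fixed_seed_identical(self, small_cfg):
        a = synthetic.gen_expression_matrix(small_cfg)
        b = synthetic.gen_expression_matrix(small_cfg)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestGeneSets:
    def test_categories_and_focus_genes(self, small_cfg):
        focus = ["G0001", "G0002"]
        coll = synthetic.gen_gene_sets(small_cfg, focus_genes=focus)
        cats = {t.category for t in coll}
        assert cats == {"BP", "CC", "MF", "pathway"}
        for cat in cats:
            first = next(t for t in coll if t.category == cat and t.term_id.endswith("T001"))
            assert set(focus) <= set(first.genes)


class TestRoundTrips:
    def test_tables_survive_write_read(self, small_cfg, tmp_path):
        compounds = synthetic.gen_compound_table(small_cfg)
        synthetic.write_compounds(compounds, tmp_path / "c.tsv")
        pd.testing.assert_frame_equal(synthetic.read_compounds(tmp_path / "c.tsv"), compounds)

        preds = synthetic.gen_target_predictions(compounds, small_cfg)
        synthetic.write_predictions(preds, tmp_path / "p.tsv")
        pd.testing.assert_frame_equal(synthetic.read_predictions(tmp_path / "p.tsv"), preds)

        genes = sorted(synthetic.gen_disease_targets(small_cfg)["source_1"])
        synthetic.write_gene_list(genes, tmp_path / "g.txt")
        assert synthetic.read_gene_list(tmp_path / "g.txt") == genes

    def test_expression_round_trip(self, small_cfg, tmp_path):
        mat = synthetic.gen_expression_matrix(small_cfg)
        from netpharm import expression

        expression.write_expression(mat, tmp_path / "e.tsv", tmp_path / "l.tsv")
        back = expression.read_expression(tmp_path / "e.tsv", tmp_path / "l.tsv")
        pd.testing.assert_frame_equal(back.values, mat.values)
        pd.testing.assert_series_equal(back.labels, mat.labels)
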