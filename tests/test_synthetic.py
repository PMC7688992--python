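"""Generator determinism, planted-structure round-trips, and file outputs."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from vigornet import synthetic
from vigornet.config import SimConfig
from vigornet.crosstalk import classify_crosstalk, summarize_crosstalk
from vigornet.enrichment import fisher_enrichment, read_gmt
from vigornet.errors import ConfigError
from vigornet.grn import RoleAssignment, learn_subnetwork, preprocess
from vigornet.integration import filter_ppi


def test_same_seed_identical_outputs(small_cfg):
    a, pa = synthetic.generate_compendium(small_cfg)
    b, pb = synthetic.generate_compendium(small_cfg)
    pd.testing.assert_frame_equal(a, b)
    assert pa.effects == pb.effects


def test_bundle_byte_identical(small_cfg, tmp_path):
    p1 = synthetic.write_bundle(small_cfg, tmp_path / "a")
    p2 = synthetic.write_bundle(small_cfg, tmp_path / "b")
    for name in p1:
        assert filecmp.cmp(p1[name], p2[name], shallow=False), name


def test_compendium_shape_and_positivity(small_cfg):
    expr, planted = synthetic.generate_compendium(small_cfg)
    assert expr.shape == (small_cfg.n_genes, small_cfg.n_samples)
    assert (expr.to_numpy() >= 0).all()
    assert expr.index.is_unique
    assert len(planted) == small_cfg.n_factors * small_cfg.targets_per_factor
    assert all(f != t for f, t in planted.edges), "no self-edges"


def test_no_factors_means_no_structure():
    cfg = SimConfig(n_samples=20, n_genes=50, n_factors=0,
                    planted_category_counts={}, ppi_edges=30, seed=3)
    _, planted = synthetic.generate_compendium(cfg)
    assert len(planted) == 0


def test_invalid_config_names_field():
    with pytest.raises(ConfigError, match="n_factors"):
        SimConfig(n_genes=10, n_factors=10)
    with pytest.raises(ConfigError, match="ppi_edges"):
        SimConfig(n_genes=10, n_factors=2, ppi_edges=100, planted_category_counts={})
    with pytest.raises(ConfigError, match="planted_category_counts"):
        SimConfig(n_genes=10, n_factors=2, planted_category_counts={1: 11}, ppi_edges=5)


def test_planted_categories_round_trip(small_cfg):
    """The classifier recovers exactly the planted per-category counts."""
    transcripts, proteins = synthetic.generate_diff_tables(small_cfg)
    table = classify_crosstalk(transcripts, proteins)
    summary = summarize_crosstalk(table["category"].dropna().astype(int))
    assert summary.counts == small_cfg.planted_category_counts


def test_zero_counts_empty_tables():
    cfg = SimConfig(n_genes=20, n_factors=2, planted_category_counts={}, ppi_edges=10)
    transcripts, proteins = synthetic.generate_diff_tables(cfg)
    assert transcripts.empty and proteins.empty
    summary = summarize_crosstalk([])
    assert summary.total == 0


def test_noiseless_planted_edges_recovered(noiseless_cfg):
    """With zero noise the per-subset learner finds every planted edge."""
    expr, planted = synthetic.generate_compendium(noiseless_cfg)
    zm = preprocess(expr)
    roles = RoleAssignment(
        factors=frozenset(synthetic.factor_ids(noiseless_cfg)),
        targets=frozenset(expr.index),
    )
    edges = set(learn_subnetwork(zm, roles))
    assert planted.edges <= edges


def test_ppi_boundaries_and_determinism():
    hi = SimConfig(n_genes=40, n_factors=4, ppi_edges=50,
                   ppi_score_range=(400, 1000), planted_category_counts={}, seed=5)
    lo = SimConfig(n_genes=40, n_factors=4, ppi_edges=50,
                   ppi_score_range=(0, 399), planted_category_counts={}, seed=5)
    edges_hi = synthetic.generate_interaction_file(hi)
    edges_lo = synthetic.generate_interaction_file(lo)
    assert len(filter_ppi(edges_hi, min_score=400)) == len(edges_hi)
    assert len(filter_ppi(edges_lo, min_score=400)) == 0
    pd.testing.assert_frame_equal(edges_hi, synthetic.generate_interaction_file(hi))
    # unique undirected pairs, no self-interactions
    pairs = set(map(tuple, edges_hi[["node_a", "node_b"]].to_numpy()))
    assert len(pairs) == len(edges_hi)
    assert all(a != b for a, b in pairs)


def test_planted_enriched_term_detected(small_cfg, tmp_path):
    """The designated term is significantly enriched in the planted DE set."""
    annotation = synthetic.generate_annotation_map(small_cfg)
    path = tmp_path / "anno.gmt"
    synthetic.write_gmt(annotation, path)
    assert read_gmt(path).keys() == annotation.keys()

    transcripts, _ = synthetic.generate_diff_tables(small_cfg)
    de = [
        r.gene_id
        for r in transcripts.itertuples()
        if (r.fc > 1.2 or r.fc < 1 / 1.2) and r.adj_p < 0.05
    ]
    background = synthetic.gene_ids(small_cfg)
    cells = {c.term_id: c for c in fisher_enrichment(de, background, annotation)}
    assert cells["TERM_ENRICHED"].q < 0.05


def test_term_covering_background_is_not_enriched(small_cfg):
    genes = synthetic.gene_ids(small_cfg)
    annotation = {"ALL": ("everything", genes)}
    (cell,) = fisher_enrichment(genes[:30], genes, annotation)
    assert cell.p == pytest.approx(1.0)


def test_empty_annotation_empty_result(small_cfg):
    genes = synthetic.gene_ids(small_cfg)
    assert fisher_enrichment(genes[:5], genes, {}) == []


def test_mirna_targets_count_and_determinism(small_cfg):
    t1 = synthetic.generate_mirna_targets(small_cfg)
    t2 = synthetic.generate_mirna_targets(small_cfg)
    assert t1 == t2
    assert len(t1) == small_cfg.n_mirna_targets
    assert len(set(t1)) == len(t1)


def test_log_scale_output():
    cfg = SimConfig(n_samples=10, n_genes=30, n_factors=2, ppi_edges=10,
                    planted_category_counts={}, output_scale="log", seed=2)
    log_expr, _ = synthetic.generate_compendium(cfg)
    lin_expr, _ = synthetic.generate_compendium(
        SimConfig(n_samples=10, n_genes=30, n_factors=2, ppi_edges=10,
                  planted_category_counts={}, output_scale="linear", seed=2)
    )
    np.testing.assert_allclose(log_expr, np.log2(lin_expr + 1), rtol=1e-12)
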