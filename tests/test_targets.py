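"""Cis/trans target prediction, DEPTG tallies and network export."""

from __future__ import annotations

import math

import numpy as np
import pytest

from conftest import make_matrix, make_transcript
from lincpipe.core_io import AnnotationSet, PipelineConfig
from lincpipe.diffexpr import DEResult
from lincpipe.simulate import generate_correlated_pair
from lincpipe.targets import (
    TargetEdge,
    classify_deptgs,
    export_network,
    predict_cis_targets,
    predict_trans_targets,
    read_edge_table,
)

SAMPLES = [f"s{i}" for i in range(6)]


def _de(feature_id, is_de=True, direction="up"):
    lfc = 2.0 if direction == "up" else -2.0
    return DEResult(feature_id, 10, 1, lfc if is_de else 0.1, 1e-4, 1e-3, is_de,
                    direction if is_de else "none")


def _pair_rows(r, seed=0):
    x, y = generate_correlated_pair(r, 6, seed)
    return (10 + x).tolist(), (10 + 5 * y).tolist()


class TestCisCandidates:
    def _setup(self, gene_start, gene_end):
        linc = make_transcript("L1", "chr1", [(200_000, 205_000)])
        gene = make_transcript("g1.t", "chr1", [(gene_start, gene_end)], gene_id="g1",
                               biotype="protein_coding")
        xs, ys = _pair_rows(0.9)
        expr = make_matrix({"L1": xs, "g1": ys}, SAMPLES)
        return [linc], AnnotationSet([gene]), expr

    def test_gap_84999_is_a_candidate(self):
        lincs, genes, expr = self._setup(290_000, 300_000)
        (edge,) = predict_cis_targets(lincs, genes, expr)
        assert edge.distance_bp == 84_999
        assert edge.mode == "cis"
        assert edge.r == pytest.approx(0.9)

    def test_gap_exactly_100k_excluded(self):
        lincs, genes, expr = self._setup(305_001, 310_000)
        assert genes.gene_span("g1").start - lincs[0].span.end - 1 == 100_000
        assert predict_cis_targets(lincs, genes, expr) == []

    def test_overlapping_gene_gap_zero(self):
        lincs, genes, expr = self._setup(204_000, 210_000)
        (edge,) = predict_cis_targets(lincs, genes, expr)
        assert edge.distance_bp == 0

    def test_cis_pairs_reported_regardless_of_significance(self):
        # weak correlation still yields an edge, with its honest p
        linc = make_transcript("L1", "chr1", [(200_000, 205_000)])
        gene = make_transcript("g1.t", "chr1", [(290_000, 300_000)], gene_id="g1")
        xs, ys = _pair_rows(0.1)
        expr = make_matrix({"L1": xs, "g1": ys}, SAMPLES)
        (edge,) = predict_cis_targets([linc], AnnotationSet([gene]), expr)
        assert edge.p_value > 0.5

    def test_constant_vector_gives_nan_outside_fdr_family(self):
        linc = make_transcript("L1", "chr1", [(200_000, 205_000)])
        g1 = make_transcript("g1.t", "chr1", [(290_000, 300_000)], gene_id="g1")
        g2 = make_transcript("g2.t", "chr1", [(100_000, 150_000)], gene_id="g2")
        xs, ys = _pair_rows(0.9)
        expr = make_matrix({"L1": xs, "g1": [3.0] * 6, "g2": ys}, SAMPLES)
        edges = {e.gene_id: e for e in
                 predict_cis_targets([linc], AnnotationSet([g1, g2]), expr)}
        assert math.isnan(edges["g1"].r) and math.isnan(edges["g1"].fdr)
        # the defined pair's FDR equals its own BH with family size 1
        assert edges["g2"].fdr == pytest.approx(edges["g2"].p_value)


def _trans_setup(r_planted, n_null=20, seed=3):
    """One DE lincRNA far from every gene; first gene planted at r_planted."""
    rng = np.random.default_rng(seed)
    linc = make_transcript("L1", "chr1", [(200_000, 205_000)])
    genes, rows = [], {}
    x, y = generate_correlated_pair(r_planted, 6, seed)
    rows["L1"] = (10 + x).tolist()
    genes.append(make_transcript("gP.t", "chr2", [(1_000, 5_000)], gene_id="gP"))
    rows["gP"] = (10 + 5 * y).tolist()
    xv = np.asarray(rows["L1"])
    for i in range(n_null):
        genes.append(
            make_transcript(f"gN{i}.t", "chr3", [(10_000 * (i + 1), 10_000 * (i + 1) + 500)],
                            gene_id=f"gN{i}")
        )
        # null profiles with correlation bounded well below the cutoff, as
        # the synthetic generator plants them (at n=6 an unconstrained draw
        # crosses |r|=0.95 a few times per hundred)
        while True:
            v = rng.normal(0, 1, 6)
            if abs(np.corrcoef(xv, v)[0, 1]) < 0.8:
                break
        rows[f"gN{i}"] = (10 + v).tolist()
    return [linc], AnnotationSet(genes), make_matrix(rows, SAMPLES)


class TestTransSelection:
    def test_planted_high_correlation_retained(self):
        lincs, genes, expr = _trans_setup(0.99)
        edges = predict_trans_targets(lincs, genes, expr)
        assert [e.gene_id for e in edges] == ["gP"]
        assert edges[0].sign == "positive"
        assert edges[0].fdr < 0.05

    def test_r_094_rejected_whatever_its_fdr(self):
        lincs, genes, expr = _trans_setup(0.94, n_null=3)
        assert predict_trans_targets(lincs, genes, expr) == []

    def test_negative_correlation_retained_with_negative_sign(self):
        lincs, genes, expr = _trans_setup(-0.99)
        (edge,) = predict_trans_targets(lincs, genes, expr)
        assert edge.sign == "negative"
        assert edge.r == pytest.approx(-0.99)

    def test_cis_eligible_genes_excluded_from_trans_family(self):
        linc = make_transcript("L1", "chr1", [(200_000, 205_000)])
        near = make_transcript("gn.t", "chr1", [(250_000, 260_000)], gene_id="gn")
        xs, ys = _pair_rows(0.99)
        expr = make_matrix({"L1": xs, "gn": ys}, SAMPLES)
        edges = predict_trans_targets([linc], AnnotationSet([near]), expr)
        assert edges == []  # perfectly correlated but a cis neighbour

    def test_selection_invariant_to_gene_order(self):
        lincs, genes, expr = _trans_setup(0.99, n_null=15)
        shuffled = AnnotationSet(reversed(list(genes)))
        a = {(e.lincrna_id, e.gene_id) for e in predict_trans_targets(lincs, genes, expr)}
        b = {(e.lincrna_id, e.gene_id) for e in predict_trans_targets(lincs, shuffled, expr)}
        assert a == b

    def test_every_trans_edge_satisfies_both_thresholds(self, default_bundle):
        from lincpipe.pipeline import _gene_level_models

        b = default_bundle
        gene_models = AnnotationSet(_gene_level_models(b.reference, b.fpkm))
        de_lincs = [b.candidates.get(t) for t in b.truth.de_linc_log2fc]
        cfg = PipelineConfig()
        edges = predict_trans_targets(de_lincs, gene_models, b.fpkm, cfg)
        assert edges
        for e in edges:
            assert abs(e.r) >= cfg.trans_abs_r_min
            assert e.fdr < cfg.fdr_max


class TestDeptgs:
    def _edges(self):
        return [
            TargetEdge("L1", "gA", "trans", 0.99, 1e-4, 1e-3, "positive"),
            TargetEdge("L1", "gB", "trans", 0.98, 1e-4, 1e-3, "positive"),
            TargetEdge("L1", "gC", "trans", -0.99, 1e-4, 1e-3, "negative"),
            TargetEdge("L1", "gD", "trans", 0.97, 1e-4, 1e-3, "positive"),
            TargetEdge("L2", "gA", "trans", -0.96, 1e-3, 1e-2, "negative"),
        ]

    def test_tally_by_sign(self):
        de_genes = [_de("gA"), _de("gB"), _de("gC"), _de("gD", is_de=False)]
        summary = classify_deptgs(self._edges(), de_genes)
        rows = {r[0]: r for r in summary.rows}
        assert rows["L1"] == ("L1", 3, 2, 1)  # gD not DE -> excluded
        assert rows["L2"] == ("L2", 1, 0, 1)

    def test_conservation_up_plus_down_equals_total(self):
        de_genes = [_de(g) for g in ("gA", "gB", "gC", "gD")]
        for _, total, up, down in classify_deptgs(self._edges(), de_genes).rows:
            assert up + down == total


class TestNetworkExport:
    def test_sif_and_round_trip_and_degree(self, tmp_path):
        edges = self._edges_for_export()
        graph = export_network(edges, [_de("L1"), _de("L2")], [_de("gA"), _de("gB")],
                               tmp_path / "net")
        sif = (tmp_path / "net.sif").read_text().strip().split("\n")
        assert len(sif) == len(edges)
        back = read_edge_table(tmp_path / "net.edges.tsv")
        assert {(e.lincrna_id, e.gene_id, e.mode) for e in back} == {
            (e.lincrna_id, e.gene_id, e.mode) for e in edges
        }
        # gA is targeted by both lincRNAs -> appears in 2 SIF lines, degree 2
        assert sum(line.endswith("gA") for line in sif) == 2
        assert graph.in_degree("gA") == 2

    def test_duplicates_dropped_with_warning(self, tmp_path, caplog):
        e = TargetEdge("L1", "gA", "trans", 0.99, 1e-4, 1e-3, "positive")
        with caplog.at_level("WARNING"):
            graph = export_network([e, e], None, None, tmp_path / "net")
        assert graph.number_of_edges() == 1
        assert "duplicate edge" in caplog.text

    def test_empty_edge_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_network([], None, None, tmp_path / "net")

    @staticmethod
    def _edges_for_export():
        return [
            TargetEdge("L1", "gA", "trans", 0.99, 1e-4, 1e-3, "positive"),
            TargetEdge("L1", "gB", "cis", 0.9, 1e-2, 2e-2, "positive", distance_bp=50_000),
            TargetEdge("L2", "gA", "trans", -0.97, 1e-3, 5e-3, "negative"),
        ]


def test_edge_sign_invariant_enforced():
    with pytest.raises(ValueError):
        TargetEdge("L", "g", "trans", -0.99, 1e-4, 1e-3, "positive")
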