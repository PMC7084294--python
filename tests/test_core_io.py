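"""I/O contracts: GTF/BED parsing, coordinate conversion, validation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import make_transcript, random_transcript
from lincpipe.core_io import (
    AnnotationSet,
    EvidenceRecord,
    EvidenceBundle,
    ExpressionMatrix,
    GenomicInterval,
    GtfParseError,
    PipelineConfig,
    ValidationError,
    read_evidence,
    read_gtf,
    read_qtl_bed,
    write_evidence,
    write_gtf,
    write_qtl_bed,
)


def _gtf_line(chrom, start, end, tid, gid, strand="+"):
    return (
        f'{chrom}\tsrc\texon\t{start}\t{end}\t.\t{strand}\t.\t'
        f'transcript_id "{tid}"; gene_id "{gid}";\n'
    )


class TestReadGtf:
    def test_two_exons_one_transcript(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(_gtf_line("chr1", 100, 199, "T1", "G1") + _gtf_line("chr1", 300, 399, "T1", "G1"))
        ann = read_gtf(p)
        t = ann.get("T1")
        assert t.exon_count == 2
        assert t.length == 200
        assert (t.span.start, t.span.end) == (100, 399)

    def test_end_before_start_is_parse_error(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(_gtf_line("chr1", 500, 400, "T1", "G1"))
        with pytest.raises(GtfParseError, match=":1:"):
            read_gtf(p)

    def test_exons_on_two_chromosomes_rejected(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(_gtf_line("chr1", 100, 199, "T1", "G1") + _gtf_line("chr2", 300, 399, "T1", "G1"))
        with pytest.raises(ValidationError, match="chr2"):
            read_gtf(p)

    def test_duplicate_exon_rejected(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(_gtf_line("chr1", 100, 199, "T1", "G1") * 2)
        with pytest.raises(ValidationError, match="duplicate exon"):
            read_gtf(p)

    def test_wrong_field_count_names_line(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(_gtf_line("chr1", 100, 199, "T1", "G1") + "chr1\tonly\tthree\n")
        with pytest.raises(GtfParseError, match=":2:"):
            read_gtf(p)

    def test_round_trip_preserves_annotation(self, tmp_path):
        rng = np.random.default_rng(3)
        ann = AnnotationSet(random_transcript(rng, f"T{i}") for i in range(20))
        p = tmp_path / "rt.gtf"
        write_gtf(ann, p)
        back = read_gtf(p)
        assert back.transcript_ids == ann.transcript_ids
        for tid in ann.transcript_ids:
            a, b = ann.get(tid), back.get(tid)
            assert a.exons == b.exons
            assert a.gene_id == b.gene_id

    def test_duplicate_transcript_ids_across_sets_rejected(self):
        t = make_transcript("T1", "chr1", [(1, 100)])
        with pytest.raises(ValidationError, match="duplicate transcript_id"):
            AnnotationSet([t, make_transcript("T1", "chr2", [(1, 100)])])


class TestTranscriptLength:
    def test_length_matches_position_count_on_random_fixtures(self):
        # spliced length must equal the brute-force count of covered positions
        rng = np.random.default_rng(42)
        for i in range(100):
            t = random_transcript(rng, f"T{i}")
            covered = set()
            for e in t.exons:
                covered.update(range(e.start, e.end + 1))
            assert t.length == len(covered)

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValidationError, match="overlapping"):
            make_transcript("T1", "chr1", [(100, 200), (150, 250)])


class TestIntervals:
    def test_invariants(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 0, 10)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 10, 9)

    def test_gap_to(self):
        a = GenomicInterval("chr1", 200_000, 205_000)
        b = GenomicInterval("chr1", 290_000, 300_000)
        assert a.gap_to(b) == 84_999
        assert b.gap_to(a) == 84_999
        assert a.gap_to(GenomicInterval("chr1", 204_000, 206_000)) == 0
        assert a.gap_to(GenomicInterval("chr2", 1, 2)) is None


class TestQtlBed:
    def test_imf_keyword_and_conversion(self, tmp_path, config):
        p = tmp_path / "q.bed"
        p.write_text("chr1\t0\t5000\tIntramuscular fat content\tQ1\n")
        (rec,) = read_qtl_bed(p, config)
        assert (rec.interval.start, rec.interval.end) == (1, 5000)
        assert rec.trait_class == "IMF"

    def test_backfat_is_fat_other(self, tmp_path, config):
        p = tmp_path / "q.bed"
        p.write_text("chr1\t999\t2000\tAverage backfat thickness\n")
        (rec,) = read_qtl_bed(p, config)
        assert (rec.interval.start, rec.interval.end) == (1000, 2000)
        assert rec.trait_class == "fat_other"

    def test_unmatched_trait_is_non_fat(self, tmp_path, config):
        p = tmp_path / "q.bed"
        p.write_text("chr1\t0\t100\tTeat number\n")
        assert read_qtl_bed(p, config)[0].trait_class == "non_fat"

    @pytest.mark.parametrize("row", ["chr1\t100\t100\tTrait", "chr1\t0\t100\t "])
    def test_bad_rows_rejected(self, tmp_path, config, row):
        p = tmp_path / "q.bed"
        p.write_text(row + "\n")
        with pytest.raises(GtfParseError):
            read_qtl_bed(p, config)

    def test_bed_round_trip_exact(self, tmp_path, config):
        p = tmp_path / "q.bed"
        lines = [
            "chr1\t0\t5000\tIntramuscular fat content\tQ1",
            "chr3\t12345\t99999\tTeat number\tQ2",
        ]
        p.write_text("\n".join(lines) + "\n")
        recs = read_qtl_bed(p, config)
        q = tmp_path / "q2.bed"
        write_qtl_bed(recs, q)
        assert q.read_text() == p.read_text()


class TestExpressionMatrix:
    def _write(self, tmp_path, body):
        p = tmp_path / "m.tsv"
        p.write_text(body)
        return p

    def test_all_zero_counts_valid(self, tmp_path):
        from lincpipe.core_io import read_expression_matrix

        p = self._write(tmp_path, "feature_id\ts1\ts2\nf1\t0\t0\nf2\t0\t0\n")
        m = read_expression_matrix(p, "counts", {"s1": "A", "s2": "B"})
        assert m.values.sum().sum() == 0

    def test_negative_value_rejected(self, tmp_path):
        from lincpipe.core_io import read_expression_matrix

        p = self._write(tmp_path, "feature_id\ts1\ts2\nf1\t1\t-1\n")
        with pytest.raises(ValidationError, match="negative"):
            read_expression_matrix(p, "counts", {"s1": "A", "s2": "B"})

    def test_fractional_count_names_cell(self, tmp_path):
        from lincpipe.core_io import read_expression_matrix

        p = self._write(tmp_path, "feature_id\ts1\ts2\nf1\t1\t2.5\n")
        with pytest.raises(ValidationError, match=r"\(f1, s2\)"):
            read_expression_matrix(p, "counts", {"s1": "A", "s2": "B"})

    def test_sample_without_group_rejected(self, tmp_path):
        from lincpipe.core_io import read_expression_matrix

        p = self._write(tmp_path, "feature_id\ts1\ts2\nf1\t1\t2\n")
        with pytest.raises(ValidationError, match="group map"):
            read_expression_matrix(p, "counts", {"s1": "A"})


class TestEvidence:
    def test_round_trip_and_missing_lookup(self, tmp_path):
        bundle = EvidenceBundle(
            [
                EvidenceRecord("T1", -1.5, -2.0, None, {"NR": 1e-8, "UniRef90": None}),
                EvidenceRecord("T2", 0.5, -0.1, 2e-6, {"NR": None, "UniRef90": 0.01}),
            ]
        )
        p = tmp_path / "e.tsv"
        write_evidence(bundle, p)
        back = read_evidence(p)
        r = back.get("T1")
        assert r.cpc_fwd == -1.5
        assert r.protein_db_evalues["NR"] == pytest.approx(1e-8)
        assert r.protein_db_evalues["UniRef90"] is None
        with pytest.raises(ValidationError, match="T3"):
            back.get("T3")

    def test_nonpositive_evalue_rejected(self):
        with pytest.raises(ValidationError, match="E-value"):
            EvidenceRecord("T1", -1.0, -1.0, 0.0, {})


class TestPipelineConfig:
    def test_defaults_are_the_published_thresholds(self, config):
        assert (config.min_exons, config.min_length) == (2, 200)
        assert config.evalue_max == 1e-5
        assert config.cis_window == 100_000
        assert (config.trans_abs_r_min, config.fdr_max) == (0.95, 0.05)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"cpc_rule": "either"},
            {"min_overlap_fraction": 0.0},
            {"min_overlap_fraction": 1.5},
            {"fat_keywords": ()},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            PipelineConfig(**kwargs)

    def test_trait_priority_imf_over_fat(self, config):
        # "intramuscular fat" contains "fat" too; IMF must win
        assert config.classify_trait("Intramuscular fat content") == "IMF"
        assert config.classify_trait("Leaf fat weight") == "fat_other"
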