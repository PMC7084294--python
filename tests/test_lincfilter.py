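"""Filter cascade order, threshold boundary directions, known/novel calls,
class characterization and FPKM arithmetic."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_matrix, make_transcript, random_transcript
from lincpipe.core_io import (
    AnnotationSet,
    EvidenceBundle,
    EvidenceRecord,
    PipelineConfig,
    ValidationError,
)
from lincpipe.intergenic import ClassLabel
from lincpipe.lincfilter import (
    FILTER_STAGES,
    assign_known_novel,
    characterize_sets,
    filter_lincrnas,
    fpkm_from_counts,
)

SAMPLES = [f"s{i}" for i in range(6)]


def _clean_evidence(tid, **kw):
    defaults = dict(cpc_fwd=-1.0, cpc_rev=-1.0, domain_evalue=None,
                    protein_db_evalues={"NR": None, "UniRef90": None})
    defaults.update(kw)
    return EvidenceRecord(tid, **defaults)


def _run_single(transcript, record, fpkm_row, config=None):
    """Push one already-intergenic candidate through the cascade."""
    cands = AnnotationSet([transcript])
    labels = [ClassLabel(transcript.transcript_id, "intergenic", ())]
    fpkm = make_matrix({transcript.transcript_id: fpkm_row}, SAMPLES)
    retained, report = filter_lincrnas(
        cands, labels, EvidenceBundle([record]), fpkm, config or PipelineConfig()
    )
    return retained, report


GOOD_EXONS = [(1000, 1199), (2000, 2199)]  # 2 exons, 400 nt
GOOD_FPKM = [0.6, 0.0, 0.0, 0.0, 0.0, 0.0]


class TestBoundaryDirections:
    """Each threshold behaves exactly per its configured comparison."""

    def test_single_exon_removed_at_structure(self):
        t = make_transcript("T", "chr1", [(1000, 1400)])
        retained, report = _run_single(t, _clean_evidence("T"), GOOD_FPKM)
        assert len(retained) == 0
        assert report.removal_stage("T") == "structure"

    def test_two_exons_exactly_200nt_retained(self):
        t = make_transcript("T", "chr1", [(1000, 1099), (2000, 2099)])
        retained, _ = _run_single(t, _clean_evidence("T"), GOOD_FPKM)
        assert "T" in retained

    def test_length_199_removed(self):
        t = make_transcript("T", "chr1", [(1000, 1099), (2000, 2098)])
        retained, report = _run_single(t, _clean_evidence("T"), GOOD_FPKM)
        assert report.removal_stage("T") == "structure"

    def test_cpc_zero_is_not_negative(self):
        t = make_transcript("T", "chr1", GOOD_EXONS)
        _, report = _run_single(t, _clean_evidence("T", cpc_fwd=0.0), GOOD_FPKM)
        assert report.removal_stage("T") == "cpc"

    def test_cpc_negative_both_strands_retained(self):
        t = make_transcript("T", "chr1", GOOD_EXONS)
        retained, _ = _run_single(t, _clean_evidence("T", cpc_fwd=-0.1, cpc_rev=-0.1), GOOD_FPKM)
        assert "T" in retained

    def test_cpc_any_rule_retains_one_noncoding_strand(self):
        t = make_transcript("T", "chr1", GOOD_EXONS)
        rec = _clean_evidence("T", cpc_fwd=1.0, cpc_rev=-0.5)
        _, report_both = _run_single(t, rec, GOOD_FPKM)
        retained_any, _ = _run_single(t, rec, GOOD_FPKM, PipelineConfig(cpc_rule="any"))
        assert report_both.removal_stage("T") == "cpc"
        assert "T" in retained_any

    def test_domain_evalue_exactly_1e5_is_not_a_hit(self):
        t = make_transcript("T", "chr1", GOOD_EXONS)
        retained, _ = _run_single(t, _clean_evidence("T", domain_evalue=1e-5), GOOD_FPKM)
        assert "T" in retained

    def test_domain_evalue_below_1e5_removed(self):
        t = make_transcript("T", "chr1", GOOD_EXONS)
        _, report = _run_single(t, _clean_evidence("T", domain_evalue=9.9e-6), GOOD_FPKM)
        assert report.removal_stage("T") == "domain"

    def test_protein_db_hit_in_any_database_removes(self):
        t = make_transcript("T", "chr1", GOOD_EXONS)
        rec = _clean_evidence("T", protein_db_evalues={"NR": None, "UniRef90": 1e-9})
        _, report = _run_single(t, rec, GOOD_FPKM)
        assert report.removal_stage("T") == "protein_db"

    def test_protein_db_insignificant_hit_survives(self):
        t = make_transcript("T", "chr1", GOOD_EXONS)
        rec = _clean_evidence("T", protein_db_evalues={"NR": 1e-5, "UniRef90": 0.01})
        retained, _ = _run_single(t, rec, GOOD_FPKM)
        assert "T" in retained

    def test_fpkm_below_half_everywhere_removed(self):
        t = make_transcript("T", "chr1", GOOD_EXONS)
        _, report = _run_single(t, _clean_evidence("T"), [0.49] * 6)
        assert report.removal_stage("T") == "expression"

    def test_fpkm_exactly_half_in_one_sample_retained(self):
        t = make_transcript("T", "chr1", GOOD_EXONS)
        retained, _ = _run_single(t, _clean_evidence("T"), [0.5, 0.1, 0.0, 0.0, 0.0, 0.0])
        assert "T" in retained


class TestCascadeAccounting:
    def test_counts_partition_and_chain(self, default_bundle):
        from lincpipe.intergenic import classify_transcripts

        b = default_bundle
        labels = classify_transcripts(b.candidates, b.reference)
        retained, report = filter_lincrnas(
            b.candidates, labels, b.evidence, b.fpkm, PipelineConfig()
        )
        assert tuple(s.stage for s in report.stages) == FILTER_STAGES
        for s, nxt in zip(report.stages, report.stages[1:]):
            assert s.n_retained == nxt.n_input
            assert s.n_retained + len(s.removed_ids) == s.n_input
        removed_total = sum(len(s.removed_ids) for s in report.stages)
        assert len(retained) + removed_total == len(b.candidates)

    def test_missing_evidence_is_an_error(self):
        t = make_transcript("T", "chr1", GOOD_EXONS)
        cands = AnnotationSet([t])
        labels = [ClassLabel("T", "intergenic", ())]
        fpkm = make_matrix({"T": GOOD_FPKM}, SAMPLES)
        with pytest.raises(ValidationError, match="T"):
            filter_lincrnas(cands, labels, EvidenceBundle([]), fpkm, PipelineConfig())

    def test_missing_fpkm_row_is_an_error(self):
        t = make_transcript("T", "chr1", GOOD_EXONS)
        cands = AnnotationSet([t])
        labels = [ClassLabel("T", "intergenic", ())]
        fpkm = make_matrix({"other": GOOD_FPKM}, SAMPLES)
        with pytest.raises(ValidationError, match="no FPKM row"):
            filter_lincrnas(cands, labels, EvidenceBundle([_clean_evidence("T")]), fpkm,
                            PipelineConfig())


class TestKnownNovel:
    def test_identical_coordinates_are_known(self):
        cand = make_transcript("c", "chr1", GOOD_EXONS)
        db = AnnotationSet([make_transcript("db1", "chr1", GOOD_EXONS)])
        assert assign_known_novel(AnnotationSet([cand]), db)["c"] == "known"

    def test_absent_chromosome_is_novel(self):
        cand = make_transcript("c", "chr9", GOOD_EXONS)
        db = AnnotationSet([make_transcript("db1", "chr1", GOOD_EXONS)])
        assert assign_known_novel(AnnotationSet([cand]), db)["c"] == "novel"

    def test_overlap_fraction_threshold_direction(self):
        # candidate: one 100 nt exon; db transcript shares exactly 40 positions
        cand = make_transcript("c", "chr1", [(1000, 1099)])
        db = AnnotationSet([make_transcript("db1", "chr1", [(1060, 1200)])])
        lincs = AnnotationSet([cand])
        assert assign_known_novel(lincs, db, 0.5)["c"] == "novel"
        assert assign_known_novel(lincs, db, 0.3)["c"] == "known"

    def test_bad_fraction_rejected(self):
        cand = AnnotationSet([make_transcript("c", "chr1", GOOD_EXONS)])
        with pytest.raises(ValidationError):
            assign_known_novel(cand, cand, 0.0)


class TestCharacterization:
    def test_mean_arithmetic(self):
        a = make_transcript("a", "chr1", [(1, 500)])  # 500 nt, 1 exon
        b = make_transcript("b", "chr1", [(1000, 1099), (2000, 2599)])  # 700 nt, 2 exons
        fpkm = make_matrix({"a": [2, 4, 0, 0, 0, 0], "b": [1, 1, 1, 1, 1, 1]}, SAMPLES)
        summary = characterize_sets([a, b], [], [], fpkm)
        st = summary.classes["lincRNA_novel"]
        assert st.mean_transcript_length == 600
        assert st.mean_exon_number == 1.5
        # pooled exons: 500, 100, 600
        assert st.mean_exon_length == pytest.approx(400)
        assert st.mean_fpkm == pytest.approx((1.0 + 1.0) / 2)

    def test_empty_class_has_undefined_means(self):
        a = make_transcript("a", "chr1", [(1, 500)])
        fpkm = make_matrix({"a": [1] * 6}, SAMPLES)
        summary = characterize_sets([], [a], [], fpkm)
        st = summary.classes["lincRNA_novel"]
        assert st.n == 0
        assert st.mean_transcript_length is None

    def test_matches_direct_recomputation_on_random_transcripts(self):
        rng = np.random.default_rng(5)
        ts = [random_transcript(rng, f"T{i}") for i in range(50)]
        fpkm = make_matrix({t.transcript_id: rng.uniform(0, 20, 6).tolist() for t in ts}, SAMPLES)
        st = characterize_sets(ts, [], [], fpkm).classes["lincRNA_novel"]
        assert st.mean_transcript_length == pytest.approx(
            sum(sum(e.length for e in t.exons) for t in ts) / 50
        )
        all_exons = [e.length for t in ts for e in t.exons]
        assert st.mean_exon_length == pytest.approx(sum(all_exons) / len(all_exons))
        assert st.mean_exon_number == pytest.approx(sum(t.exon_count for t in ts) / 50)

    def test_overlapping_classes_rejected(self):
        a = make_transcript("a", "chr1", [(1, 500)])
        fpkm = make_matrix({"a": [1] * 6}, SAMPLES)
        with pytest.raises(ValidationError):
            characterize_sets([a], [a], [], fpkm)


class TestFpkm:
    def test_worked_example(self):
        # library size of s1 is exactly 1e6, feature length 1 kb, count 10
        counts = make_matrix({"f": [10, 5], "g": [999_990, 999_995]}, ["s1", "s2"],
                             kind="counts")
        fpkm = fpkm_from_counts(counts, {"f": 1000, "g": 1000})
        assert fpkm.values.loc["f", "s1"] == pytest.approx(10.0)

    def test_zero_count_gives_zero_fpkm(self):
        counts = make_matrix({"f": [0, 3], "g": [5, 2]}, ["s1", "s2"], kind="counts")
        fpkm = fpkm_from_counts(counts, {"f": 100, "g": 100})
        assert fpkm.values.loc["f", "s1"] == 0.0

    def test_conservation_identity(self):
        rng = np.random.default_rng(8)
        samples = ["a", "b", "c", "d"]
        counts = make_matrix(
            {f"f{i}": rng.integers(1, 1000, 4).tolist() for i in range(20)},
            samples, kind="counts",
        )
        lengths = {f"f{i}": int(rng.integers(200, 5000)) for i in range(20)}
        fpkm = fpkm_from_counts(counts, lengths)
        lib = counts.values.sum(axis=0)
        lv = np.array([lengths[f] for f in fpkm.feature_ids], dtype=float)
        recon = (fpkm.values.to_numpy() * lv[:, None] / 1e9) * lib.to_numpy()[None, :]
        assert np.allclose(recon, counts.values.to_numpy())

    def test_zero_length_and_zero_library_rejected(self):
        counts = make_matrix({"f": [0, 0], "g": [5, 2]}, ["s1", "s2"], kind="counts")
        with pytest.raises(ValidationError, match="length"):
            fpkm_from_counts(counts, {"f": 0, "g": 100})
        zero_lib = make_matrix({"f": [0, 1]}, ["s1", "s2"], kind="counts")
        with pytest.raises(ValidationError, match="library"):
            fpkm_from_counts(zero_lib, {"f": 100})
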