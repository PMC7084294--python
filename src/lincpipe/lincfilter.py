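"""The lincRNA filter cascade and class characterization.

Six stages are applied in a fixed order to candidate transcripts:

1. intergenic  — drop candidates overlapping a reference gene locus
2. structure   — keep exon_count >= 2 and spliced length >= 200 nt
3. cpc         — keep coding-potential score < 0 (both strands by default)
4. domain      — drop any significant protein-domain hit (E < 1e-5)
5. protein_db  — drop similarity to known proteins in any database (E < 1e-5)
6. expression  — keep FPKM >= 0.5 in at least one sample

Survivors are split into known/novel against a lincRNA annotation database
by exonic-coordinate overlap, and the classes are summarized (length, exon
structure, expression) for comparison with protein-coding transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core_io import (
    AnnotationSet,
    EvidenceBundle,
    ExpressionMatrix,
    PipelineConfig,
    TranscriptModel,
    ValidationError,
)
from .intergenic import ClassLabel

__all__ = [
    "FilterReport",
    "StageResult",
    "CharacterizationSummary",
    "ClassStats",
    "FILTER_STAGES",
    "filter_lincrnas",
    "assign_known_novel",
    "characterize_sets",
    "fpkm_from_counts",
]

FILTER_STAGES = ("intergenic", "structure", "cpc", "domain", "protein_db", "expression")


@dataclass(frozen=True)
class StageResult:
    stage: str
    n_input: int
    n_retained: int
    removed_ids: Tuple[str, ...]


@dataclass
class FilterReport:
    """Per-stage accounting of the cascade; counts are non-increasing and
    retained(stage k) equals input(stage k+1)."""

    stages: List[StageResult] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return self.stages[0].n_input if self.stages else 0

    @property
    def n_retained(self) -> int:
        return self.stages[-1].n_retained if self.stages else 0

    def removal_stage(self, transcript_id: str) -> Optional[str]:
        for s in self.stages:
            if transcript_id in s.removed_ids:
                return s.stage
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [s.stage for s in self.stages],
                "n_input": [s.n_input for s in self.stages],
                "n_retained": [s.n_retained for s in self.stages],
                "n_removed": [len(s.removed_ids) for s in self.stages],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_lincrnas(
    candidates: AnnotationSet,
    class_labels: Sequence[ClassLabel],
    evidence: EvidenceBundle,
    fpkm: ExpressionMatrix,
    config: PipelineConfig,
) -> Tuple[AnnotationSet, FilterReport]:
    """Apply the six-stage cascade; returns survivors and a full report.

    A candidate that survives the intergenic stage but lacks an evidence
    record or an FPKM row raises :class:`ValidationError` — evidence gaps
    never pass silently.
    """
    if fpkm.kind != "FPKM":
        raise ValidationError("expression filter requires an FPKM matrix")
    labels = {l.transcript_id: l for l in class_labels}
    current = [t.transcript_id for t in candidates]
    report = FilterReport()

    def apply_stage(name: str, keep) -> None:
        nonlocal current
        retained, removed = [], []
        for tid in current:
            (retained if keep(tid) else removed).append(tid)
        report.stages.append(
            StageResult(name, len(current), len(retained), tuple(removed))
        )
        current = retained

    def intergenic_ok(tid: str) -> bool:
        if tid not in labels:
            raise ValidationError(f"no class label for candidate {tid!r}")
        return labels[tid].label == "intergenic"

    apply_stage("intergenic", intergenic_ok)

    def structure_ok(tid: str) -> bool:
        t = candidates.get(tid)
        return t.exon_count >= config.min_exons and t.length >= config.min_length

    apply_stage("structure", structure_ok)

    def cpc_ok(tid: str) -> bool:
        ev = evidence.get(tid)
        fwd = ev.cpc_fwd < config.cpc_max
        rev = ev.cpc_rev < config.cpc_max
        return (fwd and rev) if config.cpc_rule == "both" else (fwd or rev)

    apply_stage("cpc", cpc_ok)

    def domain_ok(tid: str) -> bool:
        e = evidence.get(tid).domain_evalue
        return e is None or not (e < config.evalue_max)

    apply_stage("domain", domain_ok)

    def protein_db_ok(tid: str) -> bool:
        for e in evidence.get(tid).protein_db_evalues.values():
            if e is not None and e < config.evalue_max:
                return False
        return True

    apply_stage("protein_db", protein_db_ok)

    def expression_ok(tid: str) -> bool:
        row = fpkm.row(tid)  # KeyError -> surfaced below
        return bool(np.any(row >= config.fpkm_min))

    def expression_ok_checked(tid: str) -> bool:
        try:
            return expression_ok(tid)
        except KeyError:
            raise ValidationError(f"no FPKM row for surviving candidate {tid!r}") from None

    apply_stage("expression", expression_ok_checked)

    return candidates.subset(current), report


# ---------------------------------------------------------------------------
# known / novel assignment
# ---------------------------------------------------------------------------


def _merged_exon_intervals(t: TranscriptModel) -> List[Tuple[int, int]]:
    # exons are already sorted and non-overlapping by invariant
    return [(e.start, e.end) for e in t.exons]


def _shared_exonic_bp(a: TranscriptModel, b: TranscriptModel) -> int:
    if a.chrom != b.chrom:
        return 0
    total = 0
    for (s1, e1) in _merged_exon_intervals(a):
        for (s2, e2) in _merged_exon_intervals(b):
            lo, hi = max(s1, s2), min(e1, e2)
            if lo <= hi:
                total += hi - lo + 1
    return total


def assign_known_novel(
    lincs: AnnotationSet,
    linc_db: AnnotationSet,
    min_overlap_fraction: float = 0.5,
) -> Dict[str, str]:
    """Label each lincRNA ``known`` or ``novel`` by exonic overlap.

    A candidate is known when some database lincRNA on the same chromosome
    shares >= ``min_overlap_fraction`` of the candidate's exonic length.
    Coordinate matching stands in for a sequence search: it is deterministic
    and needs no sequence data.
    """
    if not 0 < min_overlap_fraction <= 1:
        raise ValidationError("min_overlap_fraction must lie in (0, 1]")
    trees: Dict[str, IntervalTree] = {}
    for t in linc_db:
        span = t.span
        trees.setdefault(t.chrom, IntervalTree()).addi(span.start, span.end + 1, t.transcript_id)
    labels: Dict[str, str] = {}
    for cand in lincs:
        span = cand.span
        tree = trees.get(cand.chrom)
        label = "novel"
        if tree is not None:
            needed = min_overlap_fraction * cand.length
            for iv in tree.overlap(span.start, span.end + 1):
                db_t = linc_db.get(iv.data)
                if _shared_exonic_bp(cand, db_t) >= needed:
                    label = "known"
                    break
        labels[cand.transcript_id] = label
    return labels


# ---------------------------------------------------------------------------
# characterization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassStats:
    n: int
    mean_transcript_length: Optional[float]
    mean_exon_length: Optional[float]
    mean_exon_number: Optional[float]
    mean_fpkm: Optional[float]


@dataclass
class CharacterizationSummary:
    """Structure/expression means per transcript class.

    Mean exon length pools all exons of the class, so mean exon length times
    mean exon number need not equal mean transcript length.
    """

    classes: Dict[str, ClassStats]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, s in self.classes.items():
            rows.append(
                {
                    "class": name,
                    "n": s.n,
                    "mean_transcript_length": s.mean_transcript_length,
                    "mean_exon_length": s.mean_exon_length,
                    "mean_exon_number": s.mean_exon_number,
                    "mean_fpkm": s.mean_fpkm,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def _class_stats(transcripts: List[TranscriptModel], fpkm: ExpressionMatrix) -> ClassStats:
    if not transcripts:
        return ClassStats(0, None, None, None, None)
    lengths = [t.length for t in transcripts]
    exon_lengths = [e.length for t in transcripts for e in t.exons]
    exon_counts = [t.exon_count for t in transcripts]
    fpkm_means = [float(np.mean(fpkm.row(t.transcript_id))) for t in transcripts]
    return ClassStats(
        n=len(transcripts),
        mean_transcript_length=float(np.mean(lengths)),
        mean_exon_length=float(np.mean(exon_lengths)),
        mean_exon_number=float(np.mean(exon_counts)),
        mean_fpkm=float(np.mean(fpkm_means)),
    )


def characterize_sets(
    novel: Iterable[TranscriptModel],
    known: Iterable[TranscriptModel],
    coding: Iterable[TranscriptModel],
    fpkm: ExpressionMatrix,
) -> CharacterizationSummary:
    """Compare novel/known lincRNAs with protein-coding transcripts."""
    novel, known, coding = list(novel), list(known), list(coding)
    ids = [t.transcript_id for ts in (novel, known, coding) for t in ts]
    if len(ids) != len(set(ids)):
        raise ValidationError("characterization classes must be disjoint")
    return CharacterizationSummary(
        classes={
            "lincRNA_novel": _class_stats(novel, fpkm),
            "lincRNA_known": _class_stats(known, fpkm),
            "protein_coding": _class_stats(coding, fpkm),
        }
    )


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------


def fpkm_from_counts(
    counts: ExpressionMatrix, lengths: Mapping[str, int]
) -> ExpressionMatrix:
    """FPKM[f, s] = counts[f, s] * 1e9 / (library_size[s] * length[f])."""
    if counts.kind != "counts":
        raise ValidationError("fpkm_from_counts needs a counts matrix")
    missing = [f for f in counts.feature_ids if f not in lengths]
    if missing:
        raise ValidationError(f"no length for features: {missing[:5]}")
    length_vec = np.array([lengths[f] for f in counts.feature_ids], dtype=float)
    if np.any(length_vec <= 0):
        bad = counts.feature_ids[int(np.argmax(length_vec <= 0))]
        raise ValidationError(f"non-positive length for {bad!r}")
    mat = counts.values.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if np.any(lib <= 0):
        bad = counts.sample_ids[int(np.argmax(lib <= 0))]
        raise ValidationError(f"zero library size for sample {bad!r}")
    fpkm = mat * 1e9 / (lib[None, :] * length_vec[:, None])
    return ExpressionMatrix(
        pd.DataFrame(fpkm, index=counts.values.index, columns=counts.values.columns),
        kind="FPKM",
        groups=dict(counts.groups),
    )
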