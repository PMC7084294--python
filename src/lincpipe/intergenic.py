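"""Intergenic classification of candidate transcripts.

A candidate is intergenic when its genomic span shares no position with any
reference gene span on the same chromosome, strand-agnostically. Gene spans
(not individual transcripts or exons) define the occupied loci, so a
candidate sitting inside an intron is *not* intergenic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Tuple

from .core_io import AnnotationSet

__all__ = ["ClassLabel", "classify_transcripts", "write_class_labels"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassLabel:
    transcript_id: str
    label: str  # "intergenic" | "overlapping"
    overlapping_gene_ids: Tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.label == "intergenic") != (len(self.overlapping_gene_ids) == 0):
            raise ValueError(
                f"{self.transcript_id}: label {self.label!r} inconsistent with "
                f"{len(self.overlapping_gene_ids)} overlapping genes"
            )


def classify_transcripts(
    candidates: AnnotationSet, reference: AnnotationSet
) -> List[ClassLabel]:
    """Label each candidate intergenic or overlapping, in input order.

    Uses a per-chromosome interval tree over reference gene spans; a
    chromosome absent from the reference is allowed (its candidates are
    trivially intergenic) and logged.
    """
    if len(candidates) == 0 or len(reference) == 0:
        raise ValueError("candidate and reference sets must be non-empty")
    trees = reference.gene_span_index()
    missing_chroms = set()
    labels: List[ClassLabel] = []
    for t in candidates:
        span = t.span
        tree = trees.get(t.chrom)
        if tree is None:
            missing_chroms.add(t.chrom)
            hits: Tuple[str, ...] = ()
        else:
            # internal tree is half-open: query [start, end+1)
            hits = tuple(sorted({iv.data for iv in tree.overlap(span.start, span.end + 1)}))
        labels.append(
            ClassLabel(
                transcript_id=t.transcript_id,
                label="intergenic" if not hits else "overlapping",
                overlapping_gene_ids=hits,
            )
        )
    for chrom in sorted(missing_chroms):
        log.warning("chromosome %s absent from reference; candidates there are intergenic", chrom)
    return labels


def write_class_labels(labels: List[ClassLabel], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tlabel\toverlapping_gene_ids\n")
        for l in labels:
            fh.write(f"{l.transcript_id}\t{l.label}\t{','.join(l.overlapping_gene_ids)}\n")
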