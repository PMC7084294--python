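"""QTL co-localization of differentially expressed lincRNAs.

Each DE lincRNA locus (transcript span) is intersected with trait-labelled
QTL intervals; one overlap record per (lincRNA, QTL) pair sharing at least
one genomic position. Summaries tally fat-deposition and IMF-content
classes, per-chromosome fat counts, and per-trait-name counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

from intervaltree import IntervalTree

from .core_io import QTLRecord, TranscriptModel

__all__ = ["QTLOverlap", "QTLSummary", "colocalize_qtl", "summarize_qtl"]


@dataclass(frozen=True)
class QTLOverlap:
    lincrna_id: str
    qtl_id: str
    chrom: str
    trait_name: str
    trait_class: str
    overlap_bp: int

    def __post_init__(self) -> None:
        if self.overlap_bp < 1:
            raise ValueError("overlap_bp must be >= 1")


@dataclass
class QTLSummary:
    """Tallies over an overlap list; percentages are None when undefined."""

    total_overlaps: int
    fat_overlaps: int
    imf_overlaps: int
    fat_by_chrom: Dict[str, int] = field(default_factory=dict)
    by_trait_name: Dict[str, int] = field(default_factory=dict)

    @property
    def fat_pct(self) -> Optional[float]:
        if self.total_overlaps == 0:
            return None
        return 100.0 * self.fat_overlaps / self.total_overlaps

    @property
    def imf_of_fat_pct(self) -> Optional[float]:
        if self.fat_overlaps == 0:
            return None
        return 100.0 * self.imf_overlaps / self.fat_overlaps

    def report_text(self) -> str:
        def pct(v: Optional[float]) -> str:
            return "NA" if v is None else f"{v:.1f}%"

        lines = [
            f"QTL overlaps (lincRNA x QTL pairs): {self.total_overlaps}",
            f"fat-deposition overlaps: {self.fat_overlaps} ({pct(self.fat_pct)} of total)",
            f"IMF-content overlaps: {self.imf_overlaps} ({pct(self.imf_of_fat_pct)} of fat)",
            "fat overlaps by chromosome:",
        ]
        for chrom in sorted(self.fat_by_chrom):
            lines.append(f"  {chrom}\t{self.fat_by_chrom[chrom]}")
        lines.append("overlaps by trait name:")
        for trait, n in sorted(self.by_trait_name.items(), key=lambda kv: (-kv[1], kv[0])):
            lines.append(f"  {trait}\t{n}")
        return "\n".join(lines) + "\n"


def colocalize_qtl(
    de_lincs: Iterable[TranscriptModel], qtls: List[QTLRecord]
) -> List[QTLOverlap]:
    """All (DE lincRNA, QTL) pairs whose intervals share >= 1 position.

    Pair-counting: a QTL hit by two lincRNAs contributes two records.
    Output order follows the lincRNA input order, QTLs by ascending id
    within each lincRNA.
    """
    trees: Dict[str, IntervalTree] = {}
    for i, q in enumerate(qtls):
        trees.setdefault(q.interval.chrom, IntervalTree()).addi(
            q.interval.start, q.interval.end + 1, i
        )
    overlaps: List[QTLOverlap] = []
    for linc in de_lincs:
        span = linc.span
        tree = trees.get(linc.chrom)
        if tree is None:
            continue
        hits = sorted(iv.data for iv in tree.overlap(span.start, span.end + 1))
        for i in hits:
            q = qtls[i]
            overlaps.append(
                QTLOverlap(
                    lincrna_id=linc.transcript_id,
                    qtl_id=q.qtl_id,
                    chrom=q.interval.chrom,
                    trait_name=q.trait_name,
                    trait_class=q.trait_class,
                    overlap_bp=span.overlap_bp(q.interval),
                )
            )
    return overlaps


def summarize_qtl(overlaps: List[QTLOverlap]) -> QTLSummary:
    """Count totals, fat-deposition and IMF classes, and marginal tallies."""
    fat_classes = ("IMF", "fat_other")
    fat_by_chrom: Dict[str, int] = {}
    by_trait: Dict[str, int] = {}
    fat = imf = 0
    for o in overlaps:
        by_trait[o.trait_name] = by_trait.get(o.trait_name, 0) + 1
        if o.trait_class in fat_classes:
            fat += 1
            fat_by_chrom[o.chrom] = fat_by_chrom.get(o.chrom, 0) + 1
        if o.trait_class == "IMF":
            imf += 1
    return QTLSummary(
        total_overlaps=len(overlaps),
        fat_overlaps=fat,
        imf_overlaps=imf,
        fat_by_chrom=fat_by_chrom,
        by_trait_name=by_trait,
    )
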