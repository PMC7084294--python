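"""Domain types, thresholds, and readers/writers for the pipeline's formats.

The pipeline is coordinate- and evidence-table-driven: transcript structures
come from GTF, QTL intervals from BED-like files (0-based half-open,
converted at the boundary), expression matrices from TSV, and per-transcript
coding-potential/homology evidence from a TSV produced upstream.

All internal coordinates are 1-based inclusive (GTF convention).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "AnnotationSet",
    "ExpressionMatrix",
    "EvidenceRecord",
    "EvidenceBundle",
    "QTLRecord",
    "PipelineConfig",
    "GtfParseError",
    "ValidationError",
    "read_gtf",
    "write_gtf",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_qtl_bed",
    "write_qtl_bed",
    "read_evidence",
    "write_evidence",
]

BIOTYPES = ("protein_coding", "lincRNA_known", "lincRNA_novel", "candidate", "other")
UNSTRANDED = "."
_STRANDS = ("+", "-", UNSTRANDED)


class GtfParseError(ValueError):
    """Malformed line in a GTF/BED input; message carries the line number."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Closed interval [start, end] on a chromosome, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(f"end {self.end} < start {self.start}")
        if self.strand not in _STRANDS:
            raise ValidationError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-agnostic: any shared genomic position on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if not self.overlaps(other):
            return 0
        return min(self.end, other.end) - max(self.start, other.start) + 1

    def gap_to(self, other: "GenomicInterval") -> Optional[int]:
        """Positions strictly between the two intervals; 0 if they overlap.

        None for intervals on different chromosomes.
        """
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if other.start > self.end:
            return other.start - self.end - 1
        return self.start - other.end - 1


@dataclass(frozen=True)
class TranscriptModel:
    """Exon-structured transcript.

    Exons are stored sorted by start, pairwise non-overlapping, all on one
    chromosome and strand. ``length`` is the spliced (exonic) length;
    ``span`` is the genomic footprint from first to last exon.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[GenomicInterval, ...]
    biotype: str = "candidate"

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValidationError("transcript_id must be non-empty")
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript needs >= 1 exon")
        if self.strand not in _STRANDS:
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"{self.transcript_id}: bad biotype {self.biotype!r}")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        for e in exons:
            if e.chrom != self.chrom:
                raise ValidationError(
                    f"{self.transcript_id}: exon on {e.chrom} but transcript on {self.chrom}"
                )
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"{self.transcript_id}: overlapping/duplicate exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def with_biotype(self, biotype: str) -> "TranscriptModel":
        return replace(self, biotype=biotype)


class AnnotationSet:
    """A collection of transcripts with gene and interval indexes."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self._by_id: Dict[str, TranscriptModel] = {}
        self._by_gene: Dict[str, List[TranscriptModel]] = {}
        for t in transcripts:
            if t.transcript_id in self._by_id:
                raise ValidationError(f"duplicate transcript_id {t.transcript_id!r}")
            self._by_id[t.transcript_id] = t
            self._by_gene.setdefault(t.gene_id, []).append(t)
        self._span_trees: Optional[Dict[str, IntervalTree]] = None
        self._gene_trees: Optional[Dict[str, IntervalTree]] = None

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._by_id.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    @property
    def transcript_ids(self) -> List[str]:
        return list(self._by_id)

    @property
    def gene_ids(self) -> List[str]:
        return list(self._by_gene)

    def get(self, transcript_id: str) -> TranscriptModel:
        return self._by_id[transcript_id]

    def gene_transcripts(self, gene_id: str) -> List[TranscriptModel]:
        return list(self._by_gene[gene_id])

    def gene_span(self, gene_id: str) -> GenomicInterval:
        """Genomic footprint of a gene: min exon start to max exon end."""
        ts = self._by_gene[gene_id]
        chroms = {t.chrom for t in ts}
        if len(chroms) > 1:
            raise ValidationError(f"gene {gene_id} spans chromosomes {sorted(chroms)}")
        return GenomicInterval(
            ts[0].chrom,
            min(t.span.start for t in ts),
            max(t.span.end for t in ts),
        )

    def subset(self, transcript_ids: Iterable[str]) -> "AnnotationSet":
        return AnnotationSet(self._by_id[i] for i in transcript_ids)

    def gene_span_index(self) -> Dict[str, IntervalTree]:
        """chrom -> IntervalTree over gene spans (half-open internally)."""
        if self._gene_trees is None:
            trees: Dict[str, IntervalTree] = {}
            for gid in self._by_gene:
                span = self.gene_span(gid)
                trees.setdefault(span.chrom, IntervalTree()).addi(
                    span.start, span.end + 1, gid
                )
            self._gene_trees = trees
        return self._gene_trees


@dataclass
class ExpressionMatrix:
    """Features x samples expression values with per-sample group labels.

    ``kind`` is either ``counts`` (non-negative integers) or ``FPKM``
    (non-negative reals). Backed by a pandas DataFrame; feature and sample
    order is preserved.
    """

    values: pd.DataFrame
    kind: str
    groups: Dict[str, str]

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "FPKM"):
            raise ValidationError(f"kind must be 'counts' or 'FPKM', got {self.kind!r}")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValidationError("feature and sample ids must be unique")
        arr = self.values.to_numpy(dtype=float)
        if np.any(~np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        if np.any(arr < 0):
            f, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value at ({self.values.index[f]}, {self.values.columns[s]})"
            )
        if self.kind == "counts":
            frac = arr != np.floor(arr)
            if np.any(frac):
                f, s = np.argwhere(frac)[0]
                raise ValidationError(
                    f"non-integer count at ({self.values.index[f]}, "
                    f"{self.values.columns[s]}): {arr[f, s]}"
                )
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValidationError(f"samples missing from group map: {missing}")

    @property
    def feature_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)

    def row(self, feature_id: str) -> np.ndarray:
        if feature_id not in self.values.index:
            raise KeyError(f"no expression row for {feature_id!r}")
        return self.values.loc[feature_id].to_numpy(dtype=float)

    def group_samples(self, group: str) -> List[str]:
        out = [s for s in self.values.columns if self.groups[s] == group]
        if not out:
            raise ValidationError(f"unknown group {group!r}")
        return out

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)].copy(), self.kind, dict(self.groups))


@dataclass(frozen=True)
class EvidenceRecord:
    """Coding-potential and homology evidence for one transcript.

    CPC scores are signed (negative = non-coding) and computed on both
    strands upstream; E-values are the best (smallest) hits from the
    protein-domain search and from each protein database, None when the
    search returned no hit at all.
    """

    transcript_id: str
    cpc_fwd: float
    cpc_rev: float
    domain_evalue: Optional[float] = None
    protein_db_evalues: Mapping[str, Optional[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, e in [("domain", self.domain_evalue)] + list(
            self.protein_db_evalues.items()
        ):
            if e is not None and e <= 0:
                raise ValidationError(
                    f"{self.transcript_id}: E-value for {name} must be > 0, got {e}"
                )


class EvidenceBundle:
    """Per-transcript evidence records; a missing transcript is an error
    at lookup time, never a silent pass."""

    def __init__(self, records: Iterable[EvidenceRecord]):
        self._records: Dict[str, EvidenceRecord] = {}
        for r in records:
            if r.transcript_id in self._records:
                raise ValidationError(f"duplicate evidence for {r.transcript_id!r}")
            self._records[r.transcript_id] = r

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._records

    def get(self, transcript_id: str) -> EvidenceRecord:
        try:
            return self._records[transcript_id]
        except KeyError:
            raise ValidationError(
                f"no evidence computed for transcript {transcript_id!r}"
            ) from None

    @property
    def db_names(self) -> List[str]:
        names: List[str] = []
        for r in self._records.values():
            for n in r.protein_db_evalues:
                if n not in names:
                    names.append(n)
        return names


@dataclass(frozen=True)
class QTLRecord:
    """Trait-labelled genomic interval from a QTL database dump."""

    interval: GenomicInterval
    qtl_id: str
    trait_name: str
    trait_class: str

    def __post_init__(self) -> None:
        if not self.trait_name.strip():
            raise ValidationError(f"{self.qtl_id}: empty trait name")
        if self.trait_class not in ("IMF", "fat_other", "non_fat"):
            raise ValidationError(f"{self.qtl_id}: bad trait_class {self.trait_class!r}")


@dataclass
class PipelineConfig:
    """Every threshold of the pipeline, with its comparison direction fixed.

    min_exons / min_length: structure filter, both inclusive (>=).
    cpc_max: coding-potential cutoff, strict < on both strands by default
        (``cpc_rule='any'`` retains transcripts non-coding on one strand).
    evalue_max: strict < marks a domain/protein hit significant.
    fpkm_min: retained if FPKM >= fpkm_min in at least one sample.
    cis_window: neighbour gap strictly < this many nt.
    trans_abs_r_min: inclusive >= on |Pearson r|.
    fdr_max / de_padj_max: strict <.
    de_abs_log2fc_min: strict > on |log2 fold change|.
    """

    min_exons: int = 2
    min_length: int = 200
    cpc_max: float = 0.0
    cpc_rule: str = "both"
    evalue_max: float = 1e-5
    fpkm_min: float = 0.5
    cis_window: int = 100_000
    trans_abs_r_min: float = 0.95
    fdr_max: float = 0.05
    de_abs_log2fc_min: float = 1.0
    de_padj_max: float = 0.05
    min_overlap_fraction: float = 0.5
    imf_keywords: Tuple[str, ...] = ("intramuscular fat", "imf")
    fat_keywords: Tuple[str, ...] = ("fat", "backfat", "leaf fat")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_exons", "min_length", "cpc_max", "evalue_max", "fpkm_min",
            "cis_window", "trans_abs_r_min", "fdr_max", "de_abs_log2fc_min",
            "de_padj_max", "min_overlap_fraction",
        ):
            if not math.isfinite(float(getattr(self, name))):
                raise ValidationError(f"threshold {name} must be finite")
        if self.cpc_rule not in ("both", "any"):
            raise ValidationError("cpc_rule must be 'both' or 'any'")
        if not 0 < self.min_overlap_fraction <= 1:
            raise ValidationError("min_overlap_fraction must lie in (0, 1]")
        if not self.imf_keywords or not self.fat_keywords:
            raise ValidationError("keyword lists must be non-empty")
        object.__setattr__(self, "imf_keywords", tuple(k.lower() for k in self.imf_keywords))
        object.__setattr__(self, "fat_keywords", tuple(k.lower() for k in self.fat_keywords))

    def classify_trait(self, trait_name: str) -> str:
        """IMF beats fat_other beats non_fat; lower-cased substring match."""
        low = trait_name.lower()
        if any(k in low for k in self.imf_keywords):
            return "IMF"
        if any(k in low for k in self.fat_keywords):
            return "fat_other"
        return "non_fat"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("imf_keywords", "fat_keywords"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path, biotype_attr: str = "biotype") -> AnnotationSet:
    """Parse exon features of a GTF into an :class:`AnnotationSet`.

    Only ``exon`` rows are used; each must carry ``transcript_id`` and
    ``gene_id`` attributes. The biotype is taken from ``biotype_attr`` when
    present (unknown labels collapse to ``other``), else ``candidate``.
    """
    path = Path(path)
    exons: Dict[str, List[GenomicInterval]] = {}
    meta: Dict[str, Tuple[str, str, str, str]] = {}
    order: List[str] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path.name}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"{path.name}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if end < start or start < 1:
                raise GtfParseError(
                    f"{path.name}:{lineno}: invalid interval {start}-{end}"
                )
            attr = _parse_attributes(attrs)
            tid = attr.get("transcript_id")
            gid = attr.get("gene_id")
            if not tid or not gid:
                raise GtfParseError(
                    f"{path.name}:{lineno}: exon lacks transcript_id/gene_id attributes"
                )
            if strand not in _STRANDS:
                raise GtfParseError(f"{path.name}:{lineno}: bad strand {strand!r}")
            exon = GenomicInterval(chrom, start, end, strand)
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
                biotype = attr.get(biotype_attr, "candidate")
                if biotype not in BIOTYPES:
                    biotype = "other"
                meta[tid] = (gid, chrom, strand, biotype)
            else:
                if any(e.start == start and e.end == end and e.chrom == chrom for e in exons[tid]):
                    raise ValidationError(
                        f"{path.name}:{lineno}: duplicate exon {chrom}:{start}-{end} "
                        f"for transcript {tid!r}"
                    )
            exons[tid].append(exon)
    transcripts = []
    for tid in order:
        gid, chrom, strand, biotype = meta[tid]
        transcripts.append(
            TranscriptModel(
                transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand,
                exons=tuple(exons[tid]), biotype=biotype,
            )
        )
    return AnnotationSet(transcripts)


def write_gtf(annotation: AnnotationSet, path: str | Path, source: str = "lincpipe") -> None:
    """Write exon rows (one per exon, transcripts in set order)."""
    with Path(path).open("w") as fh:
        for t in annotation:
            for e in t.exons:
                attrs = (
                    f'transcript_id "{t.transcript_id}"; gene_id "{t.gene_id}"; '
                    f'biotype "{t.biotype}";'
                )
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{e.start}\t{e.end}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def read_expression_matrix(
    path: str | Path, kind: str, group_map: Mapping[str, str]
) -> ExpressionMatrix:
    """TSV with a header row of sample ids and feature ids in column 1."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, kind=kind, groups=dict(group_map))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values
    if matrix.kind == "counts":
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="feature_id", float_format="%.12g")


# ---------------------------------------------------------------------------
# QTL BED
# ---------------------------------------------------------------------------


def read_qtl_bed(path: str | Path, config: PipelineConfig) -> List[QTLRecord]:
    """BED4/BED5: chrom, 0-based start, half-open end, trait name[, id].

    Coordinates convert to 1-based inclusive as (start+1, end). The trait
    class is assigned from the config keyword lists (IMF first, then fat).
    """
    path = Path(path)
    records: List[QTLRecord] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise GtfParseError(
                    f"{path.name}:{lineno}: BED-like QTL rows need >= 4 columns"
                )
            chrom, start_s, end_s, trait = fields[0], fields[1], fields[2], fields[3]
            try:
                start0, end0 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from None
            if end0 <= start0:
                raise GtfParseError(
                    f"{path.name}:{lineno}: end {end0} must exceed start {start0}"
                )
            if not trait.strip():
                raise GtfParseError(f"{path.name}:{lineno}: empty trait name")
            qtl_id = fields[4] if len(fields) > 4 and fields[4] else f"QTL{lineno}"
            records.append(
                QTLRecord(
                    interval=GenomicInterval(chrom, start0 + 1, end0),
                    qtl_id=qtl_id,
                    trait_name=trait,
                    trait_class=config.classify_trait(trait),
                )
            )
    return records


def write_qtl_bed(records: Sequence[QTLRecord], path: str | Path) -> None:
    """Inverse of :func:`read_qtl_bed`: emits 0-based half-open rows."""
    with Path(path).open("w") as fh:
        for r in records:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start - 1}\t{r.interval.end}\t"
                f"{r.trait_name}\t{r.qtl_id}\n"
            )


# ---------------------------------------------------------------------------
# evidence tables
# ---------------------------------------------------------------------------


def _parse_optional_float(cell: str, lineno: int, path: Path) -> Optional[float]:
    cell = cell.strip()
    if cell == "" or cell.upper() == "NA":
        return None
    try:
        return float(cell)
    except ValueError:
        raise GtfParseError(f"{path.name}:{lineno}: bad E-value {cell!r}") from None


def read_evidence(path: str | Path) -> EvidenceBundle:
    """Evidence TSV: transcript_id, cpc_fwd, cpc_rev, best_domain_evalue,
    then one best_hit_evalue_<db> column per protein database; empty cells
    mean the search returned no hit."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["transcript_id", "cpc_fwd", "cpc_rev", "best_domain_evalue"]
        if header[: len(expected)] != expected:
            raise GtfParseError(
                f"{path.name}:1: header must start with {expected}, got {header[:4]}"
            )
        db_names = []
        for col in header[len(expected):]:
            if not col.startswith("best_hit_evalue_"):
                raise GtfParseError(f"{path.name}:1: unexpected column {col!r}")
            db_names.append(col[len("best_hit_evalue_"):])
        records = []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise GtfParseError(
                    f"{path.name}:{lineno}: expected {len(header)} columns, got {len(cells)}"
                )
            tid = cells[0]
            try:
                cpc_fwd, cpc_rev = float(cells[1]), float(cells[2])
            except ValueError:
                raise GtfParseError(f"{path.name}:{lineno}: bad CPC score") from None
            domain = _parse_optional_float(cells[3], lineno, path)
            dbs = {
                name: _parse_optional_float(cells[4 + i], lineno, path)
                for i, name in enumerate(db_names)
            }
            records.append(
                EvidenceRecord(
                    transcript_id=tid, cpc_fwd=cpc_fwd, cpc_rev=cpc_rev,
                    domain_evalue=domain, protein_db_evalues=dbs,
                )
            )
    return EvidenceBundle(records)


def write_evidence(bundle: EvidenceBundle, path: str | Path) -> None:
    db_names = bundle.db_names
    cols = ["transcript_id", "cpc_fwd", "cpc_rev", "best_domain_evalue"] + [
        f"best_hit_evalue_{n}" for n in db_names
    ]
    def fmt(v: Optional[float]) -> str:
        return "" if v is None else f"{v:.6g}"
    with Path(path).open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for tid in sorted(r for r in bundle._records):
            r = bundle.get(tid)
            row = [tid, f"{r.cpc_fwd:.6g}", f"{r.cpc_rev:.6g}", fmt(r.domain_evalue)]
            row += [fmt(r.protein_db_evalues.get(n)) for n in db_names]
            fh.write("\t".join(row) + "\n")
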