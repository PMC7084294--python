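"""Seeded synthetic input bundles with planted ground truth.

The generator emulates the study design the pipeline targets: two pig
breeds (fat-type and lean-type) with three RNA-seq samples each. It lays
features out on 18 autosomes in non-overlapping 1 Mb blocks so that every
spatial relation is planted, never accidental:

* true lincRNAs (known and novel) that pass every filter stage;
* one cohort of decoys per filter stage, each failing exactly that stage;
* protein-coding genes, a few placed < 100 kb from a DE lincRNA (cis
  partners), the rest far from every lincRNA;
* QTL intervals covering designated DE lincRNA loci, plus background QTLs
  that overlap nothing;
* a negative-binomial count matrix with planted fold changes, and an FPKM
  matrix carrying planted expression correlations that are exact *sample*
  correlations (at n = 6, an |r| >= 0.95 cutoff leaves no room for
  in-expectation planting).

Unplanted ("null") expression profiles are redrawn until their correlation
with every DE lincRNA profile stays below ``max_null_abs_r``, so the
planted trans edge set is exactly recoverable for any seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core_io import (
    AnnotationSet,
    EvidenceBundle,
    EvidenceRecord,
    ExpressionMatrix,
    GenomicInterval,
    PipelineConfig,
    QTLRecord,
    TranscriptModel,
    write_evidence,
    write_expression_matrix,
    write_gtf,
    write_qtl_bed,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticBundle",
    "GenerationError",
    "generate_dataset",
    "generate_correlated_pair",
]

DECOY_STAGES = ("intergenic", "structure", "cpc", "domain", "protein_db", "expression")

IMF_TRAITS = ("Intramuscular fat content",)
FAT_TRAITS = ("Average backfat thickness", "Backfat at last rib", "Leaf fat weight")
NON_FAT_TRAITS = ("Teat number", "Loin muscle area", "Average daily gain", "Body weight at birth")


class GenerationError(RuntimeError):
    """Requested bundle cannot be placed (e.g. chromosomes too short)."""


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; the defaults are the study conditions.

    ``rng_seed`` is mandatory — bundles are only meaningful when
    reproducible. Counts are negative-binomial with mean drawn lognormally
    (``exp(N(nb_log_mu, nb_log_sigma))``) and size ``nb_size`` (variance
    m + m^2/size); planted DE features split the fold change symmetrically
    across the two groups.
    """

    rng_seed: int
    n_coding_genes: int = 560
    n_lincs_known: int = 20
    n_lincs_novel: int = 8
    n_de_lincs: int = 10
    n_de_genes: int = 60
    n_decoys_per_stage: int = 5
    samples_per_group: int = 3
    group_names: Tuple[str, str] = ("Wei", "Yorkshire")
    n_chroms: int = 18
    chrom_length: int = 40_000_000
    block_size: int = 1_000_000
    nb_log_mu: float = 5.5
    nb_log_sigma: float = 0.8
    nb_size: float = 50.0
    planted_log2fc: float = 3.0
    n_trans_pairs: int = 50
    trans_r: float = 0.99
    trans_negative_frac: float = 0.2
    n_cis_pairs: int = 6
    cis_r: float = 0.9
    qtls_per_de_linc: int = 3
    n_background_qtls: int = 30
    imf_trait_frac: float = 0.25
    fat_trait_frac: float = 0.35
    max_null_abs_r: float = 0.8

    def __post_init__(self) -> None:
        for name in (
            "n_coding_genes", "n_lincs_known", "n_lincs_novel", "n_de_lincs",
            "n_de_genes", "n_decoys_per_stage", "n_trans_pairs", "n_cis_pairs",
            "qtls_per_de_linc", "n_background_qtls",
        ):
            if getattr(self, name) < 0:
                raise GenerationError(f"{name} must be >= 0")
        n_lincs = self.n_lincs_known + self.n_lincs_novel
        if self.n_de_lincs > n_lincs:
            raise GenerationError("n_de_lincs exceeds the number of lincRNAs")
        if self.n_cis_pairs > self.n_de_lincs:
            raise GenerationError("n_cis_pairs exceeds n_de_lincs")
        if self.n_de_genes > self.n_coding_genes:
            raise GenerationError("n_de_genes exceeds n_coding_genes")
        if self.samples_per_group < 2:
            raise GenerationError("need >= 2 samples per group")
        if not abs(self.trans_r) <= 1 or not abs(self.cis_r) <= 1:
            raise GenerationError("correlation targets must lie in [-1, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth of one bundle."""

    linc_ids_known: List[str]
    linc_ids_novel: List[str]
    decoy_stage: Dict[str, str]
    de_linc_log2fc: Dict[str, float]
    de_gene_log2fc: Dict[str, float]
    cis_pairs: List[Tuple[str, str, int, float]]  # (linc, gene, gap_bp, target r)
    trans_pairs: List[Tuple[str, str, float]]  # (linc, gene, target r)
    qtl_hits: List[Tuple[str, str, str]]  # (linc, qtl_id, trait_class)

    @property
    def linc_ids(self) -> List[str]:
        return self.linc_ids_known + self.linc_ids_novel

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


@dataclass
class SyntheticBundle:
    out_dir: Path
    files: Dict[str, Path]
    truth: SyntheticTruth
    config: GeneratorConfig
    candidates: AnnotationSet
    reference: AnnotationSet
    linc_db: AnnotationSet
    evidence: EvidenceBundle
    counts: ExpressionMatrix
    fpkm: ExpressionMatrix
    qtls: List[QTLRecord]
    groups: Dict[str, str]


# ---------------------------------------------------------------------------
# exact-sample-correlation construction
# ---------------------------------------------------------------------------


def _unit_centered(rng: np.random.Generator, n: int) -> np.ndarray:
    """A centered unit-norm vector drawn isotropically."""
    while True:
        v = rng.standard_normal(n)
        v = v - v.mean()
        norm = np.linalg.norm(v)
        if norm > 1e-9:
            return v / norm


def _orthogonal_unit(rng: np.random.Generator, u: np.ndarray) -> np.ndarray:
    """A centered unit vector orthogonal to the centered unit vector u."""
    while True:
        w = _unit_centered(rng, u.size)
        w = w - (w @ u) * u
        norm = np.linalg.norm(w)
        if norm > 1e-9:
            return w / norm


def generate_correlated_pair(
    r_target: float, n: int, seed: int | np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Two n-vectors whose *sample* Pearson correlation equals r_target exactly.

    y is built as r*u + sqrt(1-r^2)*w from the centered, normalized draw u
    of x and an orthogonalized independent draw w, so the construction is
    exact, not merely in expectation.
    """
    if not -1.0 <= r_target <= 1.0:
        raise ValueError("|r_target| must be <= 1")
    if n < 3:
        raise ValueError("need n >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.standard_normal(n)
    u = x - x.mean()
    u = u / np.linalg.norm(u)
    w = _orthogonal_unit(rng, u)
    y = r_target * u + np.sqrt(max(0.0, 1.0 - r_target**2)) * w
    return x, y


# ---------------------------------------------------------------------------
# transcript construction
# ---------------------------------------------------------------------------


def _build_transcript(
    rng: np.random.Generator,
    tid: str,
    gid: str,
    chrom: str,
    anchor: int,
    n_exons: int,
    exon_len_range: Tuple[int, int],
    intron_len_range: Tuple[int, int],
    biotype: str = "candidate",
) -> TranscriptModel:
    strand = "+" if rng.random() < 0.5 else "-"
    exons = []
    pos = anchor
    for i in range(n_exons):
        ln = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
        exons.append(GenomicInterval(chrom, pos, pos + ln - 1, strand))
        pos += ln + int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
    return TranscriptModel(tid, gid, chrom, strand, tuple(exons), biotype)


class _BlockAllocator:
    """Hands out non-overlapping 1 Mb blocks chromosome-major."""

    def __init__(self, cfg: GeneratorConfig):
        self.cfg = cfg
        self.per_chrom = cfg.chrom_length // cfg.block_size
        self.total = self.per_chrom * cfg.n_chroms
        self.i = 0

    def next(self) -> Tuple[str, int]:
        if self.i >= self.total:
            raise GenerationError(
                f"chromosomes too short: need more than {self.total} feature blocks"
            )
        chrom = f"chr{self.i // self.per_chrom + 1}"
        start = (self.i % self.per_chrom) * self.cfg.block_size + 1
        self.i += 1
        return chrom, start


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def generate_dataset(cfg: GeneratorConfig, out_dir: str | Path) -> SyntheticBundle:
    """Write a complete input bundle under ``out_dir`` and return it.

    Outputs: reference.gtf (protein-coding annotation), linc_db.gtf (known
    lincRNA database stand-in), candidates.gtf, evidence.tsv, counts.tsv,
    fpkm.tsv, qtls.bed, groups.tsv, truth.json, manifest.json. Identical
    config + seed gives a byte-identical bundle.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    alloc = _BlockAllocator(cfg)
    n_samples = 2 * cfg.samples_per_group
    samples = [f"{g}_{i+1}" for g in cfg.group_names for i in range(cfg.samples_per_group)]
    groups = {s: s.rsplit("_", 1)[0] for s in samples}

    # --- lincRNAs ---------------------------------------------------------
    linc_known = [f"LINC_K{i+1:03d}" for i in range(cfg.n_lincs_known)]
    linc_novel = [f"LINC_N{i+1:03d}" for i in range(cfg.n_lincs_novel)]
    linc_ids = linc_known + linc_novel
    linc_models: Dict[str, TranscriptModel] = {}
    linc_blocks: Dict[str, Tuple[str, int]] = {}
    for tid in linc_ids:
        chrom, bstart = alloc.next()
        linc_blocks[tid] = (chrom, bstart)
        linc_models[tid] = _build_transcript(
            rng, tid, f"G_{tid}", chrom, bstart + 200_000,
            n_exons=int(rng.integers(2, 5)), exon_len_range=(120, 600),
            intron_len_range=(200, 2000),
        )

    # DE lincRNAs: mostly known, a couple novel (mirrors the 22+2 split)
    n_de_novel = min(2, cfg.n_de_lincs, cfg.n_lincs_novel)
    de_lincs = linc_known[: cfg.n_de_lincs - n_de_novel] + linc_novel[:n_de_novel]
    if len(de_lincs) < cfg.n_de_lincs:
        de_lincs = (linc_ids[: cfg.n_de_lincs])

    # --- coding genes -----------------------------------------------------
    gene_ids = [f"ENSG{i+1:05d}" for i in range(cfg.n_coding_genes)]
    gene_models: Dict[str, TranscriptModel] = {}
    cis_pairs: List[Tuple[str, str, int, float]] = []
    cis_gene_ids = gene_ids[: cfg.n_cis_pairs]
    for i, gid in enumerate(cis_gene_ids):
        linc = de_lincs[i]
        chrom, _ = linc_blocks[linc]
        gap = int(rng.integers(5_000, 95_000))
        gstart = linc_models[linc].span.end + gap + 1
        gene_models[gid] = _build_transcript(
            rng, f"{gid}.t1", gid, chrom, gstart,
            n_exons=int(rng.integers(4, 9)), exon_len_range=(150, 400),
            intron_len_range=(200, 800), biotype="protein_coding",
        )
        actual_gap = linc_models[linc].span.gap_to(gene_models[gid].span)
        assert actual_gap == gap
        cis_pairs.append((linc, gid, int(actual_gap), cfg.cis_r))
    for gid in gene_ids[cfg.n_cis_pairs:]:
        chrom, bstart = alloc.next()
        anchor = bstart + 400_000 + int(rng.integers(0, 100_000))
        gene_models[gid] = _build_transcript(
            rng, f"{gid}.t1", gid, chrom, anchor,
            n_exons=int(rng.integers(6, 13)), exon_len_range=(150, 400),
            intron_len_range=(200, 2000), biotype="protein_coding",
        )

    # --- decoys, one cohort per stage ------------------------------------
    decoy_stage: Dict[str, str] = {}
    decoy_models: Dict[str, TranscriptModel] = {}
    non_cis_genes = gene_ids[cfg.n_cis_pairs:]
    for stage in DECOY_STAGES:
        for j in range(cfg.n_decoys_per_stage):
            tid = f"DECOY_{stage.upper()}_{j+1:02d}"
            decoy_stage[tid] = stage
            if stage == "intergenic":
                if not non_cis_genes:
                    raise GenerationError("intergenic decoys need a coding gene to overlap")
                host = gene_models[non_cis_genes[j % len(non_cis_genes)]]
                decoy_models[tid] = _build_transcript(
                    rng, tid, f"G_{tid}", host.chrom, host.span.start + 50,
                    n_exons=2, exon_len_range=(150, 300), intron_len_range=(100, 300),
                )
            elif stage == "structure":
                chrom, bstart = alloc.next()
                anchor = bstart + 450_000
                if j % 2 == 0:  # mono-exonic, long enough
                    decoy_models[tid] = _build_transcript(
                        rng, tid, f"G_{tid}", chrom, anchor,
                        n_exons=1, exon_len_range=(300, 800), intron_len_range=(1, 1),
                    )
                else:  # two exons but spliced length < 200
                    decoy_models[tid] = _build_transcript(
                        rng, tid, f"G_{tid}", chrom, anchor,
                        n_exons=2, exon_len_range=(80, 99), intron_len_range=(200, 500),
                    )
            else:
                chrom, bstart = alloc.next()
                decoy_models[tid] = _build_transcript(
                    rng, tid, f"G_{tid}", chrom, bstart + 450_000,
                    n_exons=int(rng.integers(2, 5)), exon_len_range=(120, 600),
                    intron_len_range=(200, 2000),
                )

    candidate_models = list(linc_models.values()) + list(decoy_models.values())
    candidates = AnnotationSet(candidate_models)
    reference = AnnotationSet(gene_models.values())

    # --- lincRNA database: known lincs with jittered boundaries -----------
    db_models = []
    for tid in linc_known:
        t = linc_models[tid]
        ext5 = int(rng.integers(0, 200))
        ext3 = int(rng.integers(0, 200))
        exons = list(t.exons)
        first = exons[0]
        exons[0] = GenomicInterval(
            first.chrom, max(1, first.start - ext5), first.end, first.strand
        )
        last = exons[-1]
        exons[-1] = GenomicInterval(last.chrom, last.start, last.end + ext3, last.strand)
        db_models.append(
            TranscriptModel(f"ALDB_{tid}", f"ALDBG_{tid}", t.chrom, t.strand,
                            tuple(exons), "lincRNA_known")
        )
    linc_db = AnnotationSet(db_models)

    # --- evidence ---------------------------------------------------------
    def clean_cpc() -> Tuple[float, float]:
        return (float(rng.uniform(-3.0, -0.5)), float(rng.uniform(-3.0, -0.5)))

    evidence_records: List[EvidenceRecord] = []
    for t in candidate_models:
        tid = t.transcript_id
        stage = decoy_stage.get(tid)
        cpc_fwd, cpc_rev = clean_cpc()
        domain: Optional[float] = None
        nr: Optional[float] = None
        uniref: Optional[float] = None
        if stage == "cpc":
            # coding potential on exactly one strand (>= 0 fails the < 0 rule)
            if rng.random() < 0.5:
                cpc_fwd = float(rng.uniform(0.0, 2.0))
            else:
                cpc_rev = float(rng.uniform(0.0, 2.0))
        elif stage == "domain":
            domain = float(10.0 ** rng.uniform(-12, -6))
        elif stage == "protein_db":
            if rng.random() < 0.5:
                nr = float(10.0 ** rng.uniform(-12, -6))
            else:
                uniref = float(10.0 ** rng.uniform(-12, -6))
        elif stage is None and rng.random() < 0.3:
            # true lincRNAs may carry insignificant hits (E > 1e-5)
            domain = float(10.0 ** rng.uniform(-4.5, -1.0))
        evidence_records.append(
            EvidenceRecord(tid, cpc_fwd, cpc_rev, domain,
                           {"NR": nr, "UniRef90": uniref})
        )
    evidence = EvidenceBundle(evidence_records)

    # --- planted DE assignment -------------------------------------------
    trans_gene_ids = gene_ids[cfg.n_cis_pairs: cfg.n_cis_pairs + cfg.n_trans_pairs]
    if len(trans_gene_ids) < cfg.n_trans_pairs:
        raise GenerationError("not enough coding genes for the requested trans pairs")
    de_linc_log2fc = {
        tid: float(cfg.planted_log2fc * (1 if i % 2 == 0 else -1))
        for i, tid in enumerate(de_lincs)
    }
    # DE genes: planted trans targets first, then cis partners, then null genes
    de_gene_pool = (
        trans_gene_ids + cis_gene_ids + gene_ids[cfg.n_cis_pairs + cfg.n_trans_pairs:]
    )
    de_gene_ids = de_gene_pool[: cfg.n_de_genes]
    de_gene_log2fc = {
        gid: float(cfg.planted_log2fc * (1 if i % 2 == 0 else -1))
        for i, gid in enumerate(de_gene_ids)
    }

    # --- counts matrix ----------------------------------------------------
    count_feature_ids = [t.transcript_id for t in candidate_models] + gene_ids
    lfc_map = {**de_linc_log2fc, **de_gene_log2fc}
    base_mean = np.exp(rng.normal(cfg.nb_log_mu, cfg.nb_log_sigma, len(count_feature_ids)))
    counts_mat = np.zeros((len(count_feature_ids), n_samples), dtype=np.int64)
    for i, fid in enumerate(count_feature_ids):
        lfc = lfc_map.get(fid, 0.0)
        mean_a = base_mean[i] * 2.0 ** (lfc / 2.0)
        mean_b = base_mean[i] * 2.0 ** (-lfc / 2.0)
        for s, mean in ((0, mean_a), (1, mean_b)):
            p = cfg.nb_size / (cfg.nb_size + mean)
            sl = slice(s * cfg.samples_per_group, (s + 1) * cfg.samples_per_group)
            counts_mat[i, sl] = rng.negative_binomial(cfg.nb_size, p, cfg.samples_per_group)
    counts = ExpressionMatrix(
        pd.DataFrame(counts_mat, index=count_feature_ids, columns=samples),
        kind="counts", groups=groups,
    )

    # --- FPKM matrix with exact planted correlations ----------------------
    # class-specific baselines mirror the field's observation that coding
    # genes are expressed above known lincRNAs, which sit above novel ones;
    # affine scaling leaves every planted correlation untouched
    novel_set = set(linc_novel)

    def fpkm_scale(fid: str) -> Tuple[float, float]:
        if fid in gene_models:  # gene ids
            return 12.0, 5.0
        if fid in novel_set:
            return 4.0, 1.5
        return 6.0, 1.5  # known lincRNAs and non-expression decoys

    profiles: Dict[str, np.ndarray] = {}  # centered unit profiles of DE lincs
    fpkm_rows: Dict[str, np.ndarray] = {}
    for tid in de_lincs:
        u = _unit_centered(rng, n_samples)
        # DE linc profiles mutually |r| <= 0.5 so planted partners cannot
        # cross the trans threshold against the wrong lincRNA
        while any(abs(float(u @ v)) > 0.5 for v in profiles.values()):
            u = _unit_centered(rng, n_samples)
        profiles[tid] = u
        base, amp = fpkm_scale(tid)
        fpkm_rows[tid] = base + amp * u

    def planted_partner(linc: str, gid: str, r: float) -> np.ndarray:
        u = profiles[linc]
        w = _orthogonal_unit(rng, u)
        y = r * u + np.sqrt(max(0.0, 1.0 - r * r)) * w
        base, amp = fpkm_scale(gid)
        return base + amp * y

    trans_pairs: List[Tuple[str, str, float]] = []
    for k, gid in enumerate(trans_gene_ids):
        linc = de_lincs[k % len(de_lincs)] if de_lincs else None
        if linc is None:
            break
        r = -cfg.trans_r if rng.random() < cfg.trans_negative_frac else cfg.trans_r
        fpkm_rows[gid] = planted_partner(linc, gid, r)
        trans_pairs.append((linc, gid, float(r)))
    for linc, gid, _, r in cis_pairs:
        fpkm_rows[gid] = planted_partner(linc, gid, r)

    def null_profile(fid: str) -> np.ndarray:
        base, amp = fpkm_scale(fid)
        while True:
            u = _unit_centered(rng, n_samples)
            if all(abs(float(u @ v)) < cfg.max_null_abs_r for v in profiles.values()):
                return base + amp * u

    all_feature_ids = count_feature_ids
    for fid in all_feature_ids:
        if fid in fpkm_rows:
            continue
        if decoy_stage.get(fid) == "expression":
            fpkm_rows[fid] = rng.uniform(0.05, 0.45, n_samples)
        else:
            fpkm_rows[fid] = null_profile(fid)
    fpkm_mat = np.vstack([fpkm_rows[f] for f in all_feature_ids])
    fpkm = ExpressionMatrix(
        pd.DataFrame(fpkm_mat, index=all_feature_ids, columns=samples),
        kind="FPKM", groups=groups,
    )

    # --- QTLs -------------------------------------------------------------
    qtl_rows: List[Tuple[str, int, int, str, str]] = []  # bed-style, 0-based
    qtl_hits: List[Tuple[str, str, str]] = []
    pcfg = PipelineConfig()
    qtl_no = 0

    def draw_trait() -> str:
        roll = rng.random()
        if roll < cfg.imf_trait_frac:
            return str(IMF_TRAITS[int(rng.integers(0, len(IMF_TRAITS)))])
        if roll < cfg.imf_trait_frac + cfg.fat_trait_frac:
            return str(FAT_TRAITS[int(rng.integers(0, len(FAT_TRAITS)))])
        return str(NON_FAT_TRAITS[int(rng.integers(0, len(NON_FAT_TRAITS)))])

    for linc in de_lincs:
        span = linc_models[linc].span
        chrom, bstart = linc_blocks[linc]
        for _ in range(cfg.qtls_per_de_linc):
            qtl_no += 1
            qid = f"QTL_{qtl_no:04d}"
            ext5 = int(rng.integers(10_000, 120_000))
            ext3 = int(rng.integers(10_000, 120_000))
            start1 = max(bstart, span.start - ext5)
            end1 = min(bstart + cfg.block_size - 1, span.end + ext3)
            trait = draw_trait()
            qtl_rows.append((chrom, start1 - 1, end1, trait, qid))
            qtl_hits.append((linc, qid, pcfg.classify_trait(trait)))
    for _ in range(cfg.n_background_qtls):
        qtl_no += 1
        qid = f"QTL_{qtl_no:04d}"
        if not non_cis_genes:
            break
        host = gene_models[non_cis_genes[int(rng.integers(0, len(non_cis_genes)))]]
        chrom = host.chrom
        bstart = (host.span.start - 1) // cfg.block_size * cfg.block_size + 1
        # upper half of the block is guaranteed feature-free
        start1 = bstart + 700_000 + int(rng.integers(0, 50_000))
        end1 = start1 + int(rng.integers(50_000, 200_000))
        qtl_rows.append((chrom, start1 - 1, end1, draw_trait(), qid))

    # --- write the bundle -------------------------------------------------
    truth = SyntheticTruth(
        linc_ids_known=linc_known,
        linc_ids_novel=linc_novel,
        decoy_stage=decoy_stage,
        de_linc_log2fc=de_linc_log2fc,
        de_gene_log2fc=de_gene_log2fc,
        cis_pairs=cis_pairs,
        trans_pairs=trans_pairs,
        qtl_hits=qtl_hits,
    )
    files = {
        "reference_gtf": out_dir / "reference.gtf",
        "linc_db_gtf": out_dir / "linc_db.gtf",
        "candidates_gtf": out_dir / "candidates.gtf",
        "evidence_tsv": out_dir / "evidence.tsv",
        "counts_tsv": out_dir / "counts.tsv",
        "fpkm_tsv": out_dir / "fpkm.tsv",
        "qtl_bed": out_dir / "qtls.bed",
        "groups_tsv": out_dir / "groups.tsv",
        "truth_json": out_dir / "truth.json",
        "manifest_json": out_dir / "manifest.json",
    }
    write_gtf(reference, files["reference_gtf"])
    write_gtf(linc_db, files["linc_db_gtf"])
    write_gtf(candidates, files["candidates_gtf"])
    write_evidence(evidence, files["evidence_tsv"])
    write_expression_matrix(counts, files["counts_tsv"])
    write_expression_matrix(fpkm, files["fpkm_tsv"])
    qtl_records = [
        QTLRecord(GenomicInterval(c, s0 + 1, e0), qid, trait, pcfg.classify_trait(trait))
        for c, s0, e0, trait, qid in qtl_rows
    ]
    write_qtl_bed(qtl_records, files["qtl_bed"])
    with files["groups_tsv"].open("w") as fh:
        fh.write("sample_id\tgroup\n")
        for s in samples:
            fh.write(f"{s}\t{groups[s]}\n")
    truth.to_json(files["truth_json"])
    manifest = {
        "seed": cfg.rng_seed,
        "files": {role: p.name for role, p in files.items()},
        "roles": {
            "reference_gtf": "protein-coding reference annotation",
            "linc_db_gtf": "known-lincRNA database stand-in",
            "candidates_gtf": "merged-transcriptome candidates (lincRNAs + decoys)",
            "evidence_tsv": "coding-potential and homology evidence per candidate",
            "counts_tsv": "read counts, features x samples",
            "fpkm_tsv": "FPKM, features x samples",
            "qtl_bed": "QTL intervals with trait names (BED, 0-based half-open)",
            "groups_tsv": "sample -> group map",
            "truth_json": "planted ground truth (never read by the pipeline)",
        },
        "groups": groups,
    }
    files["manifest_json"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return SyntheticBundle(
        out_dir=out_dir, files=files, truth=truth, config=cfg,
        candidates=candidates, reference=reference, linc_db=linc_db,
        evidence=evidence, counts=counts, fpkm=fpkm, qtls=qtl_records,
        groups=groups,
    )
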