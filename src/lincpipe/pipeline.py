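"""End-to-end orchestration of the analysis stages.

A single declarative YAML config names the inputs (or requests synthetic
generation with a seed), the thresholds, and the two-group contrast. Stages
run in a fixed order — classify, filter, diffexpr, qtl, targets — each
writing its outputs under the run directory so a later run can resume from
any stage (``from_stage``) and reproduce downstream outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .core_io import (
    AnnotationSet,
    PipelineConfig,
    ValidationError,
    read_evidence,
    read_expression_matrix,
    read_gtf,
    read_qtl_bed,
    write_gtf,
)
from .diffexpr import DEResult, de_results_frame, test_differential_expression
from .intergenic import classify_transcripts, write_class_labels
from .lincfilter import assign_known_novel, characterize_sets, filter_lincrnas
from .qtl import colocalize_qtl, summarize_qtl
from .simulate import GeneratorConfig, generate_dataset
from .stats import fisher_enrichment
from .targets import classify_deptgs, export_network, predict_cis_targets, predict_trans_targets

__all__ = ["RunManifest", "PipelineError", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("classify", "filter", "diffexpr", "qtl", "targets")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config_snapshot: dict
    input_digests: Dict[str, str]
    stage_seconds: Dict[str, float] = field(default_factory=dict)
    outputs: List[str] = field(default_factory=list)
    version: str = __version__

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _md5(path: Path) -> str:
    h = hashlib.md5()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_groups(path: Path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample_id"], df["group"]))


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        data = yaml.safe_load(Path(config).read_text())
    else:
        data = dict(config)
    if not isinstance(data, dict):
        raise ValidationError("pipeline config must be a mapping")
    return data


def run_pipeline(
    config: str | Path | dict,
    from_stage: Optional[str] = None,
) -> RunManifest:
    """Execute the pipeline described by ``config``; returns the manifest.

    ``from_stage`` resumes at the named stage, re-reading earlier stage
    outputs from the run directory; analytical outputs are reproduced
    bit-identically.
    """
    cfg = _load_config(config)
    out_dir = Path(cfg.get("out_dir", "lincpipe_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    thresholds = PipelineConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in (cfg.get("thresholds") or {}).items()
    })
    stage_flags = {"qtl": True, "targets": True, **(cfg.get("stages") or {})}
    contrast: Tuple[str, str] = tuple(cfg.get("contrast", ("Wei", "Yorkshire")))  # type: ignore

    # ------------------------------------------------------------------ inputs
    if "synthetic" in cfg:
        gen_cfg = GeneratorConfig(**cfg["synthetic"])
        bundle = generate_dataset(gen_cfg, out_dir / "data")
        inputs = {k: str(v) for k, v in bundle.files.items()}
    elif "inputs" in cfg:
        inputs = dict(cfg["inputs"])
    else:
        raise ValidationError("config needs either an 'inputs' or a 'synthetic' section")

    required = ["reference_gtf", "candidates_gtf", "linc_db_gtf", "evidence_tsv",
                "counts_tsv", "fpkm_tsv", "groups_tsv"]
    if stage_flags.get("qtl", True):
        required.append("qtl_bed")
    missing = [k for k in required if k not in inputs or not Path(inputs[k]).exists()]
    if missing:
        raise ValidationError(f"missing pipeline inputs: {missing}")

    digests = {k: _md5(Path(v)) for k, v in sorted(inputs.items()) if Path(v).is_file()}
    manifest = RunManifest(
        config_snapshot={k: v for k, v in cfg.items()}, input_digests=digests
    )

    groups = _read_groups(Path(inputs["groups_tsv"]))
    candidates = read_gtf(inputs["candidates_gtf"])
    reference = read_gtf(inputs["reference_gtf"])
    linc_db = read_gtf(inputs["linc_db_gtf"])
    evidence = read_evidence(inputs["evidence_tsv"])
    counts = read_expression_matrix(inputs["counts_tsv"], "counts", groups)
    fpkm = read_expression_matrix(inputs["fpkm_tsv"], "FPKM", groups)

    if from_stage and from_stage not in STAGES:
        raise ValidationError(f"unknown stage {from_stage!r}; stages are {STAGES}")
    start_idx = STAGES.index(from_stage) if from_stage else 0

    def record(name: str, t0: float, *paths: Path) -> None:
        manifest.stage_seconds[name] = round(time.perf_counter() - t0, 4)
        manifest.outputs.extend(str(p) for p in paths)

    # --------------------------------------------------------------- classify
    labels_path = out_dir / "class_labels.tsv"
    if start_idx <= STAGES.index("classify"):
        t0 = time.perf_counter()
        try:
            if len(candidates) == 0:
                labels = []
                labels_path.write_text("transcript_id\tlabel\toverlapping_gene_ids\n")
            else:
                labels = classify_transcripts(candidates, reference)
                write_class_labels(labels, labels_path)
        except Exception as exc:  # noqa: BLE001 - rethrown with stage context
            raise PipelineError("classify", str(exc)) from exc
        record("classify", t0, labels_path)
    else:
        from .intergenic import ClassLabel

        df = pd.read_csv(labels_path, sep="\t", keep_default_na=False)
        labels = [
            ClassLabel(str(r.transcript_id), str(r.label),
                       tuple(g for g in str(r.overlapping_gene_ids).split(",") if g))
            for r in df.itertuples(index=False)
        ]

    # ----------------------------------------------------------------- filter
    lincs_gtf = out_dir / "lincrnas.gtf"
    report_path = out_dir / "filter_report.tsv"
    char_path = out_dir / "characterization.tsv"
    if start_idx <= STAGES.index("filter"):
        t0 = time.perf_counter()
        try:
            if len(candidates) == 0:
                lincs = AnnotationSet([])
                pd.DataFrame(
                    columns=["stage", "n_input", "n_retained", "n_removed"]
                ).to_csv(report_path, sep="\t", index=False)
            else:
                lincs, report = filter_lincrnas(candidates, labels, evidence, fpkm, thresholds)
                report.write_tsv(report_path)
            kn = assign_known_novel(lincs, linc_db, thresholds.min_overlap_fraction)
            lincs = AnnotationSet(
                t.with_biotype("lincRNA_known" if kn[t.transcript_id] == "known" else "lincRNA_novel")
                for t in lincs
            )
            write_gtf(lincs, lincs_gtf)
            novel = [t for t in lincs if t.biotype == "lincRNA_novel"]
            known = [t for t in lincs if t.biotype == "lincRNA_known"]
            # coding expression is gene-level: re-key representatives by gene id
            coding = _gene_level_models(reference, fpkm)
            summary = characterize_sets(novel, known, coding, fpkm)
            summary.write_tsv(char_path)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("filter", str(exc)) from exc
        record("filter", t0, lincs_gtf, report_path, char_path)
    else:
        lincs = read_gtf(lincs_gtf)

    # --------------------------------------------------------------- diffexpr
    de_linc_path = out_dir / "de_lincrnas.tsv"
    de_gene_path = out_dir / "de_genes.tsv"
    if start_idx <= STAGES.index("diffexpr"):
        t0 = time.perf_counter()
        try:
            results = test_differential_expression(counts, contrast, thresholds)
            by_id = {r.feature_id: r for r in results}
            linc_ids = [t.transcript_id for t in lincs if t.transcript_id in by_id]
            gene_ids = [g for g in reference.gene_ids if g in by_id]
            de_lincs_res = [by_id[i] for i in linc_ids]
            de_genes_res = [by_id[g] for g in gene_ids]
            for path, res in ((de_linc_path, de_lincs_res), (de_gene_path, de_genes_res)):
                with open(path, "w") as fh:
                    fh.write(f"# contrast: {contrast[0]} over {contrast[1]}; "
                             "engine: Welch test on log2 size-factor-normalized counts\n")
                    de_results_frame(res).to_csv(fh, sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("diffexpr", str(exc)) from exc
        record("diffexpr", t0, de_linc_path, de_gene_path)
    else:
        de_lincs_res = _read_de_table(de_linc_path)
        de_genes_res = _read_de_table(de_gene_path)

    de_linc_models = [lincs.get(r.feature_id) for r in de_lincs_res if r.is_de]

    # -------------------------------------------------------------------- qtl
    qtl_overlap_path = out_dir / "qtl_overlaps.tsv"
    qtl_summary_path = out_dir / "qtl_summary.txt"
    if stage_flags.get("qtl", True) and start_idx <= STAGES.index("qtl"):
        t0 = time.perf_counter()
        try:
            qtls = read_qtl_bed(inputs["qtl_bed"], thresholds)
            overlaps = colocalize_qtl(de_linc_models, qtls)
            pd.DataFrame(
                {
                    "lincrna_id": [o.lincrna_id for o in overlaps],
                    "qtl_id": [o.qtl_id for o in overlaps],
                    "chrom": [o.chrom for o in overlaps],
                    "trait_name": [o.trait_name for o in overlaps],
                    "trait_class": [o.trait_class for o in overlaps],
                    "overlap_bp": [o.overlap_bp for o in overlaps],
                }
            ).to_csv(qtl_overlap_path, sep="\t", index=False)
            qtl_summary_path.write_text(summarize_qtl(overlaps).report_text())
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("qtl", str(exc)) from exc
        record("qtl", t0, qtl_overlap_path, qtl_summary_path)

    # ---------------------------------------------------------------- targets
    cis: List = []
    trans: List = []
    if stage_flags.get("targets", True) and start_idx <= STAGES.index("targets"):
        t0 = time.perf_counter()
        try:
            gene_expr_models = _gene_level_models(reference, fpkm)
            gene_set = AnnotationSet(gene_expr_models)
            cis = predict_cis_targets(de_linc_models, gene_set, fpkm, thresholds)
            trans = predict_trans_targets(de_linc_models, gene_set, fpkm, thresholds)
            cis_path = out_dir / "cis_targets.tsv"
            pd.DataFrame(
                {
                    "lincrna_id": [e.lincrna_id for e in cis],
                    "gene_id": [e.gene_id for e in cis],
                    "r": [e.r for e in cis],
                    "p_value": [e.p_value for e in cis],
                    "fdr": [e.fdr for e in cis],
                    "distance_bp": [e.distance_bp for e in cis],
                }
            ).to_csv(cis_path, sep="\t", index=False, na_rep="NA")
            deptg = classify_deptgs(list(cis) + list(trans), de_genes_res)
            deptg_path = out_dir / "deptg_summary.tsv"
            deptg.write_tsv(deptg_path)
            edges = list(cis) + list(trans)
            net_paths: List[Path] = []
            if edges:
                export_network(edges, de_lincs_res, de_genes_res, out_dir / "network")
                net_paths = [out_dir / "network.sif", out_dir / "network.edges.tsv",
                             out_dir / "network.nodes.tsv"]
            record("targets", t0, cis_path, deptg_path, *net_paths)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("targets", str(exc)) from exc

    # ------------------------------------------------------------- enrichment
    gmt = cfg.get("enrichment_gmt")
    if gmt:
        t0 = time.perf_counter()
        try:
            target_ids = {e.gene_id for e in (list(cis) + list(trans))}
            universe = set(reference.gene_ids)
            rows = []
            for name, members in _read_gmt(Path(gmt)).items():
                members &= universe
                if not members:
                    continue
                odds, p = fisher_enrichment(target_ids, members, universe)
                rows.append({"gene_set": name, "n_set": len(members),
                             "n_overlap": len(target_ids & members),
                             "odds_ratio": odds, "p_value": p})
            enr_path = out_dir / "enrichment.tsv"
            pd.DataFrame(rows).to_csv(enr_path, sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("enrichment", str(exc)) from exc
        record("enrichment", t0, enr_path)

    _write_summary(out_dir, lincs, de_lincs_res, de_genes_res)
    manifest.outputs.append(str(out_dir / "summary.txt"))
    manifest.write(out_dir / "manifest.json")
    return manifest


def _gene_level_models(reference: AnnotationSet, expr) -> List:
    """One representative transcript per gene, re-keyed by gene id so its
    expression row resolves at gene level; exon structure kept."""
    from dataclasses import replace

    models = []
    for gid in reference.gene_ids:
        if gid not in expr.feature_ids:
            continue
        t = reference.gene_transcripts(gid)[0]
        models.append(replace(t, transcript_id=gid, biotype="protein_coding"))
    return models


def _read_de_table(path: Path) -> List[DEResult]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        DEResult(str(r.feature_id), float(r.base_mean_a), float(r.base_mean_b),
                 float(r.log2fc), float(r.p_value), float(r.padj), bool(r.is_de),
                 str(r.direction))
        for r in df.itertuples(index=False)
    ]


def _read_gmt(path: Path) -> Dict[str, set]:
    sets: Dict[str, set] = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValidationError(f"GMT line needs name, description, >=1 gene: {line[:40]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


def _write_summary(out_dir: Path, lincs, de_lincs_res, de_genes_res) -> None:
    n_known = sum(1 for t in lincs if t.biotype == "lincRNA_known")
    n_novel = sum(1 for t in lincs if t.biotype == "lincRNA_novel")
    de_l = [r for r in de_lincs_res if r.is_de]
    de_g = [r for r in de_genes_res if r.is_de]
    lines = [
        f"lincRNAs identified: {len(lincs)} ({n_known} known, {n_novel} novel)",
        f"DE lincRNAs: {len(de_l)} ({sum(r.direction == 'up' for r in de_l)} up, "
        f"{sum(r.direction == 'down' for r in de_l)} down)",
        f"DE protein-coding genes: {len(de_g)} ({sum(r.direction == 'up' for r in de_g)} up, "
        f"{sum(r.direction == 'down' for r in de_g)} down)",
    ]
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
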