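"""Cis and trans potential-target prediction and the signed target network.

Cis candidates are protein-coding genes whose span lies within a fixed
window (default < 100 kb boundary gap) of a DE lincRNA on the same
chromosome; every neighbour pair is reported with its Pearson r and
two-sided p across all samples, whatever the p. Trans candidates are all
remaining (DE lincRNA, gene) pairs; those are retained only when
|r| >= 0.95 and the BH-adjusted p over the whole tested trans family is
< 0.05. An edge's regulatory sign is the sign of its correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import pandas as pd

from .core_io import AnnotationSet, ExpressionMatrix, PipelineConfig, TranscriptModel
from .diffexpr import DEResult
from .stats import ConstantVectorError, bh_adjust, correlation_test

__all__ = [
    "TargetEdge",
    "DEPTGSummary",
    "predict_cis_targets",
    "predict_trans_targets",
    "classify_deptgs",
    "export_network",
    "read_edge_table",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetEdge:
    lincrna_id: str
    gene_id: str
    mode: str  # "cis" | "trans"
    r: float
    p_value: float
    fdr: float
    sign: str  # "positive" | "negative"
    distance_bp: Optional[int] = None  # boundary gap; cis edges only

    def __post_init__(self) -> None:
        if self.mode not in ("cis", "trans"):
            raise ValueError(f"bad mode {self.mode!r}")
        if not math.isnan(self.r) and (self.sign == "positive") != (self.r > 0):
            raise ValueError("sign must equal the sign of r")


def _sign(r: float) -> str:
    return "positive" if r > 0 else "negative"


def _cis_candidate_genes(
    linc: TranscriptModel, coding_genes: AnnotationSet, window: int
) -> List[Tuple[str, int]]:
    """Gene ids with boundary gap < window of the lincRNA span (gap 0 when
    the spans overlap), sorted by gene id."""
    out = []
    span = linc.span
    for gid in coding_genes.gene_ids:
        gspan = coding_genes.gene_span(gid)
        gap = span.gap_to(gspan)
        if gap is not None and gap < window:
            out.append((gid, gap))
    out.sort()
    return out


def _correlate(
    linc_id: str, gene_id: str, expr: ExpressionMatrix
) -> Tuple[float, float]:
    """(r, p) across all samples; (nan, nan) for a constant vector."""
    x = expr.row(linc_id)
    y = expr.row(gene_id)
    try:
        res = correlation_test(x, y)
    except ConstantVectorError:
        log.warning("constant expression for pair (%s, %s); r undefined", linc_id, gene_id)
        return float("nan"), float("nan")
    return res.r, res.p_value


def _attach_fdr(
    pairs: List[Tuple[str, str, float, float, Optional[int]]]
) -> List[Tuple[str, str, float, float, float, Optional[int]]]:
    """BH over the pairs with defined p; NaN pairs keep NaN fdr."""
    defined = [i for i, p in enumerate(pairs) if not math.isnan(p[3])]
    fdrs = [float("nan")] * len(pairs)
    if defined:
        adj = bh_adjust([pairs[i][3] for i in defined])
        for i, q in zip(defined, adj):
            fdrs[i] = float(q)
    return [(l, g, r, p, fdrs[i], d) for i, (l, g, r, p, d) in enumerate(pairs)]


def predict_cis_targets(
    de_lincs: Iterable[TranscriptModel],
    coding_genes: AnnotationSet,
    expr: ExpressionMatrix,
    config: Optional[PipelineConfig] = None,
) -> List[TargetEdge]:
    """Neighbour-gene edges for each DE lincRNA, with r, p and a cis-family FDR.

    All neighbour pairs are reported regardless of significance; pairs with
    an undefined correlation (constant vector) carry NaN statistics and are
    excluded from the FDR family.
    """
    config = config or PipelineConfig()
    raw: List[Tuple[str, str, float, float, Optional[int]]] = []
    for linc in sorted(de_lincs, key=lambda t: t.transcript_id):
        for gid, gap in _cis_candidate_genes(linc, coding_genes, config.cis_window):
            r, p = _correlate(linc.transcript_id, gid, expr)
            raw.append((linc.transcript_id, gid, r, p, gap))
    edges = []
    for l, g, r, p, q, gap in _attach_fdr(raw):
        edges.append(
            TargetEdge(l, g, "cis", r, p, q, _sign(r) if not math.isnan(r) else "negative",
                       distance_bp=gap)
        )
    return edges


def predict_trans_targets(
    de_lincs: Iterable[TranscriptModel],
    coding_genes: AnnotationSet,
    expr: ExpressionMatrix,
    config: Optional[PipelineConfig] = None,
) -> List[TargetEdge]:
    """Distant co-expression edges: |r| >= threshold and family FDR < cutoff.

    Cis-eligible genes (boundary gap < the cis window) are excluded from a
    lincRNA's trans family so the two modes stay disjoint. The BH family is
    every tested (lincRNA, gene) pair of the run, making retention invariant
    to input order.
    """
    config = config or PipelineConfig()
    lincs = sorted(de_lincs, key=lambda t: t.transcript_id)
    raw: List[Tuple[str, str, float, float, Optional[int]]] = []
    for linc in lincs:
        cis_ids = {gid for gid, _ in _cis_candidate_genes(linc, coding_genes, config.cis_window)}
        for gid in sorted(coding_genes.gene_ids):
            if gid in cis_ids:
                continue
            r, p = _correlate(linc.transcript_id, gid, expr)
            raw.append((linc.transcript_id, gid, r, p, None))
    edges = []
    for l, g, r, p, q, _ in _attach_fdr(raw):
        if math.isnan(r):
            continue
        if abs(r) >= config.trans_abs_r_min and q < config.fdr_max:
            edges.append(TargetEdge(l, g, "trans", r, p, q, _sign(r)))
    return edges


@dataclass
class DEPTGSummary:
    """Per-lincRNA tallies of differentially expressed potential targets,
    split by edge sign (up + down = total for every row)."""

    rows: List[Tuple[str, int, int, int]]  # (lincrna_id, total, up, down)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["lincrna_id", "deptgs", "upregulated", "downregulated"]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def classify_deptgs(
    edges: Sequence[TargetEdge], de_genes: Sequence[DEResult]
) -> DEPTGSummary:
    """Count DE target genes per lincRNA, up/down by correlation sign."""
    de_ids = {r.feature_id for r in de_genes if r.is_de}
    per_linc: Dict[str, Dict[str, int]] = {}
    seen = set()
    for e in edges:
        key = (e.lincrna_id, e.gene_id)
        if key in seen or e.gene_id not in de_ids:
            continue
        seen.add(key)
        tally = per_linc.setdefault(e.lincrna_id, {"up": 0, "down": 0})
        tally["up" if e.sign == "positive" else "down"] += 1
    rows = [
        (linc, t["up"] + t["down"], t["up"], t["down"])
        for linc, t in sorted(per_linc.items())
    ]
    return DEPTGSummary(rows)


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------


def export_network(
    edges: Sequence[TargetEdge],
    de_lincs: Sequence[DEResult] | None,
    de_genes: Sequence[DEResult] | None,
    out_prefix: str | Path,
) -> nx.DiGraph:
    """Write SIF + edge/node attribute tables importable by graph tools.

    Files: ``<prefix>.sif`` (lincRNA <mode> gene), ``<prefix>.edges.tsv``
    and ``<prefix>.nodes.tsv``. Duplicate (lincRNA, gene, mode) edges are
    dropped with a warning. Returns the deduplicated directed graph.
    """
    if not edges:
        raise ValueError("cannot export an empty edge list")
    out_prefix = Path(out_prefix)
    graph = nx.DiGraph()
    deduped: List[TargetEdge] = []
    seen = set()
    for e in edges:
        key = (e.lincrna_id, e.gene_id, e.mode)
        if key in seen:
            log.warning("duplicate edge %s dropped", key)
            continue
        seen.add(key)
        deduped.append(e)
        graph.add_node(e.lincrna_id, node_type="lincRNA")
        graph.add_node(e.gene_id, node_type="gene")
        graph.add_edge(e.lincrna_id, e.gene_id, mode=e.mode, r=e.r, fdr=e.fdr, sign=e.sign)

    with out_prefix.with_suffix(".sif").open("w") as fh:
        for e in deduped:
            fh.write(f"{e.lincrna_id}\t{e.mode}\t{e.gene_id}\n")

    pd.DataFrame(
        {
            "lincrna_id": [e.lincrna_id for e in deduped],
            "gene_id": [e.gene_id for e in deduped],
            "mode": [e.mode for e in deduped],
            "r": [e.r for e in deduped],
            "p_value": [e.p_value for e in deduped],
            "fdr": [e.fdr for e in deduped],
            "sign": [e.sign for e in deduped],
            "distance_bp": [e.distance_bp for e in deduped],
        }
    ).to_csv(out_prefix.with_suffix(".edges.tsv"), sep="\t", index=False, na_rep="NA")

    directions = {}
    for res in list(de_lincs or []) + list(de_genes or []):
        directions[res.feature_id] = res.direction
    with out_prefix.with_suffix(".nodes.tsv").open("w") as fh:
        fh.write("node_id\tnode_type\tde_direction\n")
        for node, data in sorted(graph.nodes(data=True)):
            fh.write(f"{node}\t{data['node_type']}\t{directions.get(node, 'none')}\n")
    return graph


def read_edge_table(path: str | Path) -> List[TargetEdge]:
    """Re-read an exported ``.edges.tsv`` into TargetEdge records."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    edges = []
    for row in df.itertuples(index=False):
        dist = None if pd.isna(row.distance_bp) else int(row.distance_bp)
        edges.append(
            TargetEdge(
                lincrna_id=str(row.lincrna_id), gene_id=str(row.gene_id),
                mode=str(row.mode), r=float(row.r), p_value=float(row.p_value),
                fdr=float(row.fdr), sign=str(row.sign), distance_bp=dist,
            )
        )
    return edges
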