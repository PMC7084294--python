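"""Bundle loading shared by the analysis drivers."""

from pathlib import Path

import pandas as pd

from lincpipe.core_io import (
    PipelineConfig,
    read_evidence,
    read_expression_matrix,
    read_gtf,
    read_qtl_bed,
)


def load_bundle(data_dir: str):
    d = Path(data_dir)
    groups = dict(
        pd.read_csv(d / "groups.tsv", sep="\t", dtype=str).itertuples(index=False)
    )
    cfg = PipelineConfig()
    return {
        "dir": d,
        "config": cfg,
        "groups": groups,
        "candidates": read_gtf(d / "candidates.gtf"),
        "reference": read_gtf(d / "reference.gtf"),
        "linc_db": read_gtf(d / "linc_db.gtf"),
        "evidence": read_evidence(d / "evidence.tsv"),
        "counts": read_expression_matrix(d / "counts.tsv", "counts", groups),
        "fpkm": read_expression_matrix(d / "fpkm.tsv", "FPKM", groups),
        "qtls": read_qtl_bed(d / "qtls.bed", cfg),
    }


def detected_de_lincs(diffexpr_dir: str):
    df = pd.read_csv(Path(diffexpr_dir) / "de_lincrnas.tsv", sep="\t", comment="#")
    return set(df[df["is_de"]]["feature_id"])
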