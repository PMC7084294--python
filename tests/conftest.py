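from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
import pandas as pd
import pytest

from lincpipe.core_io import (
    AnnotationSet,
    ExpressionMatrix,
    GenomicInterval,
    PipelineConfig,
    TranscriptModel,
)
from lincpipe.simulate import GeneratorConfig, generate_dataset

# (adjacent gene, printed Pearson r, printed two-sided p) for the published
# DE lincRNA / neighbour-gene pairs at n = 6
NEIGHBOUR_PAIR_TABLE = [
    ("OTUB2", -0.915706465, 0.010358),
    ("CCDC19", 0.817455545, 0.04694),
    ("RGS8", 0.950415666, 0.003626),
    ("CACNG4", 0.826596447, 0.042496),
    ("ETS", 0.87248832, 0.02335),
    ("HOXD10", 0.939146854, 0.00544),
    ("HOXD1", 0.919787616, 0.00939),
    ("HOXD11", 0.840680905, 0.03605),
    ("RNF103", 0.86271199, 0.026978),
    ("RMND5A", 0.929580341, 0.00726),
    ("SQLE", 0.965516179, 0.001763),
]


def make_transcript(
    tid: str,
    chrom: str,
    exons: Sequence[Tuple[int, int]],
    strand: str = "+",
    gene_id: str | None = None,
    biotype: str = "candidate",
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene_id or f"G_{tid}",
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        biotype=biotype,
    )


def make_matrix(
    rows: dict, samples: Sequence[str], kind: str = "FPKM", groups: dict | None = None
) -> ExpressionMatrix:
    if groups is None:
        half = len(samples) // 2
        groups = {s: ("A" if i < half else "B") for i, s in enumerate(samples)}
    df = pd.DataFrame(rows, index=samples).T
    df.columns = list(samples)
    return ExpressionMatrix(df, kind=kind, groups=groups)


def random_transcript(rng: np.random.Generator, tid: str, chrom: str = "chr1") -> TranscriptModel:
    n_exons = int(rng.integers(1, 6))
    pos = int(rng.integers(1, 100_000))
    exons = []
    for _ in range(n_exons):
        ln = int(rng.integers(50, 500))
        exons.append((pos, pos + ln - 1))
        pos += ln + int(rng.integers(50, 1000))
    return make_transcript(tid, chrom, exons)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default synthetic bundle shared across the suite."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_dataset(GeneratorConfig(rng_seed=11), out)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """A full pipeline run on a default synthetic bundle."""
    from lincpipe.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("run")
    cfg = {"out_dir": str(out), "synthetic": {"rng_seed": 11},
           "contrast": ["Wei", "Yorkshire"]}
    manifest = run_pipeline(cfg)
    return out, manifest


@pytest.fixture()
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture()
def small_reference() -> AnnotationSet:
    return AnnotationSet(
        [
            make_transcript("ref1", "chr1", [(10_000, 15_000), (18_000, 20_000)],
                            gene_id="GENE1", biotype="protein_coding"),
            make_transcript("ref2", "chr2", [(5_000, 9_000)], gene_id="GENE2",
                            biotype="protein_coding"),
        ]
    )
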