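"""Predict cis and trans potential targets of the DE lincRNAs, tally their
differentially expressed targets by regulatory sign, and export the signed
co-expression network.

Usage: python analysis/05_target_network.py [--data results/data]
       [--lincs results/identification/lincrnas.gtf]
       [--diffexpr results/diffexpr] [--out results/targets]
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _shared import detected_de_lincs, load_bundle  # noqa: E402

from lincpipe.core_io import AnnotationSet, read_gtf  # noqa: E402
from lincpipe.pipeline import _gene_level_models, _read_de_table  # noqa: E402
from lincpipe.targets import (  # noqa: E402
    classify_deptgs,
    export_network,
    predict_cis_targets,
    predict_trans_targets,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--lincs", default="results/identification/lincrnas.gtf")
    ap.add_argument("--diffexpr", default="results/diffexpr")
    ap.add_argument("--out", default="results/targets")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    b = load_bundle(args.data)
    lincs = read_gtf(args.lincs)
    de_ids = detected_de_lincs(args.diffexpr)
    de_models = [lincs.get(t) for t in lincs.transcript_ids if t in de_ids]
    genes = AnnotationSet(_gene_level_models(b["reference"], b["fpkm"]))

    cis = predict_cis_targets(de_models, genes, b["fpkm"], b["config"])
    trans = predict_trans_targets(de_models, genes, b["fpkm"], b["config"])
    print(f"cis neighbour pairs (< {b['config'].cis_window:,} nt): {len(cis)}")
    print(f"trans targets (|r| >= {b['config'].trans_abs_r_min}, "
          f"FDR < {b['config'].fdr_max}): {len(trans)}")

    pd.DataFrame(
        {
            "lincrna_id": [e.lincrna_id for e in cis],
            "gene_id": [e.gene_id for e in cis],
            "r": [e.r for e in cis],
            "p_value": [e.p_value for e in cis],
            "distance_bp": [e.distance_bp for e in cis],
        }
    ).to_csv(out / "cis_targets.tsv", sep="\t", index=False, na_rep="NA")

    de_lincs_res = _read_de_table(Path(args.diffexpr) / "de_lincrnas.tsv")
    de_genes_res = _read_de_table(Path(args.diffexpr) / "de_genes.tsv")
    deptg = classify_deptgs(list(cis) + list(trans), de_genes_res)
    deptg.write_tsv(out / "deptg_summary.tsv")
    print(deptg.to_frame().to_string(index=False))

    edges = list(cis) + list(trans)
    if edges:
        graph = export_network(edges, de_lincs_res, de_genes_res, out / "network")
        multi = sum(1 for n, d in graph.in_degree() if d >= 2)
        print(f"network: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges; "
              f"{multi} genes targeted by >= 2 lincRNAs")


if __name__ == "__main__":
    main()
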