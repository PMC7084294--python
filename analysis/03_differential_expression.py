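"""Two-group differential expression of lincRNAs and protein-coding genes
(|log2FC| > 1 and BH-adjusted p < 0.05).

Usage: python analysis/03_differential_expression.py [--data results/data]
       [--lincs results/identification/lincrnas.gtf] [--out results/diffexpr]
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _shared import load_bundle  # noqa: E402

from lincpipe.core_io import read_gtf  # noqa: E402
from lincpipe.diffexpr import de_results_frame, test_differential_expression  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--lincs", default="results/identification/lincrnas.gtf")
    ap.add_argument("--out", default="results/diffexpr")
    ap.add_argument("--contrast", nargs=2, default=["Wei", "Yorkshire"])
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    b = load_bundle(args.data)
    lincs = read_gtf(args.lincs)

    results = test_differential_expression(b["counts"], tuple(args.contrast), b["config"])
    by_id = {r.feature_id: r for r in results}
    linc_res = [by_id[t] for t in lincs.transcript_ids if t in by_id]
    gene_res = [by_id[g] for g in b["reference"].gene_ids if g in by_id]

    header = (f"# contrast: {args.contrast[0]} over {args.contrast[1]}; "
              "engine: Welch test on log2 size-factor-normalized counts\n")
    for name, res in (("de_lincrnas.tsv", linc_res), ("de_genes.tsv", gene_res)):
        with open(out / name, "w") as fh:
            fh.write(header)
            de_results_frame(res).to_csv(fh, sep="\t", index=False)

    for label, res in (("lincRNAs", linc_res), ("protein-coding genes", gene_res)):
        de = [r for r in res if r.is_de]
        up = sum(r.direction == "up" for r in de)
        print(f"DE {label}: {len(de)} of {len(res)} tested "
              f"({up} up, {len(de) - up} down in {args.contrast[0]})")


if __name__ == "__main__":
    main()
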