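"""Co-localize DE lincRNA loci with trait-labelled QTL intervals and
summarize by trait class, chromosome, and trait name.

Usage: python analysis/04_qtl_colocalization.py [--data results/data]
       [--lincs results/identification/lincrnas.gtf]
       [--diffexpr results/diffexpr] [--out results/qtl]
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _shared import detected_de_lincs, load_bundle  # noqa: E402

from lincpipe.core_io import read_gtf  # noqa: E402
from lincpipe.qtl import colocalize_qtl, summarize_qtl  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--lincs", default="results/identification/lincrnas.gtf")
    ap.add_argument("--diffexpr", default="results/diffexpr")
    ap.add_argument("--out", default="results/qtl")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    b = load_bundle(args.data)
    lincs = read_gtf(args.lincs)
    de_ids = detected_de_lincs(args.diffexpr)
    de_models = [lincs.get(t) for t in lincs.transcript_ids if t in de_ids]

    overlaps = colocalize_qtl(de_models, b["qtls"])
    pd.DataFrame(
        {
            "lincrna_id": [o.lincrna_id for o in overlaps],
            "qtl_id": [o.qtl_id for o in overlaps],
            "chrom": [o.chrom for o in overlaps],
            "trait_name": [o.trait_name for o in overlaps],
            "trait_class": [o.trait_class for o in overlaps],
            "overlap_bp": [o.overlap_bp for o in overlaps],
        }
    ).to_csv(out / "qtl_overlaps.tsv", sep="\t", index=False)
    summary = summarize_qtl(overlaps)
    (out / "qtl_summary.txt").write_text(summary.report_text())
    print(f"{len(de_models)} DE lincRNAs x {len(b['qtls'])} QTLs")
    print(summary.report_text())


if __name__ == "__main__":
    main()
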