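"""Identify lincRNAs: intergenic classification, the six-stage filter
cascade, known/novel assignment, and class characterization.

Usage: python analysis/02_identify_lincrnas.py [--data results/data]
       [--out results/identification]
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _shared import load_bundle  # noqa: E402

from lincpipe.core_io import AnnotationSet, write_gtf  # noqa: E402
from lincpipe.intergenic import classify_transcripts, write_class_labels  # noqa: E402
from lincpipe.lincfilter import (  # noqa: E402
    assign_known_novel,
    characterize_sets,
    filter_lincrnas,
)
from lincpipe.pipeline import _gene_level_models  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/identification")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    b = load_bundle(args.data)

    labels = classify_transcripts(b["candidates"], b["reference"])
    write_class_labels(labels, out / "class_labels.tsv")
    n_intergenic = sum(l.label == "intergenic" for l in labels)
    print(f"intergenic candidates: {n_intergenic} of {len(labels)}")

    lincs, report = filter_lincrnas(b["candidates"], labels, b["evidence"], b["fpkm"],
                                    b["config"])
    report.write_tsv(out / "filter_report.tsv")
    for s in report.stages:
        print(f"  {s.stage:<11} kept {s.n_retained:>3} / {s.n_input:>3}")

    kn = assign_known_novel(lincs, b["linc_db"], b["config"].min_overlap_fraction)
    lincs = AnnotationSet(
        t.with_biotype("lincRNA_known" if kn[t.transcript_id] == "known"
                       else "lincRNA_novel")
        for t in lincs
    )
    write_gtf(lincs, out / "lincrnas.gtf")
    n_known = sum(v == "known" for v in kn.values())
    print(f"lincRNAs: {len(lincs)} ({n_known} known, {len(lincs) - n_known} novel)")

    novel = [t for t in lincs if t.biotype == "lincRNA_novel"]
    known = [t for t in lincs if t.biotype == "lincRNA_known"]
    coding = _gene_level_models(b["reference"], b["fpkm"])
    summary = characterize_sets(novel, known, coding, b["fpkm"])
    summary.write_tsv(out / "characterization.tsv")
    print(summary.to_frame().to_string(index=False))


if __name__ == "__main__":
    main()
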