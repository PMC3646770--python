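#!/usr/bin/env python
"""Ka/Ks estimation and selection classification for the ortholog pairs.

For each pair surviving the funnel, the CDS is sliced from the transcript
using its best protein hit, screened for internal stop codons, codon-aligned
through the protein alignment, and passed to YN00. A two-sided Fisher exact
test on the sites/differences table flags pairs whose omega deviates from 1;
pairs are labelled constrained (omega < 1, significant), fast-evolving
(omega > 1, significant) or neutral.
"""

import argparse
from pathlib import Path

import pandas as pd

from compara import io, kaks, pipeline


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", type=Path, default=Path("results/sim/config.yaml"))
    ap.add_argument("--pairs", type=Path,
                    default=Path("results/orthologs/pairs_unique_name.tsv"))
    ap.add_argument("--method", default="yn00", choices=["yn00", "ng86"])
    ap.add_argument("--out", type=Path, default=Path("results/kaks"))
    args = ap.parse_args()

    cfg = pipeline.PipelineConfig.from_yaml(args.config)
    pairs = pd.read_csv(args.pairs, sep="\t")
    seqs_a = io.read_fasta(cfg.paths["fasta_a"])
    seqs_b = io.read_fasta(cfg.paths["fasta_b"])
    rows_a = pipeline._best_hit_rows(io.read_hit_table(cfg.paths["prot_a"]),
                                     cfg.evalue)
    rows_b = pipeline._best_hit_rows(io.read_hit_table(cfg.paths["prot_b"]),
                                     cfg.evalue)

    results, kept = [], []
    n_dropped = 0
    for row in pairs.itertuples(index=False):
        ra, rb = rows_a.get(row.idA), rows_b.get(row.idB)
        if ra is None or rb is None:
            n_dropped += 1
            continue
        cds_a = kaks.extract_cds(seqs_a[row.idA], int(ra.qstart), int(ra.qend))
        cds_b = kaks.extract_cds(seqs_b[row.idB], int(rb.qstart), int(rb.qend))
        ok_a, cds_a = kaks.screen_stops(cds_a)
        ok_b, cds_b = kaks.screen_stops(cds_b)
        if not (ok_a and ok_b):
            n_dropped += 1
            continue
        res = kaks.compute_pair(cds_a, cds_b, method=args.method,
                                alpha=cfg.alpha)
        results.append(res)
        kept.append((row.idA, row.idB))

    labels, counts = kaks.classify_selection(results, cfg.alpha)
    table = pd.DataFrame([{"idA": a, "idB": b, **r.as_dict(), "label": lab}
                          for (a, b), r, lab in zip(kept, results, labels)])
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "kaks.tsv", sep="\t", index=False,
                 float_format="%.6g")

    print(f"analysed {len(results)} pairs ({n_dropped} dropped at CDS/stop "
          "screening)")
    print(f"Ka/Ks < 1: {counts['lt1']} pairs, of which {counts['sig_lt1']} "
          f"significantly < 1 (p < {cfg.alpha})")
    print(f"Ka/Ks > 1: {counts['gt1']} pairs, of which {counts['sig_gt1']} "
          f"significantly > 1 -> putative fast-evolving genes")
    print(f"labels: {table['label'].value_counts().to_dict()}")


if __name__ == "__main__":
    main()
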