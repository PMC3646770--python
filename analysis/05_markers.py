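#!/usr/bin/env python
"""Marker mining: SNPs from allele-count pileups, SSRs from sequence.

Applies the depth (>= 8 reads per allele) and minor-allele-frequency
(>= 25%) rules to both species' pileups and summarises variant types, then
scans both SSR FASTA inputs for perfect 2-6-mer repeat tracts (>= 15 bp,
>= 3 repeats) and tabulates canonical motif classes side by side.
"""

import argparse
from pathlib import Path

import pandas as pd

from compara import io, pipeline, ssr, variants


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", type=Path, default=Path("results/sim/config.yaml"))
    ap.add_argument("--out", type=Path, default=Path("results/markers"))
    args = ap.parse_args()

    cfg = pipeline.PipelineConfig.from_yaml(args.config)
    args.out.mkdir(parents=True, exist_ok=True)

    snp_rows, ssr_tables = [], {}
    for species in ("a", "b"):
        pileup = io.read_pileup(cfg.paths[f"pileup_{species}"])
        calls = variants.call_snps(pileup, cfg.min_reads, cfg.min_maf)
        calls.to_csv(args.out / f"snp_calls_{species}.tsv", sep="\t",
                     index=False, float_format="%.6g")
        variants.write_vcf(calls, args.out / f"snp_calls_{species}.vcf")
        s = variants.snp_summary(calls, total_assembled_bp=len(pileup))
        snp_rows.append({"species": species, "n_calls": s["n_calls"],
                         "transitions": s["n_transitions"],
                         "transversions": s["n_transversions"],
                         "indels": s["n_indels"],
                         "one_per_bp": s["one_per_bp"]})

        seqs = io.read_fasta(cfg.paths[f"ssr_fasta_{species}"])
        loci = ssr.scan_fasta(seqs, min_total_len=cfg.ssr_min_len,
                              min_repeats=cfg.ssr_min_repeats)
        ssr.loci_table(loci).to_csv(args.out / f"ssr_loci_{species}.tsv",
                                    sep="\t", index=False, float_format="%.6g")
        ssr_tables[species] = ssr.ssr_summary(loci)

    snp_table = pd.DataFrame(snp_rows)
    snp_table.to_csv(args.out / "snp_summary.tsv", sep="\t", index=False)
    print("SNP discovery (both species):")
    print(snp_table.to_string(index=False))

    merged = ssr_tables["a"].merge(
        ssr_tables["b"], on=["ssr_type", "motif_len"], how="outer",
        suffixes=("_a", "_b")).sort_values("motif_len")
    merged.to_csv(args.out / "ssr_summary.tsv", sep="\t", index=False)
    print("\nSSR motif classes (both species):")
    print(merged.to_string(index=False))


if __name__ == "__main__":
    main()
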