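#!/usr/bin/env python
"""Identify putative ortholog pairs and report the filter funnel.

Reciprocal best hits between the two transcriptomes are filtered by the
same-best-protein and unique-gene-name rules; the funnel counts show how
many candidate pairs each paralog-exclusion step removes.
"""

import argparse
from pathlib import Path

from compara import io, orthology, pipeline


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", type=Path, default=Path("results/sim/config.yaml"))
    ap.add_argument("--out", type=Path, default=Path("results/orthologs"))
    args = ap.parse_args()

    cfg = pipeline.PipelineConfig.from_yaml(args.config)
    P = cfg.paths
    final, stages, funnel = orthology.run_funnel(
        io.read_hit_table(P["hits_ab"]), io.read_hit_table(P["hits_ba"]),
        io.read_hit_table(P["prot_a"]), io.read_hit_table(P["prot_b"]),
        io.read_annotations(P["annot_a"]), io.read_annotations(P["annot_b"]),
        cfg.evalue)

    args.out.mkdir(parents=True, exist_ok=True)
    for stage, pairs in stages.items():
        orthology.pairs_table(pairs).to_csv(args.out / f"pairs_{stage}.tsv",
                                            sep="\t", index=False)
    funnel.to_csv(args.out / "funnel.tsv", sep="\t", index=False)

    print("ortholog filter funnel:")
    print(funnel.to_string(index=False))
    n0, n1, n2 = funnel["n_pairs"]
    print(f"\nBBH found {n0} candidate pairs; the same-protein filter removed "
          f"{n0 - n1}, the unique-gene-name filter removed {n1 - n2}; "
          f"{n2} pairs proceed to Ka/Ks analysis.")


if __name__ == "__main__":
    main()
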