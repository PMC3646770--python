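#!/usr/bin/env python
"""GO level-3 profiles for both transcriptomes and enrichment of the
selection classes.

The level-3 rollup gives a coarse functional profile comparable between the
two species. The constrained and fast-evolving gene sets from the Ka/Ks
analysis are then tested for over-represented terms against all analysed
pairs with the upper-tail hypergeometric test.
"""

import argparse
from pathlib import Path

import pandas as pd

from compara import go_tools, io, pipeline


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", type=Path, default=Path("results/sim/config.yaml"))
    ap.add_argument("--kaks", type=Path, default=Path("results/kaks/kaks.tsv"))
    ap.add_argument("--level", type=int, default=3)
    ap.add_argument("--out", type=Path, default=Path("results/go"))
    args = ap.parse_args()

    cfg = pipeline.PipelineConfig.from_yaml(args.config)
    go = go_tools.load_obo(cfg.paths["obo"])
    args.out.mkdir(parents=True, exist_ok=True)

    for species in ("a", "b"):
        annot = io.read_annotations(cfg.paths[f"annot_{species}"])
        sets = io.go_annotation_sets(annot)
        profile = go_tools.rollup_to_level(sets, go, args.level)
        profile.to_csv(args.out / f"profile_level{args.level}_{species}.tsv",
                       sep="\t", index=False, float_format="%.6g")
        print(f"species {species}: {len(profile)} level-{args.level} terms "
              f"profiled over {len(sets)} genes")

    kaks_table = pd.read_csv(args.kaks, sep="\t")
    annotations = io.go_annotation_sets(io.read_annotations(cfg.paths["annot_a"]))
    population = set(kaks_table["idA"])
    for label in ("constrained", "fast_evolving"):
        study = set(kaks_table.loc[kaks_table["label"] == label, "idA"])
        if not study:
            print(f"{label}: empty study set, skipped")
            continue
        table = go_tools.hypergeometric_enrichment(
            study, population, annotations, go, cfg.alpha)
        table.to_csv(args.out / f"enrichment_{label}.tsv", sep="\t",
                     index=False, float_format="%.6g")
        sig = table[table["significant"]]
        print(f"{label}: {len(study)} genes, {len(sig)} significantly "
              f"enriched terms (p < {cfg.alpha})")
        if not sig.empty:
            top = sig.iloc[0]
            print(f"  top term {top.term_id} ({top.term_name}): "
                  f"k={top.k}/{top.n} vs K={top.K}/{top.N}, p={top.p_value:.3g}")


if __name__ == "__main__":
    main()
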