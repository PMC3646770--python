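"""End-to-end orchestration of the comparative-transcriptome analysis.

``run_comparison`` drives the ortholog funnel (BBH -> same-protein ->
unique-name), CDS extraction and stop screening, protein-guided codon
alignment, YN00 (or NG86) Ka/Ks with Fisher significance, selection
classification, and GO enrichment of the constrained and fast-evolving
sets. ``run_markers`` drives SNP calling and SSR detection for both
transcriptomes. Every stage materialises its table under the output
directory so any stage can be re-run or audited in isolation, and reports
are deterministic for a fixed config and seed (sorted keys, no
timestamps in the report body).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import go_tools, io, kaks, orthology, simulate, ssr, variants

log = logging.getLogger("compara")

COMPARISON_INPUTS = ["fasta_a", "fasta_b", "hits_ab", "hits_ba",
                     "prot_a", "prot_b", "annot_a", "annot_b", "obo"]
MARKER_INPUTS = ["pileup_a", "pileup_b", "ssr_fasta_a", "ssr_fasta_b"]


@dataclass
class PipelineConfig:
    paths: dict = field(default_factory=dict)
    evalue: float = 1e-6
    alpha: float = 0.05
    min_reads: int = 8
    min_maf: float = 0.25
    ssr_min_len: int = 15
    ssr_min_repeats: float = 3
    total_bp_a: int | None = None
    total_bp_b: int | None = None
    method: str = "YN00"
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if hasattr(cfg, key) and key != "paths":
                setattr(cfg, key, value)
            else:
                cfg.paths[key] = value
        cfg.validate()
        return cfg

    def validate(self, require: list[str] | None = None) -> None:
        for name, val in [("evalue", self.evalue), ("alpha", self.alpha),
                          ("min_reads", self.min_reads), ("min_maf", self.min_maf),
                          ("ssr_min_len", self.ssr_min_len),
                          ("ssr_min_repeats", self.ssr_min_repeats)]:
            if val is None or val <= 0:
                raise ValueError(f"threshold {name} must be positive, got {val}")
        for key in (require or []):
            p = self.paths.get(key)
            if p is None:
                raise FileNotFoundError(f"config is missing required input '{key}'")
            if not Path(p).exists():
                raise FileNotFoundError(f"input '{key}' does not exist: {p}")


def _best_hit_rows(hits: pd.DataFrame, evalue_max: float) -> dict[str, pd.Series]:
    """Top HSP row per query (bitscore, then evalue, then subject id)."""
    kept = hits[hits["evalue"] <= evalue_max]
    if kept.empty:
        return {}
    ranked = kept.sort_values(["qseqid", "bitscore", "evalue", "sseqid"],
                              ascending=[True, False, True, True], kind="mergesort")
    top = ranked.drop_duplicates("qseqid", keep="first")
    return {row.qseqid: row for row in top.itertuples(index=False)}


def run_comparison(config: PipelineConfig) -> dict:
    """Ortholog funnel -> Ka/Ks -> selection classes -> GO enrichment."""
    config.validate(require=COMPARISON_INPUTS)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    P = config.paths

    log.info("loading inputs")
    seqs_a, seqs_b = io.read_fasta(P["fasta_a"]), io.read_fasta(P["fasta_b"])
    hits_ab, hits_ba = io.read_hit_table(P["hits_ab"]), io.read_hit_table(P["hits_ba"])
    prot_a, prot_b = io.read_hit_table(P["prot_a"]), io.read_hit_table(P["prot_b"])
    annot_a, annot_b = io.read_annotations(P["annot_a"]), io.read_annotations(P["annot_b"])

    log.info("orthology funnel")
    final_pairs, stages, funnel = orthology.run_funnel(
        hits_ab, hits_ba, prot_a, prot_b, annot_a, annot_b, config.evalue)
    for stage, pairs in stages.items():
        orthology.pairs_table(pairs).to_csv(out / f"pairs_{stage}.tsv",
                                            sep="\t", index=False)
    funnel.to_csv(out / "funnel.tsv", sep="\t", index=False)

    log.info("CDS extraction and Ka/Ks (%s) on %d pairs", config.method,
             len(final_pairs))
    cds_rows_a = _best_hit_rows(prot_a, config.evalue)
    cds_rows_b = _best_hit_rows(prot_b, config.evalue)
    results, kept_pairs = [], []
    n_stop_failed = n_no_cds = 0
    for pair in final_pairs:
        ra, rb = cds_rows_a.get(pair.idA), cds_rows_b.get(pair.idB)
        if ra is None or rb is None:
            n_no_cds += 1
            continue
        cds_a = kaks.extract_cds(seqs_a[pair.idA], int(ra.qstart), int(ra.qend))
        cds_b = kaks.extract_cds(seqs_b[pair.idB], int(rb.qstart), int(rb.qend))
        ok_a, cds_a = kaks.screen_stops(cds_a)
        ok_b, cds_b = kaks.screen_stops(cds_b)
        if not (ok_a and ok_b):
            n_stop_failed += 1
            continue
        aln = kaks.align_codons(cds_a, cds_b)
        res = kaks.yn00(aln) if config.method.upper() == "YN00" else kaks.ng86(aln)
        kaks.kaks_significance(res)
        results.append(res)
        kept_pairs.append(pair)

    labels, class_counts = kaks.classify_selection(results, config.alpha)
    kaks_df = pd.DataFrame([
        {"idA": p.idA, "idB": p.idB, **r.as_dict(), "label": lab}
        for p, r, lab in zip(kept_pairs, results, labels)])
    kaks_df.to_csv(out / "kaks.tsv", sep="\t", index=False, float_format="%.6g")

    log.info("GO enrichment of selection classes")
    go = go_tools.load_obo(P["obo"])
    annotations = io.go_annotation_sets(annot_a)
    population = {p.idA for p in kept_pairs}
    enrichment = {}
    for label in ("constrained", "fast_evolving"):
        study = {p.idA for p, lab in zip(kept_pairs, labels) if lab == label}
        if study:
            table = go_tools.hypergeometric_enrichment(
                study, population, annotations, go, config.alpha)
        else:
            table = pd.DataFrame(columns=["term_id", "term_name", "namespace",
                                          "k", "n", "K", "N", "p_value",
                                          "significant"])
        table.to_csv(out / f"enrichment_{label}.tsv", sep="\t", index=False,
                     float_format="%.6g")
        enrichment[label] = [
            {"term_id": r.term_id, "k": int(r.k), "K": int(r.K),
             "p_value": float(r.p_value)}
            for r in table.itertuples(index=False) if bool(r.significant)]

    report = {
        "funnel": {row.stage: int(row.n_pairs) for row in funnel.itertuples(index=False)},
        "n_pairs_no_cds": n_no_cds,
        "n_pairs_internal_stop": n_stop_failed,
        "n_pairs_analysed": len(results),
        "selection_classes": class_counts,
        "labels": {lab: labels.count(lab) for lab in kaks.LABELS},
        "significant_enrichment": enrichment,
        "parameters": {"evalue": config.evalue, "alpha": config.alpha,
                       "method": config.method.upper(), "seed": config.seed},
    }
    with open(out / "comparison_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def run_markers(config: PipelineConfig) -> dict:
    """SNP calling and SSR detection for both transcriptomes."""
    config.validate(require=MARKER_INPUTS)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    P = config.paths
    report: dict = {"snp": {}, "ssr": {},
                    "parameters": {"min_reads": config.min_reads,
                                   "min_maf": config.min_maf,
                                   "ssr_min_len": config.ssr_min_len,
                                   "ssr_min_repeats": config.ssr_min_repeats,
                                   "seed": config.seed}}
    totals = {"a": config.total_bp_a, "b": config.total_bp_b}
    for species, pileup_key, fasta_key in [("a", "pileup_a", "ssr_fasta_a"),
                                           ("b", "pileup_b", "ssr_fasta_b")]:
        pileup = io.read_pileup(P[pileup_key])
        calls = variants.call_snps(pileup, config.min_reads, config.min_maf)
        calls.to_csv(out / f"snp_calls_{species}.tsv", sep="\t", index=False,
                     float_format="%.6g")
        total_bp = totals[species] or int(len(pileup))
        report["snp"][species] = variants.snp_summary(calls, total_bp)

        seqs = io.read_fasta(P[fasta_key])
        loci = ssr.scan_fasta(seqs, min_total_len=config.ssr_min_len,
                              min_repeats=config.ssr_min_repeats)
        ssr.loci_table(loci).to_csv(out / f"ssr_loci_{species}.tsv", sep="\t",
                                    index=False, float_format="%.6g")
        summary = ssr.ssr_summary(loci)
        summary.to_csv(out / f"ssr_summary_{species}.tsv", sep="\t", index=False)
        report["ssr"][species] = {
            "n_loci": len(loci),
            "by_type": {row.ssr_type: {"n_motifs": int(row.n_motifs),
                                       "count": int(row.count),
                                       "major_motif": row.major_motif}
                        for row in summary.itertuples(index=False)},
        }
    with open(out / "markers_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


# ---------------------------------------------------------------------------
# Dataset simulation preset
# ---------------------------------------------------------------------------

def simulate_dataset(outdir, seed: int = 0, n_pairs: int = 100,
                     n_fast: int = 10, n_codons: int = 500, kappa: float = 2.0,
                     t: float = 0.4, omega_background=(0.1, 0.5, 1.0),
                     omega_fast: float = 3.0, n_nonreciprocal: int = 5,
                     n_diff_protein: int = 5, n_dup_name: int = 5,
                     pileup_len: int = 2000, pileup_depth: int = 60,
                     pileup_error: float = 0.0, n_snps: int = 20,
                     n_ssr_seqs: int = 20, ssr_seq_len: int = 400) -> Path:
    """Write a complete paper-like synthetic dataset plus its config file.

    Background pairs cycle through ``omega_background``; ``n_fast`` pairs
    evolve at ``omega_fast``. SNPs are planted at 50% allele fraction; SSR
    tracts cover every motif length with qualifying and sub-threshold
    examples. Returns the path of the written ``config.yaml``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    omegas = [omega_background[i % len(omega_background)]
              for i in range(n_pairs - n_fast)] + [omega_fast] * n_fast
    seqs_a, seqs_b, truth = simulate.simulate_ortholog_pairs(
        n_pairs, omegas, kappa, t, n_codons, seed=int(rng.integers(2**31)))
    tables = simulate.simulate_hit_tables(
        truth, seqs_a, seqs_b, seed=int(rng.integers(2**31)),
        n_nonreciprocal=n_nonreciprocal, n_diff_protein=n_diff_protein,
        n_dup_name=n_dup_name)
    hits_ab, hits_ba, prot_a, prot_b, annot_a, annot_b = tables

    # GO annotations planted on the A-side ids; the fast-evolving truth set
    # carries the enriched term
    pair_ids_a = [ida for ida, *_ in truth.ortholog_map]
    fast_ids = [ida for ida, _idb, w, *_ in truth.ortholog_map if w > 1]
    go_annot, obo_text, go_truth = simulate.simulate_go_annotations(
        n_genes=len(pair_ids_a), n_terms=12, study_fraction_with_term=0.9,
        background_fraction=0.1, seed=int(rng.integers(2**31)),
        gene_ids=pair_ids_a, study_genes=fast_ids)
    go_map = dict(zip(go_annot["gene"], go_annot["go_terms"]))
    annot_a = annot_a.copy()
    annot_a["go_terms"] = [go_map.get(t, "") for t in annot_a["transcript_id"]]
    # orthologs share function: mirror each pair's terms onto the B member so
    # the two level-3 profiles are comparable
    b_to_a = {idb: ida for ida, idb, *_ in truth.ortholog_map}
    annot_b = annot_b.copy()
    annot_b["go_terms"] = [go_map.get(b_to_a.get(t, ""), "")
                           for t in annot_b["transcript_id"]]

    # markers: one pileup and one SSR FASTA per species
    tract_set = [("AT", 8), ("ATC", 5), ("AT", 7), ("ATAC", 4), ("AAAAT", 3),
                 ("AAGGTC", 3), ("AC", 9), ("AAG", 6), ("AATC", 5), ("AACTG", 4)]
    for species in ("a", "b"):
        sub_seed = int(rng.integers(2**31))
        snps = []
        positions = sorted(np.random.default_rng(sub_seed).choice(
            pileup_len, size=n_snps, replace=False).tolist())
        # transition-rich mix, as in real transcriptome SNP catalogues
        patterns = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"),
                    ("A", "C"), ("A", "T"), ("A", "del"), ("C", "ins")]
        for i, pos in enumerate(positions):
            ref, alt = patterns[i % len(patterns)]
            snps.append((int(pos), ref, alt, 0.5))
        pileup, snp_truth = simulate.simulate_pileup(
            pileup_len, snps, depth=pileup_depth, error_rate=pileup_error,
            seed=sub_seed, contig_id=f"contig_{species}")
        truth.snp_truth.extend(snp_truth)
        io.write_pileup(pileup, outdir / f"pileup_{species}.tsv")

        ssr_seqs, ssr_truth = simulate.plant_ssrs(
            n_ssr_seqs, ssr_seq_len, tract_set, seed=int(rng.integers(2**31)))
        truth.ssr_truth.extend((f"{species}:{sid}", s, e, m, nr)
                               for sid, s, e, m, nr in ssr_truth)
        io.write_fasta(ssr_seqs, outdir / f"ssr_{species}.fasta")

    io.write_fasta(seqs_a, outdir / "transcriptome_a.fasta")
    io.write_fasta(seqs_b, outdir / "transcriptome_b.fasta")
    io.write_hits(hits_ab, outdir / "hits_ab.tsv")
    io.write_hits(hits_ba, outdir / "hits_ba.tsv")
    io.write_hits(prot_a, outdir / "prot_a.tsv")
    io.write_hits(prot_b, outdir / "prot_b.tsv")
    io.write_annotations(annot_a, outdir / "annot_a.tsv")
    io.write_annotations(annot_b, outdir / "annot_b.tsv")
    (outdir / "ontology.obo").write_text(obo_text + "\n")
    io.write_truth(truth, outdir / "truth")
    with open(outdir / "truth" / "truth_go.json", "w") as fh:
        json.dump(go_truth, fh, indent=2, sort_keys=True)

    config = {
        "fasta_a": str(outdir / "transcriptome_a.fasta"),
        "fasta_b": str(outdir / "transcriptome_b.fasta"),
        "hits_ab": str(outdir / "hits_ab.tsv"),
        "hits_ba": str(outdir / "hits_ba.tsv"),
        "prot_a": str(outdir / "prot_a.tsv"),
        "prot_b": str(outdir / "prot_b.tsv"),
        "annot_a": str(outdir / "annot_a.tsv"),
        "annot_b": str(outdir / "annot_b.tsv"),
        "obo": str(outdir / "ontology.obo"),
        "pileup_a": str(outdir / "pileup_a.tsv"),
        "pileup_b": str(outdir / "pileup_b.tsv"),
        "ssr_fasta_a": str(outdir / "ssr_a.fasta"),
        "ssr_fasta_b": str(outdir / "ssr_b.fasta"),
        "evalue": 1e-6, "alpha": 0.05, "min_reads": 8, "min_maf": 0.25,
        "ssr_min_len": 15, "ssr_min_repeats": 3, "seed": seed,
        "outdir": str(outdir / "out"),
    }
    cfg_path = outdir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return cfg_path
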