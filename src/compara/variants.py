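"""SNP/indel calling from per-position allele counts.

A site is called when its two most frequent alleles each have at least
``min_reads_per_allele`` reads (default 8) and the minor allele frequency —
minor / (major + minor), computed over the top two alleles — is at least
``min_maf`` (default 0.25). Both thresholds are inclusive. Third and lower
alleles are ignored for calling but tallied in a QC column; the MAF
denominator can optionally be switched to total depth.

Variant types: A<->G and C<->T are transitions, other base pairs
transversions, and any call involving a deletion or insertion allele an
indel.
"""

from __future__ import annotations

import pandas as pd

BASE_ALLELES = ("A", "C", "G", "T")
ALLELES = BASE_ALLELES + ("del", "ins")
_COUNT_COLS = ["count_A", "count_C", "count_G", "count_T", "count_del", "count_ins"]
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def classify_snp(ref: str, alt: str) -> str:
    if ref not in ALLELES or alt not in ALLELES:
        raise ValueError(f"alleles must be in {ALLELES}, got ({ref!r}, {alt!r})")
    if ref in ("del", "ins") or alt in ("del", "ins"):
        return "indel"
    return "transition" if frozenset((ref, alt)) in _TRANSITIONS else "transversion"


def call_snps(pileup: pd.DataFrame, min_reads_per_allele: int = 8,
              min_maf: float = 0.25, maf_denominator: str = "biallelic") -> pd.DataFrame:
    """Call bi-allelic variants from a sorted allele-count table.

    ``pileup`` must carry contig, pos and the six allele-count columns and be
    sorted by (contig, pos) — unsorted input is a hard error. Returns one row
    per call: contig, pos, ref (majority allele), alt, ref/alt counts, depth,
    maf, type, and the read count attributed to further alleles.
    """
    if maf_denominator not in ("biallelic", "total"):
        raise ValueError("maf_denominator must be 'biallelic' or 'total'")
    missing = [c for c in ["contig", "pos", *_COUNT_COLS] if c not in pileup.columns]
    if missing:
        raise ValueError(f"pileup is missing columns: {missing}")
    key = pileup[["contig", "pos"]].reset_index(drop=True)
    if not key.equals(key.sort_values(["contig", "pos"], kind="mergesort")
                      .reset_index(drop=True)):
        raise ValueError("pileup must be sorted by (contig, pos)")

    calls = []
    counts_mat = pileup[_COUNT_COLS].to_numpy()
    for row_i, row in enumerate(pileup.itertuples(index=False)):
        counts = counts_mat[row_i]
        order = sorted(range(6), key=lambda a: (-counts[a], a))
        top1, top2 = order[0], order[1]
        c1, c2 = int(counts[top1]), int(counts[top2])
        if min(c1, c2) < min_reads_per_allele:
            continue
        denom = c1 + c2 if maf_denominator == "biallelic" else int(counts.sum())
        maf = c2 / denom if denom else 0.0
        if maf < min_maf:
            continue
        ref, alt = ALLELES[top1], ALLELES[top2]
        calls.append({
            "contig": row.contig, "pos": int(row.pos), "ref": ref, "alt": alt,
            "count_ref": c1, "count_alt": c2, "depth": int(counts.sum()),
            "maf": maf, "type": classify_snp(ref, alt),
            "other_allele_reads": int(counts.sum()) - c1 - c2,
        })
    return pd.DataFrame(calls, columns=["contig", "pos", "ref", "alt", "count_ref",
                                        "count_alt", "depth", "maf", "type",
                                        "other_allele_reads"])


def snp_summary(calls: pd.DataFrame, total_assembled_bp: int) -> dict:
    """Counts and proportions per variant type plus the "one per X bp" rate.

    With zero calls the frequency is reported as None rather than raising.
    """
    if total_assembled_bp <= 0:
        raise ValueError("total_assembled_bp must be positive")
    n = len(calls)
    by_type = calls["type"].value_counts().to_dict() if n else {}
    summary = {
        "n_calls": n,
        "n_transitions": int(by_type.get("transition", 0)),
        "n_transversions": int(by_type.get("transversion", 0)),
        "n_indels": int(by_type.get("indel", 0)),
        "proportions": {t: by_type.get(t, 0) / n for t in
                        ("transition", "transversion", "indel")} if n else {},
        "one_per_bp": round(total_assembled_bp / n) if n else None,
        "total_assembled_bp": int(total_assembled_bp),
    }
    return summary


def write_vcf(calls: pd.DataFrame, path, source: str = "compara") -> None:
    """Minimal VCF 4.2 (CHROM, 1-based POS, REF, ALT, INFO DP/AF).

    Indel alleles are written symbolically (<DEL>, <INS>) since the caller
    works from allele counts, not read alignments.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in calls.itertuples(index=False):
            ref = row.ref if row.ref in BASE_ALLELES else "N"
            alt = row.alt if row.alt in BASE_ALLELES else f"<{row.alt.upper()}>"
            fh.write(f"{row.contig}\t{row.pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t"
                     f"DP={row.depth};AF={row.maf:.4f}\n")
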