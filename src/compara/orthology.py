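"""Bidirectional-best-hit orthology with paralog-exclusion filters.

Putative 1:1 orthologs between two transcriptomes are identified as
reciprocal best hits (BBH) in cross-species similarity tables, then passed
through two additional filters designed to exclude paralog comparisons:

1. same_protein — both members must have the same best-protein accession in
   transcript-vs-protein searches (E-value < 1e-6);
2. unique_name — the pair's annotated gene name must occur exactly once in
   each transcriptome's full annotation table.

"Best" means highest bitscore; ties break on lower E-value, then
lexicographic subject id, so results are deterministic. Gene-name
comparison is case-insensitive after whitespace normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DEFAULT_EVALUE = 1e-6
STAGES = ("bbh", "same_protein", "unique_name")


@dataclass
class OrthologPair:
    idA: str
    idB: str
    stage_passed: str = "bbh"
    best_protein: str | None = None


def best_hits(hits: pd.DataFrame, evalue_max: float = DEFAULT_EVALUE) -> dict[str, str]:
    """Best subject per query among hits with evalue <= ``evalue_max``.

    Maximises bitscore; ties break on lower evalue then lexicographic
    subject id. Queries with no qualifying hit are absent from the map.
    """
    if hits.empty:
        return {}
    kept = hits[hits["evalue"] <= evalue_max]
    if kept.empty:
        return {}
    ranked = kept.sort_values(["qseqid", "bitscore", "evalue", "sseqid"],
                              ascending=[True, False, True, True],
                              kind="mergesort")
    top = ranked.drop_duplicates("qseqid", keep="first")
    return dict(zip(top["qseqid"], top["sseqid"]))


def reciprocal_best_hits(hits_ab: pd.DataFrame, hits_ba: pd.DataFrame,
                         evalue_max: float = DEFAULT_EVALUE) -> list[OrthologPair]:
    """Pairs (a, b) with a's best hit b and b's best hit a, sorted by idA."""
    best_ab = best_hits(hits_ab, evalue_max)
    best_ba = best_hits(hits_ba, evalue_max)
    pairs = [OrthologPair(a, b) for a, b in best_ab.items()
             if best_ba.get(b) == a]
    return sorted(pairs, key=lambda p: p.idA)


def filter_same_protein(pairs: list[OrthologPair], prot_hits_a: pd.DataFrame,
                        prot_hits_b: pd.DataFrame,
                        evalue_max: float = DEFAULT_EVALUE):
    """Keep pairs whose members best-match the same protein accession.

    Best-protein matches come from the transcript-vs-protein hit tables at
    the same E-value threshold. Pairs with an unmatched member are dropped
    (tallied, not an error). Returns ``(kept_pairs, n_dropped_unannotated)``.
    """
    best_a = best_hits(prot_hits_a, evalue_max)
    best_b = best_hits(prot_hits_b, evalue_max)
    kept = []
    n_unannotated = 0
    for p in pairs:
        pa, pb = best_a.get(p.idA), best_b.get(p.idB)
        if pa is None or pb is None:
            n_unannotated += 1
            continue
        if pa == pb:
            kept.append(OrthologPair(p.idA, p.idB, "same_protein", best_protein=pa))
    return kept, n_unannotated


def _normalise_name(name) -> str | None:
    if name is None or (isinstance(name, float) and pd.isna(name)):
        return None
    norm = " ".join(str(name).split()).casefold()
    return norm or None


def gene_name_counts(annot: pd.DataFrame) -> dict[str, int]:
    """Multiplicity of each normalised gene name over a FULL annotation table."""
    counts: dict[str, int] = {}
    for name in annot["gene_name"]:
        norm = _normalise_name(name)
        if norm is not None:
            counts[norm] = counts.get(norm, 0) + 1
    return counts


def filter_unique_gene_name(pairs: list[OrthologPair], annot_a: pd.DataFrame,
                            annot_b: pd.DataFrame) -> list[OrthologPair]:
    """Keep pairs whose gene name occurs exactly once in each annotation table."""
    counts_a = gene_name_counts(annot_a)
    counts_b = gene_name_counts(annot_b)
    name_a = {r.transcript_id: _normalise_name(r.gene_name)
              for r in annot_a.itertuples()}
    name_b = {r.transcript_id: _normalise_name(r.gene_name)
              for r in annot_b.itertuples()}
    kept = []
    for p in pairs:
        na, nb = name_a.get(p.idA), name_b.get(p.idB)
        if na is None or nb is None:
            continue
        if counts_a.get(na, 0) == 1 and counts_b.get(nb, 0) == 1:
            kept.append(OrthologPair(p.idA, p.idB, "unique_name", p.best_protein))
    return kept


def funnel_report(stage_pairs: dict[str, list]) -> pd.DataFrame:
    """Counts per funnel stage; enforces the monotone non-increasing funnel."""
    rows = [{"stage": s, "n_pairs": len(stage_pairs.get(s, []))} for s in STAGES]
    counts = [r["n_pairs"] for r in rows]
    if any(a < b for a, b in zip(counts, counts[1:])):
        raise ValueError(f"funnel counts must be non-increasing, got {counts}")
    return pd.DataFrame(rows)


def run_funnel(hits_ab, hits_ba, prot_hits_a, prot_hits_b, annot_a, annot_b,
               evalue_max: float = DEFAULT_EVALUE):
    """BBH -> same-protein -> unique-name funnel in one call.

    Returns ``(final_pairs, stage_pairs dict, funnel DataFrame)``.
    """
    bbh = reciprocal_best_hits(hits_ab, hits_ba, evalue_max)
    same_prot, _ = filter_same_protein(bbh, prot_hits_a, prot_hits_b, evalue_max)
    unique = filter_unique_gene_name(same_prot, annot_a, annot_b)
    stages = {"bbh": bbh, "same_protein": same_prot, "unique_name": unique}
    return unique, stages, funnel_report(stages)


def pairs_table(pairs: list[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"idA": p.idA, "idB": p.idB, "stage": p.stage_passed,
          "best_protein": p.best_protein or ""} for p in pairs],
        columns=["idA", "idB", "stage", "best_protein"])
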