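"""Synthetic dual-transcriptome generator with known ground truth.

Every input the comparative pipeline consumes can be fabricated here:

* ortholog CDS pairs diverged under a GY94-style codon substitution process
  (single-nucleotide changes at rate proportional to the target codon's
  frequency, times kappa for transitions, times omega for nonsynonymous
  changes; each lineage evolves t/2 so the pairwise divergence is t expected
  substitutions per codon);
* similarity-hit tables and annotation tables, with confounders that each
  violate exactly one paralog-exclusion filter (non-reciprocal best hit,
  different best protein, duplicated gene name);
* per-position allele-count pileups with planted bi-allelic SNPs/indels;
* background sequences with planted SSR tracts;
* GO annotation sets with one planted enriched term, plus a toy OBO graph.

All operations take one integer seed and are byte-deterministic; draws occur
in documented order (per pair: ancestor, then lineage A, then lineage B).
Fabricated bitscores are an arbitrary monotone function of simulated
alignment identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from . import codons as cd
from . import ssr as ssr_mod

HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
ANNOT_COLUMNS = ["transcript_id", "protein_accession", "gene_name", "go_terms"]
PILEUP_COLUMNS = ["contig", "pos", "count_A", "count_C", "count_G", "count_T",
                  "count_del", "count_ins"]


@dataclass
class SimTruth:
    """Ground truth emitted alongside every synthetic dataset."""

    ortholog_map: list = field(default_factory=list)   # (idA, idB, omega, kappa, t)
    paralog_ids: list = field(default_factory=list)
    snp_truth: list = field(default_factory=list)      # (contig, pos0, ref, alt, alt_fraction)
    ssr_truth: list = field(default_factory=list)      # (seq_id, start, end, motif, n_repeats)
    decoys: list = field(default_factory=list)         # (idA, idB, filter_violated)


# ---------------------------------------------------------------------------
# Codon-pair simulation
# ---------------------------------------------------------------------------

def gy94_rate_matrix(pi: np.ndarray, kappa: float, omega: float) -> np.ndarray:
    """61x61 generator with single-nucleotide changes only, scaled to one
    expected substitution per codon per unit time at stationarity."""
    Q = np.zeros((cd.N_SENSE, cd.N_SENSE))
    for i in range(cd.N_SENSE):
        for k in range(9):
            j = cd.NB_TARGET[i, k]
            if j < 0:
                continue
            rate = pi[j]
            if cd.NB_TS[i, k]:
                rate *= kappa
            if not cd.NB_SYN[i, k]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    return Q / scale


def _sample_from_rows(P_rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    cum = np.cumsum(P_rows, axis=1)
    cum[:, -1] = 1.0
    return (u[:, None] < cum).argmax(axis=1)


def stationary_codon_frequencies(nuc_freqs=None) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide frequencies
    (uniform by default)."""
    if nuc_freqs is None:
        freqs = np.full((3, 4), 0.25)
    else:
        freqs = np.asarray(nuc_freqs, dtype=float)
        if freqs.shape != (3, 4) or (freqs < 0).any():
            raise ValueError("nuc_freqs must be a non-negative (3, 4) array")
        freqs = freqs / freqs.sum(axis=1, keepdims=True)
    pi = np.array([freqs[0, cd.CODON_NT[i, 0]] * freqs[1, cd.CODON_NT[i, 1]] *
                   freqs[2, cd.CODON_NT[i, 2]] for i in range(cd.N_SENSE)])
    return pi / pi.sum()


def simulate_ortholog_pairs(n_pairs: int, omega, kappa: float, t: float,
                            n_codons: int, seed: int, nuc_freqs=None,
                            id_prefixes=("CF", "PY")):
    """Simulate ``n_pairs`` orthologous CDS pairs.

    ``omega`` may be a scalar or a length-``n_pairs`` sequence of per-pair
    values. Returns ``(seqsA, seqsB, truth)`` where the sequence collections
    are ordered id -> DNA string dictionaries.
    """
    omegas = np.broadcast_to(np.asarray(omega, dtype=float), (n_pairs,)).copy()
    if (omegas <= 0).any():
        raise ValueError("omega must be > 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if t < 0:
        raise ValueError("t must be >= 0")
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10 (degenerate process below that)")

    rng = np.random.default_rng(seed)
    pi = stationary_codon_frequencies(nuc_freqs)
    P_cache: dict[float, np.ndarray] = {}
    for w in np.unique(omegas):
        if t == 0:
            P_cache[w] = np.eye(cd.N_SENSE)
        else:
            P_cache[w] = expm(gy94_rate_matrix(pi, kappa, w) * (t / 2.0))

    seqsA: dict[str, str] = {}
    seqsB: dict[str, str] = {}
    truth = SimTruth()
    width = max(4, len(str(n_pairs)))
    for p in range(n_pairs):
        P = P_cache[omegas[p]]
        anc = _sample_from_rows(np.broadcast_to(pi, (n_codons, cd.N_SENSE)),
                                rng.random(n_codons))
        a = _sample_from_rows(P[anc], rng.random(n_codons))
        b = _sample_from_rows(P[anc], rng.random(n_codons))
        ida = f"{id_prefixes[0]}_{p:0{width}d}"
        idb = f"{id_prefixes[1]}_{p:0{width}d}"
        seqsA[ida] = cd.decode_codons(a)
        seqsB[idb] = cd.decode_codons(b)
        truth.ortholog_map.append((ida, idb, float(omegas[p]), float(kappa), float(t)))
    return seqsA, seqsB, truth


# ---------------------------------------------------------------------------
# Hit tables and annotations
# ---------------------------------------------------------------------------

def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    same = sum(1 for x, y in zip(a, b) if x == y)
    return same / n if n else 0.0


def _hit(q, s, pident, length, qstart, qend, sstart, send, evalue, bitscore):
    return dict(qseqid=q, sseqid=s, pident=round(100 * pident, 2), length=length,
                mismatch=int(round(length * (1 - pident))), gapopen=0,
                qstart=qstart, qend=qend, sstart=sstart, send=send,
                evalue=evalue, bitscore=round(bitscore, 1))


def _evalue_from_bitscore(bitscore: float) -> float:
    return float(max(10.0 ** (-bitscore / 10.0), 1e-180))


def simulate_hit_tables(truth: SimTruth, seqsA: dict, seqsB: dict,
                        n_decoys: int = 0, seed: int = 0, *,
                        n_nonreciprocal: int | None = None,
                        n_diff_protein: int | None = None,
                        n_dup_name: int | None = None):
    """Fabricate the similarity-search and annotation inputs for orthology.

    True pairs receive mutually top-scoring cross-species hits and matching
    best-protein hits. Confounders violate exactly one filter each and are
    recorded on ``truth.decoys``: ``n_nonreciprocal`` extra transcripts whose
    best hit is not reciprocated, ``n_diff_protein`` true pairs whose B member
    best-matches a different protein, ``n_dup_name`` true pairs whose gene
    name is duplicated in annotation table A. When only ``n_decoys`` is given
    it is split round-robin over the three kinds.

    Returns ``(hitsAB, hitsBA, hitsA_protein, hitsB_protein, annotA, annotB)``
    as DataFrames in the 12-column tabular-search / annotation layouts.
    """
    if n_nonreciprocal is None and n_diff_protein is None and n_dup_name is None:
        base, extra = divmod(n_decoys, 3)
        n_nonreciprocal = base + (1 if extra > 0 else 0)
        n_diff_protein = base + (1 if extra > 1 else 0)
        n_dup_name = base
    n_nonreciprocal = n_nonreciprocal or 0
    n_diff_protein = n_diff_protein or 0
    n_dup_name = n_dup_name or 0

    pairs = truth.ortholog_map
    for ida, idb, *_ in pairs:
        if ida not in seqsA or idb not in seqsB:
            raise KeyError(f"truth pair ({ida}, {idb}) not present in the FASTA inputs")
    if n_diff_protein + n_dup_name > len(pairs):
        raise ValueError("more filter confounders requested than true pairs available")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    diff_prot_idx = set(perm[:n_diff_protein].tolist())
    dup_name_idx = set(perm[n_diff_protein:n_diff_protein + n_dup_name].tolist())

    hits_ab, hits_ba, prot_a, prot_b = [], [], [], []
    annot_a, annot_b = [], []

    for i, (ida, idb, *_rest) in enumerate(pairs):
        sa, sb = seqsA[ida], seqsB[idb]
        ident = _identity(sa, sb)
        bits = 2.0 * ident * len(sa)
        ev = _evalue_from_bitscore(bits)
        hits_ab.append(_hit(ida, idb, ident, len(sa), 1, len(sa), 1, len(sb), ev, bits))
        hits_ba.append(_hit(idb, ida, ident, len(sb), 1, len(sb), 1, len(sa), ev, bits))
        if i > 0:
            # weaker off-target cross hits so "best" is a real maximisation
            prev_b = pairs[i - 1][1]
            prev_a = pairs[i - 1][0]
            hits_ab.append(_hit(ida, prev_b, 0.3 * ident, len(sa), 1, len(sa),
                                1, len(seqsB[prev_b]), 1e-8, 0.4 * bits))
            hits_ba.append(_hit(idb, prev_a, 0.3 * ident, len(sb), 1, len(sb),
                                1, len(seqsA[prev_a]), 1e-8, 0.4 * bits))
        acc = f"P{i:05d}"
        acc_b = acc
        if i in diff_prot_idx:
            acc_b = f"PD{i:05d}"
            truth.decoys.append((ida, idb, "diff_protein"))
        pbits = 1.8 * len(sa)
        pev = _evalue_from_bitscore(pbits)
        prot_a.append(_hit(ida, acc, 0.95, len(sa) // 3, 1, len(sa), 1, len(sa) // 3,
                           pev, pbits))
        prot_b.append(_hit(idb, acc_b, 0.95, len(sb) // 3, 1, len(sb), 1, len(sb) // 3,
                           pev, pbits))
        # secondary, weaker protein hit
        prot_a.append(_hit(ida, f"PX{i:05d}", 0.5, len(sa) // 3, 1, len(sa), 1,
                           len(sa) // 3, 1e-9, 0.5 * pbits))
        gene = f"GENE{i:05d}"
        annot_a.append(dict(transcript_id=ida, protein_accession=acc,
                            gene_name=gene, go_terms=""))
        annot_b.append(dict(transcript_id=idb, protein_accession=acc_b,
                            gene_name=gene, go_terms=""))
        if i in dup_name_idx:
            dup_id = f"{ida}_DUP"
            annot_a.append(dict(transcript_id=dup_id, protein_accession=f"PQ{i:05d}",
                                gene_name=gene, go_terms=""))
            truth.paralog_ids.append(dup_id)
            truth.decoys.append((ida, idb, "dup_name"))

    width = max(4, len(str(n_nonreciprocal)))
    for k in range(n_nonreciprocal):
        ax, bx = f"CFX_{k:0{width}d}", f"PYX_{k:0{width}d}"
        anchor_a = pairs[k % len(pairs)][0] if pairs else None
        hits_ab.append(_hit(ax, bx, 0.9, 300, 1, 300, 1, 300, 1e-40, 400.0))
        if anchor_a is not None:
            # bx reciprocates towards an established transcript instead
            hits_ba.append(_hit(bx, anchor_a, 0.95, 300, 1, 300, 1, 300, 1e-60, 600.0))
        hits_ba.append(_hit(bx, ax, 0.9, 300, 1, 300, 1, 300, 1e-40, 400.0))
        # decoy-only noise hit above the usual E-value threshold
        hits_ab.append(_hit(ax, pairs[0][1] if pairs else bx, 0.2, 50, 1, 50,
                            1, 50, 1e-3, 20.0))
        annot_a.append(dict(transcript_id=ax, protein_accession=f"PNR{k}",
                            gene_name=f"GENENR{k}", go_terms=""))
        annot_b.append(dict(transcript_id=bx, protein_accession=f"PNR{k}",
                            gene_name=f"GENENR{k}", go_terms=""))
        truth.paralog_ids.extend([ax, bx])
        truth.decoys.append((ax, bx, "nonreciprocal"))

    def _df(rows, cols):
        return pd.DataFrame(rows, columns=cols)

    return (_df(hits_ab, HIT_COLUMNS), _df(hits_ba, HIT_COLUMNS),
            _df(prot_a, HIT_COLUMNS), _df(prot_b, HIT_COLUMNS),
            _df(annot_a, ANNOT_COLUMNS), _df(annot_b, ANNOT_COLUMNS))


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def simulate_pileup(contig_len: int, snps, depth: int, error_rate: float,
                    seed: int, contig_id: str = "contig_1"):
    """Per-position allele counts with planted bi-allelic variants.

    ``snps`` is a list of ``(position, ref, alt, alt_fraction)`` with 0-based
    positions; ``alt`` may be a base, ``"del"`` or ``"ins"``. Alternate read
    counts are binomial(depth, alt_fraction); substitution errors move base
    reads to a uniformly chosen other base at ``error_rate`` per read.

    Returns ``(pileup DataFrame, truth list)``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    seen = set()
    for pos, ref, alt, f in snps:
        if not 0 <= pos < contig_len:
            raise ValueError(f"SNP position {pos} outside contig of length {contig_len}")
        if pos in seen:
            raise ValueError(f"position collision at {pos}")
        seen.add(pos)
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"alt_fraction {f} outside [0, 1]")
        if ref not in _BASES:
            raise ValueError(f"ref allele {ref!r} must be a base")
        if alt not in list(_BASES) + ["del", "ins"]:
            raise ValueError(f"unsupported alt allele {alt!r}")

    rng = np.random.default_rng(seed)
    ref_seq = rng.choice(list(_BASES), size=contig_len)
    by_pos = {pos: (ref, alt, f) for pos, ref, alt, f in snps}
    for pos, (ref, _alt, _f) in by_pos.items():
        ref_seq[pos] = ref

    rows = []
    truth = []
    for pos in range(contig_len):
        counts = dict.fromkeys(["A", "C", "G", "T", "del", "ins"], 0)
        ref = str(ref_seq[pos])
        if pos in by_pos:
            _, alt, f = by_pos[pos]
            n_alt = int(rng.binomial(depth, f))
            counts[alt] += n_alt
            truth.append((contig_id, pos, ref, alt, f))
        else:
            n_alt = 0
        counts[ref] += depth - n_alt
        if error_rate > 0:
            for base in list(_BASES):
                n = counts[base]
                if n == 0:
                    continue
                n_err = int(rng.binomial(n, error_rate))
                if n_err == 0:
                    continue
                counts[base] -= n_err
                others = [b for b in _BASES if b != base]
                spread = rng.multinomial(n_err, [1 / 3] * 3)
                for b, k in zip(others, spread):
                    counts[b] += int(k)
        rows.append(dict(contig=contig_id, pos=pos,
                         count_A=counts["A"], count_C=counts["C"],
                         count_G=counts["G"], count_T=counts["T"],
                         count_del=counts["del"], count_ins=counts["ins"]))
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS), truth


# ---------------------------------------------------------------------------
# SSR planting
# ---------------------------------------------------------------------------

def plant_ssrs(n_seqs: int, seq_len: int, tracts, seed: int,
               min_total_len: int = 15, min_repeats: float = 3,
               max_attempts: int = 500):
    """Random background sequences with SSR tracts planted at recorded spans.

    Tracts (``(motif, n_repeats)``, motif length 2-6) are assigned round-robin
    to sequences. Backgrounds that spontaneously contain qualifying tracts, or
    that extend a planted tract beyond its recorded span, are rejected and
    regenerated, so detector output on the result should match truth exactly.
    Sub-threshold tracts are planted too and serve as negative controls.

    Returns ``(seqs dict, truth list of (seq_id, start, end, motif, n_repeats))``.
    """
    for motif, n_rep in tracts:
        if not 2 <= len(motif) <= 6:
            raise ValueError(f"motif length must be 2-6: {motif!r}")
        if not ssr_mod.is_primitive(motif):
            raise ValueError(f"motif {motif!r} is not primitive")
        if len(motif) * n_rep > seq_len:
            raise ValueError(f"tract {motif}x{n_rep} longer than sequence ({seq_len} bp)")

    rng = np.random.default_rng(seed)
    per_seq: list[list[tuple[str, int]]] = [[] for _ in range(n_seqs)]
    for k, tract in enumerate(tracts):
        per_seq[k % n_seqs].append(tract)

    seqs: dict[str, str] = {}
    truth = []
    for s in range(n_seqs):
        sid = f"SSRSEQ_{s:04d}"
        planted = None
        for _attempt in range(max_attempts):
            bg = "".join(rng.choice(list(_BASES), size=seq_len))
            spans = []
            ok = True
            for motif, n_rep in per_seq[s]:
                tract_seq = (motif * int(np.ceil(n_rep)))[:int(round(len(motif) * n_rep))]
                placed = False
                for _try in range(50):
                    start = int(rng.integers(0, seq_len - len(tract_seq) + 1))
                    end = start + len(tract_seq)
                    if all(end <= a or start >= b for a, b, *_ in spans):
                        spans.append((start, end, motif, n_rep, tract_seq))
                        placed = True
                        break
                if not placed:
                    ok = False
                    break
            if not ok:
                continue
            chars = list(bg)
            for start, end, motif, n_rep, tract_seq in spans:
                chars[start:end] = tract_seq
            candidate = "".join(chars)
            detected = ssr_mod.find_ssrs(candidate, seq_id=sid,
                                         min_total_len=min_total_len,
                                         min_repeats=min_repeats)
            expected = sorted((a, b) for a, b, m, nr, _ in spans
                              if (b - a) >= min_total_len and nr >= min_repeats)
            if sorted((l.start, l.end) for l in detected) == expected:
                planted = spans
                seqs[sid] = candidate
                break
        if planted is None:
            raise RuntimeError(f"could not place tracts in {sid} without spurious repeats")
        for start, end, motif, n_rep, _seq in sorted(planted):
            truth.append((sid, start, end, motif, float(n_rep)))
    return seqs, truth


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------

def simulate_go_annotations(n_genes: int, n_terms: int, enriched_term: str | None = None,
                            study_fraction_with_term: float = 0.8,
                            background_fraction: float = 0.1, seed: int = 0,
                            gene_ids=None, study_genes=None, n_study: int | None = None):
    """Annotation table + toy OBO graph with one planted enriched term.

    The ontology is a three-layer DAG (one namespace root, three mid-level
    terms, ``n_terms`` leaves). The planted term is carried by study genes at
    ``study_fraction_with_term`` and by everything else (and every other term
    by everyone) at ``background_fraction``.

    Returns ``(annotation DataFrame, obo text, truth dict)``.
    """
    if not (0 <= background_fraction <= 1 and 0 <= study_fraction_with_term <= 1):
        raise ValueError("fractions must be in [0, 1]")
    genes = list(gene_ids) if gene_ids is not None else [f"G{i:04d}" for i in range(n_genes)]
    n_genes = len(genes)
    if study_genes is not None:
        study = [g for g in genes if g in set(study_genes)]
    else:
        k = n_study if n_study is not None else max(n_genes // 5, 1)
        study = genes[:k]
    study_set = set(study)

    root = "GO:0008150"
    mids = ["GO:0000002", "GO:0000003", "GO:0000004"]
    leaves = [f"GO:{1000001 + i:07d}" for i in range(n_terms)]
    if enriched_term is None:
        enriched_term = leaves[0]
    if enriched_term not in leaves:
        raise ValueError(f"enriched_term {enriched_term} is not one of the generated terms")

    stanzas = ["format-version: 1.2", "ontology: go", ""]
    stanzas += ["[Term]", f"id: {root}", "name: biological_process",
                "namespace: biological_process", ""]
    for j, mid in enumerate(mids):
        stanzas += ["[Term]", f"id: {mid}", f"name: mid process {j}",
                    "namespace: biological_process", f"is_a: {root} ! biological_process", ""]
    for i, leaf in enumerate(leaves):
        stanzas += ["[Term]", f"id: {leaf}", f"name: leaf process {i}",
                    "namespace: biological_process",
                    f"is_a: {mids[i % 3]} ! mid process {i % 3}", ""]
    obo_text = "\n".join(stanzas)

    rng = np.random.default_rng(seed)
    rows = []
    for g in genes:
        terms = []
        for term in leaves:
            if term == enriched_term and g in study_set:
                p = study_fraction_with_term
            else:
                p = background_fraction
            if rng.random() < p:
                terms.append(term)
        rows.append(dict(gene=g, go_terms=";".join(terms)))
    annot = pd.DataFrame(rows, columns=["gene", "go_terms"])
    return annot, obo_text, {"enriched_term": enriched_term, "study_genes": study}
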