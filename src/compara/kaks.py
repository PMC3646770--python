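"""Pairwise Ka/Ks estimation for ortholog CDS pairs.

Implements the two classic approximate counting methods:

* NG86 (Nei & Gojobori 1986): unweighted pathway counting with a
  Jukes-Cantor multiple-hit correction; used here mainly as a transparent
  cross-check.
* YN00 (Yang & Nielsen 2000 style): F3x4 codon frequencies estimated from
  the pair, transition/transversion ratio kappa estimated from
  fourfold-degenerate and nondegenerate sites, mutation- and kappa-weighted
  site counting, omega-weighted pathway counting iterated to convergence,
  and K80-style corrections applied separately to the synonymous and
  nonsynonymous site classes.

Significance of omega != 1 is assessed with a two-sided Fisher exact test
on the (differences x site-class) 2x2 table, the convention of pairwise
Ka/Ks toolkits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from scipy import stats

from . import codons as cd

COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# CDS extraction and screening
# ---------------------------------------------------------------------------

def extract_cds(transcript: str, qstart: int, qend: int) -> str:
    """Slice the coding region located by a translated similarity hit.

    ``qstart``/``qend`` are 1-based inclusive query coordinates as emitted by
    tabular search output; ``qstart > qend`` marks a reverse-frame hit, in
    which case the slice is reverse-complemented. The 3' end is trimmed so
    the result length is a multiple of 3.
    """
    lo, hi = (qstart, qend) if qstart <= qend else (qend, qstart)
    if lo < 1 or hi > len(transcript):
        raise ValueError(
            f"hit coordinates [{qstart}, {qend}] outside transcript of length {len(transcript)}")
    sub = transcript[lo - 1:hi]
    if qstart > qend:
        sub = reverse_complement(sub)
    return sub[:len(sub) - len(sub) % 3]


def screen_stops(cds: str, table: int = 1):
    """Reject CDSs with internal stop codons; strip a terminal stop.

    Returns ``(passed, screened_cds)``; ``screened_cds`` is None on failure.
    """
    if len(cds) % 3:
        raise ValueError("CDS length is not a multiple of 3")
    cds = cds.upper()
    codon_list = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if not codon_list:
        return True, ""
    if codon_list[-1] in cd.STOP_CODONS:
        codon_list = codon_list[:-1]
    if any(c in cd.STOP_CODONS for c in codon_list):
        return False, None
    return True, "".join(codon_list)


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Gap-free paired codon columns under the standard genetic code."""

    codonsA: np.ndarray  # sense-codon indices
    codonsB: np.ndarray
    dropped_gap_columns: int = 0
    dropped_ambiguous_columns: int = 0

    @property
    def n_codons(self) -> int:
        return len(self.codonsA)


def _make_aligner(gap_open: float, gap_extend: float, matrix: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def align_codons(cdsA: str, cdsB: str, matrix: str = "BLOSUM62",
                 gap_open: float = 10.0, gap_extend: float = 0.5) -> CodonAlignment:
    """Protein-guided codon alignment of two stop-screened CDSs.

    The translations are globally aligned, codons are threaded back through
    the protein alignment, and columns containing a gap or an ambiguous
    nucleotide are discarded (counted in the QC fields).
    """
    protA, protB = str(Seq(cdsA).translate()), str(Seq(cdsB).translate())
    aligner = _make_aligner(gap_open, gap_extend, matrix)
    aln = aligner.align(protA, protB)[0]
    a_idx, b_idx = [], []
    n_gap = n_ambig = 0
    ra, rb = aln.aligned
    # aln.aligned gives matched blocks [(astart, aend)], [(bstart, bend)]
    gap_cols = len(protA) + len(protB)
    matched = 0
    for (a0, a1), (b0, b1) in zip(ra, rb):
        for off in range(a1 - a0):
            ca = cdsA[3 * (a0 + off): 3 * (a0 + off) + 3]
            cbv = cdsB[3 * (b0 + off): 3 * (b0 + off) + 3]
            matched += 1
            ia = cd.CODON_INDEX.get(ca.upper())
            ib = cd.CODON_INDEX.get(cbv.upper())
            if ia is None or ib is None:
                n_ambig += 1
                continue
            a_idx.append(ia)
            b_idx.append(ib)
    n_gap = gap_cols - 2 * matched  # residues left unmatched on either side
    if not a_idx:
        raise ValueError("alignment empty after discarding gap/ambiguous columns")
    return CodonAlignment(np.array(a_idx, dtype=np.int64),
                          np.array(b_idx, dtype=np.int64),
                          dropped_gap_columns=n_gap,
                          dropped_ambiguous_columns=n_ambig)


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------

@dataclass
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    kappa: float | None
    Ka: float | None
    Ks: float | None
    omega: float | None
    method: str
    p_value: float | None = None
    n_codons: int = 0
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_codons": self.n_codons, "S": self.S, "N": self.N,
            "Sd": self.Sd, "Nd": self.Nd, "kappa": self.kappa,
            "Ka": self.Ka, "Ks": self.Ks, "omega": self.omega,
            "p_value": self.p_value, "method": self.method,
            "flags": ";".join(self.flags),
        }


def _jukes_cantor(p: float):
    """JC69 distance; returns (d, ok)."""
    if p < 0:
        p = 0.0
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return math.nan, False
    return -0.75 * math.log(arg) + 0.0, True


def _k80(P: float, Q: float):
    """K80 distance split into transition and transversion parts.

    Returns (d, d_ts, d_tv, ok).
    """
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0 or a2 <= 0:
        return math.nan, math.nan, math.nan, False
    d_ts = -0.5 * math.log(a1) + 0.25 * math.log(a2) + 0.0
    d_tv = -0.5 * math.log(a2) + 0.0
    return d_ts + d_tv + 0.0, d_ts, d_tv, True


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def _ng86_differences(ia: int, ib: int):
    """Pathway-averaged (synonymous, nonsynonymous) differences for one codon pair."""
    if ia == ib:
        return 0.0, 0.0
    paths = cd.substitution_paths(ia, ib)
    sd = nd = 0.0
    for path in paths:
        for _tgt, _ts, syn in path:
            if syn:
                sd += 1.0
            else:
                nd += 1.0
    return sd / len(paths), nd / len(paths)


def ng86(aln: CodonAlignment) -> KaKsResult:
    """Nei-Gojobori (1986) pathway counting with Jukes-Cantor correction."""
    ia, ib = aln.codonsA, aln.codonsB
    L = aln.n_codons
    S = 0.5 * (cd.NG86_SYN_SITES[ia].sum() + cd.NG86_SYN_SITES[ib].sum())
    N = 3.0 * L - S
    Sd = Nd = 0.0
    pair_keys, counts = np.unique(ia * cd.N_SENSE + ib, return_counts=True)
    for key, cnt in zip(pair_keys, counts):
        sd, nd = _ng86_differences(int(key) // cd.N_SENSE, int(key) % cd.N_SENSE)
        Sd += cnt * sd
        Nd += cnt * nd
    flags = []
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks, ok_s = _jukes_cantor(pS)
    Ka, ok_n = _jukes_cantor(pN)
    if not ok_s:
        Ks, flags = None, flags + ["Ks_saturated"]
    if not ok_n:
        Ka, flags = None, flags + ["Ka_saturated"]
    omega = None
    if Ks is not None and Ka is not None:
        if Ks > 0:
            omega = Ka / Ks
        else:
            flags.append("Ks_zero")
            omega = 0.0 if Ka == 0 else None
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, kappa=None, Ka=Ka, Ks=Ks,
                      omega=omega, method="NG86", n_codons=L, flags=flags)


# ---------------------------------------------------------------------------
# YN00
# ---------------------------------------------------------------------------

def estimate_kappa(ia: np.ndarray, ib: np.ndarray, default: float = 2.0):
    """kappa from K80 applied at fourfold-degenerate and nondegenerate sites.

    A codon position enters a class only when it has the same degeneracy (0-
    or 4-fold) in both codons of the pair; the two class estimates are
    combined weighted by their site counts. Returns (kappa, flags).
    """
    degA, degB = cd.DEGENERACY[ia], cd.DEGENERACY[ib]     # (L, 3)
    ntA, ntB = cd.CODON_NT[ia], cd.CODON_NT[ib]
    differ = ntA != ntB
    purA = (ntA == cd.NUC_INDEX["A"]) | (ntA == cd.NUC_INDEX["G"])
    purB = (ntB == cd.NUC_INDEX["A"]) | (ntB == cd.NUC_INDEX["G"])
    is_ts = differ & (purA == purB)
    is_tv = differ & (purA != purB)

    estimates, weights = [], []
    for klass in (0, 4):
        mask = (degA == klass) & (degB == klass)
        Lk = int(mask.sum())
        if Lk == 0:
            continue
        P = is_ts[mask].sum() / Lk
        Q = is_tv[mask].sum() / Lk
        _, d_ts, d_tv, ok = _k80(P, Q)
        if not ok or d_tv <= 0:
            continue
        estimates.append(2.0 * d_ts / d_tv)
        weights.append(Lk)
    if not estimates:
        return default, ["kappa_default"]
    kappa = float(np.average(estimates, weights=weights))
    return max(kappa, 1e-6), []


def _yn00_site_fractions(pi: np.ndarray, kappa: float) -> np.ndarray:
    """Synonymous sites per codon under mutation rates ~ pi_target * kappa^ts."""
    tgt_ok = cd.NB_TARGET >= 0
    w = np.where(tgt_ok, pi[np.clip(cd.NB_TARGET, 0, None)], 0.0)
    w = w * np.where(cd.NB_TS, kappa, 1.0)
    tot = w.sum(axis=1)
    syn = (w * cd.NB_SYN).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, syn / tot, 0.0)
    return 3.0 * frac


def _weighted_differences(pair_keys, counts, pi, kappa, omega):
    """omega/kappa/frequency-weighted pathway counts split by ts/tv and syn/nonsyn."""
    mean_pi = float(pi.mean())
    sd_ts = sd_tv = nd_ts = nd_tv = 0.0
    for key, cnt in zip(pair_keys, counts):
        ia, ib = int(key) // cd.N_SENSE, int(key) % cd.N_SENSE
        if ia == ib:
            continue
        paths = cd.substitution_paths(ia, ib)
        path_w = []
        path_counts = []
        for path in paths:
            w = 1.0
            c = [0.0, 0.0, 0.0, 0.0]  # sd_ts, sd_tv, nd_ts, nd_tv
            for tgt, ts, syn in path:
                w *= (pi[tgt] if tgt >= 0 else mean_pi)
                if ts:
                    w *= kappa
                if not syn:
                    w *= omega
                c[(0 if syn else 2) + (0 if ts else 1)] += 1.0
            path_w.append(w)
            path_counts.append(c)
        tot = sum(path_w)
        if tot <= 0:
            path_w = [1.0] * len(paths)
            tot = float(len(paths))
        for w, c in zip(path_w, path_counts):
            f = cnt * w / tot
            sd_ts += f * c[0]
            sd_tv += f * c[1]
            nd_ts += f * c[2]
            nd_tv += f * c[3]
    return sd_ts, sd_tv, nd_ts, nd_tv


def yn00(aln: CodonAlignment, max_iter: int = 100, tol: float = 1e-6,
         min_codons_warn: int = 30) -> KaKsResult:
    """Approximate Ka/Ks with kappa- and codon-frequency-weighted counting.

    Iterates the omega used in pathway weighting until the estimate moves by
    less than ``tol`` (or ``max_iter`` is hit, flagged ``not_converged``).
    """
    ia, ib = aln.codonsA, aln.codonsB
    L = aln.n_codons
    if L < min_codons_warn:
        warnings.warn(f"alignment of {L} codons is short for YN00; "
                      "estimates will be noisy", stacklevel=2)
    flags: list[str] = []
    pi = cd.f3x4_frequencies(np.concatenate([ia, ib]))
    kappa, kflags = estimate_kappa(ia, ib)
    flags += kflags

    sfrac = _yn00_site_fractions(pi, kappa)
    S = 0.5 * (sfrac[ia].sum() + sfrac[ib].sum())
    N = 3.0 * L - S

    pair_keys, counts = np.unique(ia * cd.N_SENSE + ib, return_counts=True)
    if (ia == ib).all():
        return KaKsResult(S=S, N=N, Sd=0.0, Nd=0.0, kappa=kappa, Ka=0.0,
                          Ks=0.0, omega=None, method="YN00", n_codons=L,
                          flags=flags + ["no_differences"])

    omega = 1.0
    Sd = Nd = 0.0
    Ka = Ks = None
    for _ in range(max_iter):
        sd_ts, sd_tv, nd_ts, nd_tv = _weighted_differences(
            pair_keys, counts, pi, kappa, omega)
        Sd, Nd = sd_ts + sd_tv, nd_ts + nd_tv
        ds, ds_ok = math.nan, False
        dn, dn_ok = math.nan, False
        if S > 0:
            ds, _, _, ds_ok = _k80(sd_ts / S, sd_tv / S)
        if N > 0:
            dn, _, _, dn_ok = _k80(nd_ts / N, nd_tv / N)
        if not ds_ok:
            flags.append("Ks_saturated")
            Ka = dn if dn_ok else None
            break
        if not dn_ok:
            flags.append("Ka_saturated")
            Ks = ds
            break
        Ka, Ks = dn, ds
        if ds <= 0:
            flags.append("Ks_zero")
            break
        new_omega = dn / ds
        if abs(new_omega - omega) < tol:
            omega = new_omega
            break
        omega = new_omega
    else:
        flags.append("not_converged")

    out_omega = None
    if Ka is not None and Ks is not None and Ks > 0 and "Ks_saturated" not in flags:
        out_omega = Ka / Ks
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, kappa=kappa, Ka=Ka, Ks=Ks,
                      omega=out_omega, method="YN00", n_codons=L, flags=flags)


# ---------------------------------------------------------------------------
# Significance and classification
# ---------------------------------------------------------------------------

def kaks_significance(result: KaKsResult) -> float:
    """Two-sided Fisher exact test of equal substitution density at
    synonymous vs nonsynonymous sites.

    Table: [[round(Sd), round(Nd)], [round(S - Sd), round(N - Nd)]], cells
    clamped at zero (flagged) if a corrected count exceeds its sites.
    """
    cells = [round(result.Sd), round(result.Nd),
             round(result.S - result.Sd), round(result.N - result.Nd)]
    if min(cells) < 0:
        result.flags.append("clamped_table")
        cells = [max(c, 0) for c in cells]
    table = [[cells[0], cells[1]], [cells[2], cells[3]]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    result.p_value = float(p)
    return result.p_value


LABELS = ("constrained", "neutral", "fast_evolving")


def classify_selection(results: list[KaKsResult], alpha: float = 0.05):
    """Label each pair and tally the selection-class funnel.

    fast_evolving: omega > 1 with p < alpha; constrained: omega < 1 with
    p < alpha; everything else (including undefined omega) neutral/untyped.
    Returns (labels, counts) where counts mirrors the ratio-vs-significance
    breakdown (omega<1, significantly<1, omega>1, significantly>1, undefined).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    labels = []
    counts = {"lt1": 0, "sig_lt1": 0, "gt1": 0, "sig_gt1": 0, "undefined": 0}
    for r in results:
        if r.p_value is None:
            kaks_significance(r)
        if r.omega is None:
            counts["undefined"] += 1
            labels.append("neutral")
            continue
        if r.omega < 1:
            counts["lt1"] += 1
            if r.p_value < alpha:
                counts["sig_lt1"] += 1
                labels.append("constrained")
            else:
                labels.append("neutral")
        elif r.omega > 1:
            counts["gt1"] += 1
            if r.p_value < alpha:
                counts["sig_gt1"] += 1
                labels.append("fast_evolving")
            else:
                labels.append("neutral")
        else:
            labels.append("neutral")
    return labels, counts


def compute_pair(cdsA: str, cdsB: str, method: str = "YN00",
                 alpha: float = 0.05) -> KaKsResult:
    """Screen, align and estimate one CDS pair end to end."""
    okA, sA = screen_stops(cdsA)
    okB, sB = screen_stops(cdsB)
    if not (okA and okB):
        raise ValueError("internal stop codon in CDS")
    aln = align_codons(sA, sB)
    result = yn00(aln) if method.upper() == "YN00" else ng86(aln)
    kaks_significance(result)
    return result
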