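"""Standard-genetic-code combinatorics shared by the codon simulator and the Ka/Ks estimators.

Everything here is derived once, at import time, from the standard nuclear
code (NCBI translation table 1): the 61 sense codons, their single-nucleotide
neighbourhoods annotated with transition/transversion and synonymous/
nonsynonymous status, per-position degeneracy classes, and the NG86
synonymous-site fraction of each codon.

Conventions
-----------
* Codons are uppercase DNA 3-mers over ACGT; the 61 sense codons are indexed
  in lexicographic order (``SENSE_CODONS[i]``).
* Mutations that would create a stop codon are excluded from site counting
  (both numerator and denominator of the per-position synonymous fraction),
  following common NG86 practice.
* Degeneracy of a codon position: 4 if every non-stop single-nucleotide
  change at that position is synonymous (and all three changes are non-stop),
  0 if none is synonymous, 2 otherwise.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCS = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}
PURINES = frozenset("AG")

_table = CodonTable.unambiguous_dna_by_id[1]

ALL_CODONS = ["".join(c) for c in itertools.product(NUCS, repeat=3)]
STOP_CODONS = frozenset(_table.stop_codons)
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)  # 61

AA = {c: _table.forward_table[c] for c in SENSE_CODONS}


def is_transition(a: str, b: str) -> bool:
    """True if the a<->b nucleotide change is purine<->purine or pyrimidine<->pyrimidine."""
    return a != b and (a in PURINES) == (b in PURINES)


def _build_neighbors():
    """For each sense codon, its 9 single-nucleotide mutants.

    Returns index arrays shaped (61, 9): target sense-codon index (-1 for a
    stop target), mutated position, transition flag, synonymous flag (False
    for stop targets).
    """
    tgt = np.full((N_SENSE, 9), -1, dtype=np.int64)
    pos = np.zeros((N_SENSE, 9), dtype=np.int64)
    ts = np.zeros((N_SENSE, 9), dtype=bool)
    syn = np.zeros((N_SENSE, 9), dtype=bool)
    for i, codon in enumerate(SENSE_CODONS):
        k = 0
        for p in range(3):
            for n in NUCS:
                if n == codon[p]:
                    continue
                mutant = codon[:p] + n + codon[p + 1:]
                pos[i, k] = p
                ts[i, k] = is_transition(codon[p], n)
                if mutant not in STOP_CODONS:
                    j = CODON_INDEX[mutant]
                    tgt[i, k] = j
                    syn[i, k] = AA[mutant] == AA[codon]
                k += 1
    return tgt, pos, ts, syn


NB_TARGET, NB_POS, NB_TS, NB_SYN = _build_neighbors()

# nucleotide index of each sense codon at each position, shape (61, 3)
CODON_NT = np.array([[NUC_INDEX[c[p]] for p in range(3)] for c in SENSE_CODONS],
                    dtype=np.int64)


def _build_degeneracy():
    deg = np.zeros((N_SENSE, 3), dtype=np.int64)
    for i in range(N_SENSE):
        for p in range(3):
            k = NB_POS[i] == p
            nonstop = NB_TARGET[i] >= 0
            n_nonstop = int((k & nonstop).sum())
            n_syn = int((k & NB_SYN[i]).sum())
            if n_nonstop == 3 and n_syn == 3:
                deg[i, p] = 4
            elif n_syn == 0:
                deg[i, p] = 0
            else:
                deg[i, p] = 2
    return deg


DEGENERACY = _build_degeneracy()


def _build_ng86_site_fractions():
    """NG86 synonymous sites per codon, stop-target changes excluded."""
    s = np.zeros(N_SENSE)
    for i in range(N_SENSE):
        total = 0.0
        for p in range(3):
            k = NB_POS[i] == p
            nonstop = k & (NB_TARGET[i] >= 0)
            n_nonstop = int(nonstop.sum())
            if n_nonstop == 0:
                continue
            total += (k & NB_SYN[i]).sum() / n_nonstop
        s[i] = total
    return s


NG86_SYN_SITES = _build_ng86_site_fractions()


@lru_cache(maxsize=None)
def substitution_paths(ia: int, ib: int):
    """All orderings of single-nucleotide steps turning codon ia into ib.

    Paths whose intermediate codons are stops are discarded; if every
    ordering passes through a stop, all orderings are returned instead (the
    conventional fallback so the pair still contributes differences).

    Returns a tuple of paths; each path is a tuple of steps
    ``(target_sense_index, is_transition, is_synonymous)``.
    """
    a, b = SENSE_CODONS[ia], SENSE_CODONS[ib]
    diff = [p for p in range(3) if a[p] != b[p]]
    valid, fallback = [], []
    for order in itertools.permutations(diff):
        cur = a
        steps = []
        through_stop = False
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1:]
            if nxt in STOP_CODONS:
                through_stop = True
                break
            steps.append((CODON_INDEX[nxt],
                          is_transition(cur[p], b[p]),
                          AA[nxt] == AA[cur]))
            cur = nxt
        if not through_stop:
            valid.append(tuple(steps))
        fallback.append(order)
    if valid:
        return tuple(valid)
    # every ordering crosses a stop: count steps anyway, stop steps as
    # nonsynonymous with target index -1 (weighted by mean frequency)
    paths = []
    for order in fallback:
        cur = a
        steps = []
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1:]
            tsflag = is_transition(cur[p], b[p])
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                steps.append((CODON_INDEX.get(nxt, -1), tsflag, False))
            else:
                steps.append((CODON_INDEX[nxt], tsflag, AA[nxt] == AA[cur]))
            cur = nxt
        paths.append(tuple(steps))
    return tuple(paths)


def f3x4_frequencies(codon_indices: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies over the 61 sense codons.

    Position-specific nucleotide frequencies are tallied from the supplied
    codons (an integer index array into SENSE_CODONS), multiplied across the
    three positions and renormalised after removing stop codons.
    """
    codon_indices = np.asarray(codon_indices)
    nt = CODON_NT[codon_indices]            # (L, 3)
    freqs = np.zeros((3, 4))
    for p in range(3):
        counts = np.bincount(nt[:, p], minlength=4).astype(float)
        # guard: a position with a missing nucleotide gets a pseudo-count so
        # observed codons never receive zero frequency
        if (counts == 0).any():
            counts += 0.5
        freqs[p] = counts / counts.sum()
    pi = np.array([freqs[0, CODON_NT[i, 0]] *
                   freqs[1, CODON_NT[i, 1]] *
                   freqs[2, CODON_NT[i, 2]] for i in range(N_SENSE)])
    return pi / pi.sum()


def encode_codons(seq: str) -> np.ndarray:
    """Sense-codon index array for an in-frame DNA string (no stops, len % 3 == 0)."""
    if len(seq) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    idx = np.empty(len(seq) // 3, dtype=np.int64)
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3].upper()
        j = CODON_INDEX.get(codon)
        if j is None:
            raise ValueError(f"codon {codon!r} at position {i} is a stop or ambiguous")
        idx[i // 3] = j
    return idx


def decode_codons(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)
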