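"""Perfect microsatellite (SSR) detection and summary.

Finds maximal perfect tandem repeats of 2-6 bp motifs and reports tracts
meeting joint length/repeat-count thresholds (defaults: total length >= 15 bp
and >= 3 repeats, the SciRoKo-style settings used for transcriptome marker
mining). Motifs are grouped into canonical classes invariant to rotation and
reverse complementation, the convention behind "AT", "ATC", "AAAT"-style
motif class labels.

Only perfect repeats are reported; a trailing partial repeat extends a
tract's length fractionally unless ``count_partial=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

MOTIF_CLASS_NAMES = {2: "Dinucleotides", 3: "Trinucleotides", 4: "Tetranucleotides",
                     5: "Pentanucleotides", 6: "Hexanucleotides"}


def _smallest_period(s: str) -> int:
    n = len(s)
    for p in range(1, n):
        if n % p == 0 and s == s[:p] * (n // p):
            return p
    return n


def is_primitive(motif: str) -> bool:
    """True when the motif is not itself a repetition of a shorter unit."""
    return _smallest_period(motif) == len(motif)


def canonical_motif(motif: str) -> str:
    """Canonical class: lexicographic minimum over rotations of the motif
    and rotations of its reverse complement."""
    motif = motif.upper()
    if not 2 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 2-6, got {motif!r}")
    if any(c not in "ACGT" for c in motif):
        raise ValueError(f"motif must be over ACGT, got {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} reduces to a shorter repeat unit")
    rc = motif.translate(_COMPLEMENT)[::-1]
    candidates = [m[i:] + m[:i] for m in (motif, rc) for i in range(len(m))]
    return min(candidates)


@dataclass
class SSRLocus:
    seq_id: str
    start: int   # 0-based half-open span
    end: int
    motif: str
    canonical_class: str
    n_repeats: float
    total_len: int

    def as_dict(self) -> dict:
        return {"seq_id": self.seq_id, "start": self.start, "end": self.end,
                "motif": self.motif, "canonical_class": self.canonical_class,
                "n_repeats": self.n_repeats, "total_len": self.total_len}


def find_ssrs(sequence: str, seq_id: str = "seq", min_total_len: int = 15,
              min_repeats: float = 3, motif_lens=range(2, 7),
              count_partial: bool = True) -> list[SSRLocus]:
    """Scan one sequence for qualifying perfect repeat tracts.

    Maximal runs are found for each motif length; runs whose motif is a
    repetition of a shorter unit are skipped (shortest-period rule), and any
    remaining overlaps are resolved left-to-right, longest tract first.
    Ambiguity characters break tracts. Coordinates are 0-based half-open.
    """
    seq = sequence.upper()
    L = len(seq)
    valid = [c in "ACGT" for c in seq]
    candidates: list[SSRLocus] = []
    for m in motif_lens:
        j = m
        while j < L:
            if valid[j] and valid[j - m] and seq[j] == seq[j - m]:
                run_start = j
                while j < L and valid[j] and seq[j] == seq[j - m]:
                    j += 1
                start = run_start - m
                total = m + (j - run_start)
                motif = seq[start:start + m]
                if not count_partial:
                    total = m * (total // m)
                n_rep = total / m
                if (total >= min_total_len and n_rep >= min_repeats
                        and is_primitive(motif)):
                    candidates.append(SSRLocus(
                        seq_id, start, start + total, motif,
                        canonical_motif(motif), n_rep, total))
            else:
                j += 1
    chosen: list[SSRLocus] = []
    occupied: list[tuple[int, int]] = []
    for loc in sorted(candidates, key=lambda l: (l.start, -l.total_len, len(l.motif))):
        if all(loc.end <= a or loc.start >= b for a, b in occupied):
            chosen.append(loc)
            occupied.append((loc.start, loc.end))
    return sorted(chosen, key=lambda l: (l.seq_id, l.start))


def scan_fasta(seqs: dict[str, str], **kwargs) -> list[SSRLocus]:
    loci = []
    for sid, seq in seqs.items():
        loci.extend(find_ssrs(seq, seq_id=sid, **kwargs))
    return loci


def loci_table(loci: list[SSRLocus]) -> pd.DataFrame:
    cols = ["seq_id", "start", "end", "motif", "canonical_class",
            "n_repeats", "total_len"]
    return pd.DataFrame([l.as_dict() for l in loci], columns=cols)


def ssr_summary(loci: list[SSRLocus]) -> pd.DataFrame:
    """Per motif-length class: number of distinct canonical motifs, total
    count, and the most frequent motif (ties broken lexicographically and
    flagged)."""
    rows = []
    by_len: dict[int, list[SSRLocus]] = {}
    for loc in loci:
        by_len.setdefault(len(loc.motif), []).append(loc)
    for m in sorted(by_len):
        classes = pd.Series([l.canonical_class for l in by_len[m]]).value_counts()
        top = classes.max()
        tied = sorted(classes[classes == top].index)
        rows.append({
            "ssr_type": MOTIF_CLASS_NAMES.get(m, f"{m}-mer"),
            "motif_len": m,
            "n_motifs": int(classes.size),
            "count": int(classes.sum()),
            "major_motif": tied[0],
            "major_tied": len(tied) > 1,
        })
    return pd.DataFrame(rows, columns=["ssr_type", "motif_len", "n_motifs",
                                       "count", "major_motif", "major_tied"])
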