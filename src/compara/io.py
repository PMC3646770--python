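"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA is wrapped at 80 columns; hit tables use the standard 12-column
similarity-search tabular layout without a header; annotation, pileup and
truth tables are headered TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .simulate import ANNOT_COLUMNS, HIT_COLUMNS, PILEUP_COLUMNS, SimTruth

_HIT_DTYPES = {"pident": float, "length": int, "mismatch": int, "gapopen": int,
               "qstart": int, "qend": int, "sstart": int, "send": int,
               "evalue": float, "bitscore": float}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_hits(hits: pd.DataFrame, path) -> None:
    hits[HIT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_hit_table(path) -> pd.DataFrame:
    """Parse a 12-column tabular hit file; malformed rows raise with the line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated fields, "
                    f"got {len(fields)}")
            row = dict(zip(HIT_COLUMNS, fields))
            try:
                for col, typ in _HIT_DTYPES.items():
                    row[col] = typ(row[col])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            rows.append(row)
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_annotations(annot: pd.DataFrame, path) -> None:
    annot[ANNOT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation table missing columns {missing}")
    return df[ANNOT_COLUMNS]


def go_annotation_sets(annot: pd.DataFrame, gene_col: str = "transcript_id",
                       terms_col: str = "go_terms") -> dict[str, set]:
    """gene -> set of GO ids from a semicolon-joined annotation column."""
    out: dict[str, set] = {}
    for row in annot.itertuples(index=False):
        terms = getattr(row, terms_col)
        out[getattr(row, gene_col)] = {t for t in str(terms).split(";") if t}
    return out


def write_pileup(pileup: pd.DataFrame, path) -> None:
    pileup[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pileup(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: pileup table missing columns {missing}")
    return df[PILEUP_COLUMNS]


def write_truth(truth: SimTruth, directory) -> None:
    """Materialise every ground-truth table as TSV under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(truth.ortholog_map,
                 columns=["idA", "idB", "omega", "kappa", "t"]).to_csv(
        directory / "truth_orthologs.tsv", sep="\t", index=False)
    pd.DataFrame({"paralog_id": truth.paralog_ids}).to_csv(
        directory / "truth_paralogs.tsv", sep="\t", index=False)
    pd.DataFrame(truth.snp_truth,
                 columns=["contig", "pos", "ref", "alt", "alt_fraction"]).to_csv(
        directory / "truth_snps.tsv", sep="\t", index=False)
    pd.DataFrame(truth.ssr_truth,
                 columns=["seq_id", "start", "end", "motif", "n_repeats"]).to_csv(
        directory / "truth_ssrs.tsv", sep="\t", index=False)
    pd.DataFrame(truth.decoys, columns=["idA", "idB", "filter_violated"]).to_csv(
        directory / "truth_decoys.tsv", sep="\t", index=False)
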