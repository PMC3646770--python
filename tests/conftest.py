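import pytest

from compara import codons as cd
from compara import kaks, simulate


@pytest.fixture(scope="session")
def small_pair_set():
    """60 simulated ortholog pairs at omega=0.5, kappa=2, t=0.4, 500 codons."""
    seqs_a, seqs_b, truth = simulate.simulate_ortholog_pairs(
        60, 0.5, 2.0, 0.4, 500, seed=101)
    return seqs_a, seqs_b, truth


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """Full synthetic dataset on disk: 60 pairs (6 fast), 5 decoys per filter."""
    from compara import pipeline
    outdir = tmp_path_factory.mktemp("simdata")
    cfg_path = pipeline.simulate_dataset(
        outdir, seed=17, n_pairs=60, n_fast=6, n_codons=400,
        n_nonreciprocal=4, n_diff_protein=5, n_dup_name=3)
    return pipeline.PipelineConfig.from_yaml(cfg_path)


def alignment_from_pair(seq_a: str, seq_b: str) -> kaks.CodonAlignment:
    """Direct column pairing for simulated (indel-free) CDS pairs."""
    return kaks.CodonAlignment(cd.encode_codons(seq_a), cd.encode_codons(seq_b))


def yn00_estimates(seqs_a, seqs_b, truth):
    out = []
    for ida, idb, *_ in truth.ortholog_map:
        res = kaks.yn00(alignment_from_pair(seqs_a[ida], seqs_b[idb]))
        out.append(res)
    return out
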