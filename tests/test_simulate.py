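"""Generator-level checks: the codon process, pileups, SSR planting, GO sets."""

import itertools

import numpy as np
import pytest
from scipy import stats

from compara import codons as cd
from compara import kaks, simulate, ssr

from conftest import alignment_from_pair


def _neutral_nonsyn_fraction():
    """Independent enumeration of single-nucleotide sense->sense changes."""
    n_syn = n_tot = 0
    for codon in cd.SENSE_CODONS:
        for p, n in itertools.product(range(3), "ACGT"):
            if n == codon[p]:
                continue
            mut = codon[:p] + n + codon[p + 1:]
            if mut in cd.STOP_CODONS:
                continue
            n_tot += 1
            n_syn += cd.AA[mut] == cd.AA[codon]
    return 1 - n_syn / n_tot


class TestOrthologPairSimulation:
    def test_zero_time_yields_identical_sequences(self):
        seqs_a, seqs_b, truth = simulate.simulate_ortholog_pairs(
            5, 0.5, 2.0, 0.0, 50, seed=3)
        for ida, idb, *_ in truth.ortholog_map:
            assert seqs_a[ida] == seqs_b[idb]
            res = kaks.yn00(alignment_from_pair(seqs_a[ida], seqs_b[idb]))
            assert res.Ka == 0.0 and res.Ks == 0.0

    def test_fixed_seed_reproduces_byte_identical_output(self, tmp_path):
        from compara import io
        paths = []
        for run in range(2):
            seqs_a, _, _ = simulate.simulate_ortholog_pairs(
                10, 1.0, 2.0, 0.3, 100, seed=42)
            p = tmp_path / f"run{run}.fasta"
            io.write_fasta(seqs_a, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_neutral_substitution_spectrum_matches_enumeration(self):
        """At omega=kappa=1 with uniform frequencies, the fraction of
        nonsynonymous changes among observed single-step differences equals
        the code's neutral nonsynonymous fraction."""
        seqs_a, seqs_b, truth = simulate.simulate_ortholog_pairs(
            1, 1.0, 1.0, 0.05, 10_000, seed=7)
        ida, idb, *_ = truth.ortholog_map[0]
        ia = cd.encode_codons(seqs_a[ida])
        ib = cd.encode_codons(seqs_b[idb])
        n_syn = n_nonsyn = 0
        for a, b in zip(ia, ib):
            ca, cb = cd.SENSE_CODONS[a], cd.SENSE_CODONS[b]
            ndiff = sum(x != y for x, y in zip(ca, cb))
            if ndiff != 1:
                continue  # identical or (rare) multi-hit columns
            if cd.AA[ca] == cd.AA[cb]:
                n_syn += 1
            else:
                n_nonsyn += 1
        observed = n_nonsyn / (n_syn + n_nonsyn)
        expected = _neutral_nonsyn_fraction()
        assert observed == pytest.approx(expected, abs=0.05)

    def test_substitutions_scale_linearly_in_t(self):
        def diff_fraction(t, seed):
            sa, sb, tr = simulate.simulate_ortholog_pairs(
                1, 1.0, 2.0, t, 10_000, seed=seed)
            ida, idb, *_ = tr.ortholog_map[0]
            a = cd.encode_codons(sa[ida])
            b = cd.encode_codons(sb[idb])
            return (a != b).mean()

        d1 = diff_fraction(0.02, seed=11)
        d2 = diff_fraction(0.05, seed=12)
        assert d2 / d1 == pytest.approx(2.5, rel=0.10)

    def test_no_inframe_stop_codons(self):
        seqs_a, seqs_b, _ = simulate.simulate_ortholog_pairs(
            5, 2.0, 2.0, 0.8, 200, seed=9)
        for seq in list(seqs_a.values()) + list(seqs_b.values()):
            codons = {seq[i:i + 3] for i in range(0, len(seq), 3)}
            assert not codons & cd.STOP_CODONS

    @pytest.mark.parametrize("kwargs", [
        dict(omega=0.0), dict(omega=-1.0), dict(kappa=0.0), dict(t=-0.1),
        dict(n_codons=5),
    ])
    def test_rejects_degenerate_parameters(self, kwargs):
        params = dict(n_pairs=2, omega=1.0, kappa=2.0, t=0.1, n_codons=50, seed=0)
        params.update(kwargs)
        with pytest.raises(ValueError):
            simulate.simulate_ortholog_pairs(**params)


class TestPileupSimulation:
    def test_error_free_no_snps_is_monoallelic(self):
        pileup, _ = simulate.simulate_pileup(200, [], depth=30, error_rate=0.0,
                                             seed=1)
        counts = pileup[["count_A", "count_C", "count_G", "count_T",
                         "count_del", "count_ins"]].to_numpy()
        assert ((counts > 0).sum(axis=1) == 1).all()
        assert (counts.sum(axis=1) == 30).all()

    def test_planted_snp_allele_counts_behave_binomially(self):
        """Depth 40 at fraction 0.5: mean alt count 20, and both alleles
        >= 8 at the rate the binomial tail predicts."""
        n_rep = 300
        both_ge8 = 0
        alt_counts = []
        for seed in range(n_rep):
            pileup, _ = simulate.simulate_pileup(
                1, [(0, "A", "G", 0.5)], depth=40, error_rate=0.0, seed=seed)
            a, g = int(pileup.loc[0, "count_A"]), int(pileup.loc[0, "count_G"])
            alt_counts.append(g)
            both_ge8 += (a >= 8) and (g >= 8)
        assert np.mean(alt_counts) == pytest.approx(20, abs=1.0)
        expected = stats.binom(40, 0.5).cdf(32) - stats.binom(40, 0.5).cdf(7)
        assert both_ge8 / n_rep == pytest.approx(expected, abs=0.03)

    def test_determinism(self):
        a, _ = simulate.simulate_pileup(50, [(3, "C", "T", 0.4)], 25, 0.01, seed=5)
        b, _ = simulate.simulate_pileup(50, [(3, "C", "T", 0.4)], 25, 0.01, seed=5)
        assert a.equals(b)

    @pytest.mark.parametrize("snps,err", [
        ([(1, "A", "G", 0.5), (1, "A", "C", 0.5)], "collision"),
        ([(1, "A", "G", 1.5)], "alt_fraction"),
        ([(99, "A", "G", 0.5)], "outside"),
    ])
    def test_rejects_bad_snp_specs(self, snps, err):
        with pytest.raises(ValueError, match=err):
            simulate.simulate_pileup(10, snps, depth=10, error_rate=0.0, seed=0)


class TestSSRPlanting:
    def test_planted_qualifying_tract_has_expected_span(self):
        seqs, truth = simulate.plant_ssrs(1, 300, [("ATC", 5)], seed=2)
        (sid, start, end, motif, n_rep), = truth
        assert end - start == 15 and motif == "ATC" and n_rep == 5
        loci = ssr.find_ssrs(seqs[sid], seq_id=sid)
        assert [(l.start, l.end) for l in loci] == [(start, end)]

    def test_subthreshold_tract_recorded_but_not_detected(self):
        seqs, truth = simulate.plant_ssrs(1, 300, [("AT", 7)], seed=3)
        (sid, start, end, motif, n_rep), = truth
        assert end - start == 14
        assert ssr.find_ssrs(seqs[sid], seq_id=sid) == []

    def test_clean_background_without_tracts(self):
        seqs, truth = simulate.plant_ssrs(3, 400, [], seed=4)
        assert truth == []
        for sid, seq in seqs.items():
            assert ssr.find_ssrs(seq, seq_id=sid) == []

    def test_rejects_overlong_tract(self):
        with pytest.raises(ValueError):
            simulate.plant_ssrs(1, 20, [("ATC", 10)], seed=0)


class TestGOAnnotationSimulation:
    def test_null_false_positive_rate_is_calibrated(self):
        """study fraction == background fraction: the planted term's
        enrichment p-value rejects at <= alpha (discrete test, conservative)."""
        from compara import go_tools, io as cio
        rejections = 0
        n_rep = 400
        for seed in range(n_rep):
            annot, obo, truth = simulate.simulate_go_annotations(
                50, 3, study_fraction_with_term=0.3, background_fraction=0.3,
                seed=seed, n_study=15)
            go = go_tools.load_obo(obo)
            sets = cio.go_annotation_sets(annot, gene_col="gene")
            res = go_tools.hypergeometric_enrichment(
                set(truth["study_genes"]), set(annot["gene"]), sets, go)
            row = res[res["term_id"] == truth["enriched_term"]]
            if not row.empty and float(row["p_value"].iloc[0]) < 0.05:
                rejections += 1
        assert 0.0 <= rejections / n_rep <= 0.08

    def test_strong_enrichment_reaches_small_p(self):
        from compara import go_tools, io as cio
        annot, obo, truth = simulate.simulate_go_annotations(
            100, 5, study_fraction_with_term=1.0, background_fraction=0.05,
            seed=8, n_study=20)
        go = go_tools.load_obo(obo)
        sets = cio.go_annotation_sets(annot, gene_col="gene")
        res = go_tools.hypergeometric_enrichment(
            set(truth["study_genes"]), set(annot["gene"]), sets, go)
        p = float(res.loc[res["term_id"] == truth["enriched_term"], "p_value"].iloc[0])
        assert p < 1e-3

    def test_empty_study_set_yields_no_results(self):
        from compara import go_tools, io as cio
        annot, obo, _ = simulate.simulate_go_annotations(20, 3, seed=1)
        go = go_tools.load_obo(obo)
        sets = cio.go_annotation_sets(annot, gene_col="gene")
        res = go_tools.hypergeometric_enrichment(set(), set(annot["gene"]), sets, go)
        assert res.empty
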