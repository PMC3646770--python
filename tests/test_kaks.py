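"""Ka/Ks estimation: CDS handling, NG86 vs an independent oracle, YN00
behaviour, Fisher significance and selection classification."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats
from Bio.Data import CodonTable

from compara import codons as cd
from compara import kaks, simulate

from conftest import alignment_from_pair, yn00_estimates

# ---------------------------------------------------------------------------
# Independent NG86 oracle, written against the textbook definition only
# ---------------------------------------------------------------------------

_FWD = CodonTable.unambiguous_dna_by_id[1].forward_table
_STOPS = set(CodonTable.unambiguous_dna_by_id[1].stop_codons)


def oracle_syn_sites(codon: str) -> float:
    total = 0.0
    for pos in range(3):
        syn = considered = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1:]
            if mut in _STOPS:
                continue
            considered += 1
            syn += _FWD[mut] == _FWD[codon]
        if considered:
            total += syn / considered
    return total


def oracle_differences(c1: str, c2: str):
    if c1 == c2:
        return 0.0, 0.0
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    stop_free = []
    for order in itertools.permutations(diff_pos):
        cur, sd, nd, hit_stop = c1, 0, 0, False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in _STOPS:
                hit_stop = True
                break
            if _FWD[nxt] == _FWD[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not hit_stop:
            stop_free.append((sd, nd))
    # under the standard code every sense-sense pair has a stop-free path
    assert stop_free
    return (sum(s for s, _ in stop_free) / len(stop_free),
            sum(n for _, n in stop_free) / len(stop_free))


class TestCDSHandling:
    def test_forward_slice_identity(self):
        assert kaks.extract_cds("ATGAAATGACCC", 1, 9) == "ATGAAATGA"

    def test_reverse_coordinates_take_reverse_complement(self):
        # transcript 3' -> 5' hit: qstart > qend
        tx = "CCCTTTCATGGG"
        # reverse complement of positions 4..9 (TTTCAT) is ATGAAA
        assert kaks.extract_cds(tx, 9, 4) == "ATGAAA"

    def test_trims_to_codon_multiple(self):
        assert len(kaks.extract_cds("A" * 20, 1, 10)) == 9

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            kaks.extract_cds("ATG", 1, 10)

    def test_internal_stop_fails_terminal_stop_stripped(self):
        ok, _ = kaks.screen_stops("ATGTAAAAA")
        assert not ok
        ok, out = kaks.screen_stops("ATGAAATAA")
        assert ok and out == "ATGAAA"
        ok, out = kaks.screen_stops("ATGAAAGGG")
        assert ok and out == "ATGAAAGGG"


class TestCodonAlignment:
    def test_identical_cds_aligns_without_gaps(self):
        cds = "ATGAAACCCGGGTTT"
        aln = kaks.align_codons(cds, cds)
        assert aln.n_codons == 5 and aln.dropped_gap_columns == 0
        assert (aln.codonsA == aln.codonsB).all()

    def test_single_codon_deletion_drops_one_column(self):
        cds_a = "ATGAAATTCCTGGGGCCTTACAAG"
        cds_b = cds_a[:9] + cds_a[12:]  # delete 4th codon
        aln = kaks.align_codons(cds_a, cds_b)
        assert aln.n_codons == 7
        assert (aln.codonsA == aln.codonsB).all()

    def test_simulated_pairs_match_naive_column_pairing(self):
        seqs_a, seqs_b, truth = simulate.simulate_ortholog_pairs(
            5, 0.5, 2.0, 0.4, 80, seed=51)
        for ida, idb, *_ in truth.ortholog_map:
            aln = kaks.align_codons(seqs_a[ida], seqs_b[idb])
            naive = alignment_from_pair(seqs_a[ida], seqs_b[idb])
            assert (aln.codonsA == naive.codonsA).all()
            assert (aln.codonsB == naive.codonsB).all()


class TestNG86:
    def test_identical_sequences_zero_distances(self):
        aln = alignment_from_pair("ATGAAA", "ATGAAA")
        r = kaks.ng86(aln)
        assert r.Sd == r.Nd == 0 and r.Ka == 0.0 and r.Ks == 0.0

    def test_three_codon_worked_example(self):
        aln = alignment_from_pair("TTTGGGAAA", "TTCGGGAAA")
        r = kaks.ng86(aln)
        assert r.S == pytest.approx(5 / 3)
        assert r.N == pytest.approx(22 / 3)
        assert r.Sd == pytest.approx(1.0) and r.Nd == pytest.approx(0.0)
        assert r.Ka == 0.0

    def test_site_counts_match_oracle_for_every_codon(self):
        for i, codon in enumerate(cd.SENSE_CODONS):
            assert cd.NG86_SYN_SITES[i] == pytest.approx(oracle_syn_sites(codon))

    def test_differences_match_oracle_on_all_codon_pairs(self):
        for ia in range(cd.N_SENSE):
            for ib in range(cd.N_SENSE):
                got = kaks._ng86_differences(ia, ib)
                want = oracle_differences(cd.SENSE_CODONS[ia], cd.SENSE_CODONS[ib])
                assert got == pytest.approx(want), (ia, ib)

    def test_site_conservation_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            a = rng.integers(0, cd.N_SENSE, size=n)
            b = rng.integers(0, cd.N_SENSE, size=n)
            aln = kaks.CodonAlignment(a, b)
            for r in (kaks.ng86(aln), kaks.yn00(aln, min_codons_warn=0)):
                assert r.S + r.N == pytest.approx(3 * n, abs=1e-6)


class TestYN00:
    def test_identical_sequences_zero(self):
        aln = alignment_from_pair("ATGAAACCC" * 12, "ATGAAACCC" * 12)
        r = kaks.yn00(aln)
        assert r.Ka == 0.0 and r.Ks == 0.0

    def test_swap_symmetry(self, small_pair_set):
        seqs_a, seqs_b, truth = small_pair_set
        for ida, idb, *_ in truth.ortholog_map[:5]:
            fwd = kaks.yn00(alignment_from_pair(seqs_a[ida], seqs_b[idb]))
            rev = kaks.yn00(alignment_from_pair(seqs_b[idb], seqs_a[ida]))
            assert fwd.Ka == pytest.approx(rev.Ka, abs=1e-9)
            assert fwd.Ks == pytest.approx(rev.Ks, abs=1e-9)
            assert fwd.omega == pytest.approx(rev.omega, abs=1e-9)

    def test_omega_estimates_rank_with_truth(self):
        means = []
        for i, w in enumerate((0.1, 0.5, 1.0, 2.0)):
            sa, sb, tr = simulate.simulate_ortholog_pairs(
                25, w, 2.0, 0.4, 1000, seed=60 + i)
            ests = [r.omega for r in yn00_estimates(sa, sb, tr)]
            means.append(np.mean(ests))
        assert means == sorted(means)

    def test_agrees_with_ng86_in_reduction_limit(self):
        """kappa=1 and uniform codon frequencies: the weighted counting
        collapses towards NG86."""
        sa, sb, tr = simulate.simulate_ortholog_pairs(
            10, 0.5, 1.0, 0.3, 2000, seed=71)
        for ida, idb, *_ in tr.ortholog_map:
            aln = alignment_from_pair(sa[ida], sb[idb])
            w_yn = kaks.yn00(aln).omega
            w_ng = kaks.ng86(aln).omega
            assert w_yn == pytest.approx(w_ng, rel=0.05)

    def test_kappa_recovery(self, small_pair_set):
        seqs_a, seqs_b, truth = small_pair_set
        kappas = [r.kappa for r in yn00_estimates(seqs_a, seqs_b, truth)]
        assert np.mean(kappas) == pytest.approx(2.0, rel=0.15)


class TestSignificance:
    def test_homogeneous_table_p_one(self):
        r = kaks.KaKsResult(S=100, N=200, Sd=10, Nd=20, kappa=2, Ka=0.1,
                            Ks=0.1, omega=1.0, method="YN00")
        assert kaks.kaks_significance(r) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        """[[10, 0], [90, 100]] against an explicit tail sum over all tables
        with the same margins."""
        r = kaks.KaKsResult(S=100, N=100, Sd=10, Nd=0, kappa=2, Ka=0.0,
                            Ks=0.2, omega=0.0, method="YN00")
        p = kaks.kaks_significance(r)
        # margins: row sums 10/190, col sums 100/100
        rv = stats.hypergeom(200, 10, 100)
        p0 = rv.pmf(10)
        expected = sum(rv.pmf(k) for k in range(0, 11) if rv.pmf(k) <= p0 + 1e-12)
        assert p == pytest.approx(expected, rel=1e-6)

    def test_negative_cells_clamped_and_flagged(self):
        r = kaks.KaKsResult(S=5, N=100, Sd=7, Nd=1, kappa=2, Ka=0.01,
                            Ks=1.5, omega=0.007, method="YN00")
        p = kaks.kaks_significance(r)
        assert 0 <= p <= 1 and "clamped_table" in r.flags


class TestClassification:
    @pytest.mark.parametrize("omega,p,label", [
        (2.5, 0.01, "fast_evolving"),
        (0.9, 0.3, "neutral"),
        (0.2, 0.001, "constrained"),
        (1.0, 0.001, "neutral"),
    ])
    def test_labels(self, omega, p, label):
        r = kaks.KaKsResult(S=100, N=200, Sd=10, Nd=20, kappa=2, Ka=0.1,
                            Ks=0.1 / omega if omega else 0.1, omega=omega,
                            method="YN00", p_value=p)
        labels, _ = kaks.classify_selection([r])
        assert labels == [label]

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            kaks.classify_selection([], alpha=1.5)
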