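# Methods

This note records the models, conventions and design choices behind each
stage, in enough detail to reimplement them.

## Codon-pair simulator

Ortholog CDS pairs are generated under a GY94-style codon substitution
model. The instantaneous rate from sense codon *i* to *j* is

    q_ij = π_j · κ^[transition] · ω^[nonsynonymous]

for single-nucleotide changes, and 0 for multi-nucleotide changes; π is the
F3×4 stationary distribution built from position-specific nucleotide
frequencies (uniform by default, which makes π uniform over the 61 sense
codons). The generator matrix is scaled so that one time unit equals one
expected substitution per codon at stationarity, the ancestor is drawn from
π (stop codons can never appear in frame), and **each lineage evolves
t/2**, so the pairwise divergence between the two descendants is *t*
expected substitutions per codon. Transition probabilities come from the
matrix exponential, so simulation is exact (no time discretisation).
Indels are not simulated: aligned simulated pairs are column-paired.

Determinism: every generator operation takes one integer seed feeding a
single `numpy` Generator; draws occur in documented order (per pair:
ancestor, lineage A, lineage B), making all outputs byte-identical across
runs. Fabricated hit-table bitscores are an arbitrary monotone function of
simulated sequence identity (2 × identity × length) with E-values derived
from them; only their ordering matters.

Matched generative and inferential models are deliberate: the simulator
implements exactly the mutation structure the YN00-style estimator assumes,
so parameter recovery is a fair test of the estimator implementation,
not of model robustness. Defaults used throughout the study (κ = 2,
t = 0.4, ω ∈ {0.1, 0.5, 1, 2, 3}) are estimator-testing choices, not
claims about any real species pair.

What the generator does *not* emulate: platform-specific sequencing error
profiles (e.g. 454 homopolymer errors), assembly artefacts and isoform
structure, codon-usage bias beyond F3×4, indels within orthologous CDSs,
and linkage between sites. Passing tests therefore demonstrate correctness
of the implementations under the stated model, not performance on raw
reads.

## Ortholog identification

"Best hit" maximises bitscore; ties break on lower E-value, then
lexicographic subject id — the paperless parts of BBH are fixed this way
purely for determinism. The same-protein filter takes each member's best
protein accession from the transcript-vs-protein table at E ≤ 1e-6;
pairs with an unannotated member are dropped and tallied rather than
raising. Gene-name uniqueness is evaluated on the *full* annotation table
of each transcriptome (not only paired genes), case-insensitively after
whitespace normalisation, since annotation-derived names vary in case. The
funnel counts are checked to be non-increasing by construction.

## NG86

Synonymous sites per codon are counted per position as the fraction of
synonymous changes among the *non-stop* single-nucleotide changes at that
position (mutations to stop codons are excluded from numerator and
denominator — the MEGA/PAML convention). Differences between codon pairs
are averaged over all orderings of the changed positions, discarding
orderings that pass through a stop codon (under the standard code every
sense–sense pair retains at least one stop-free ordering). pS = Sd/S and
pN = Nd/N receive the Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3);
p ≥ 3/4 is reported as a saturation flag, not an exception.

NG86 ignores transition/transversion bias when counting sites; with κ > 1
it systematically undercounts synonymous sites, which biases ω and (at
scale) miscalibrates any test built on its counts. It is retained as a
transparent cross-check and reduction-limit oracle (κ = 1, uniform codon
frequencies), not as the production estimator.

## YN00-style estimator

1. **Codon frequencies**: F3×4 from the two sequences pooled, with a 0.5
   pseudo-count only if a nucleotide is entirely absent at a position.
2. **κ**: K80 applied separately to positions that are fourfold-degenerate
   in both codons and to positions nondegenerate in both; the two estimates
   (κ = 2·d_ts/d_tv) are combined weighted by site counts. If neither
   class yields a usable estimate (no transversions, or saturated), κ
   falls back to 2 with a `kappa_default` flag.
3. **Sites**: per codon, S_i = 3 · Σ_syn μ_ij / Σ_all μ_ij with mutation
   weights μ_ij = π_j · κ^[ts]; S is averaged over the two sequences and
   N = 3L − S.
4. **Differences**: for each differing codon pair, every stop-free ordering
   of the changed positions is weighted by the product of its step rates
   π_target · κ^[ts] · ω^[nonsyn]; expected synonymous/nonsynonymous and
   transitional/transversional step counts are accumulated under the
   normalised path weights.
5. **Distances**: K80 corrections applied separately within the synonymous
   class (P = Sd_ts/S, Q = Sd_tv/S → Ks) and the nonsynonymous class
   (→ Ka).
6. **Iteration**: the ω used in step 4 starts at 1 and is replaced by
   Ka/Ks until the change is below 1e-6 or 100 iterations (flagged
   `not_converged`). Identical sequences short-circuit to Ka = Ks = 0 with
   ω undefined; Ks = 0 or saturation is flagged rather than raised.

Because the model is reversible (π_i q_ij = π_j q_ji) and path-step
classification is symmetric, swapping the two sequences leaves S, N, Sd,
Nd and hence Ka, Ks, ω unchanged to machine precision; the tests assert
this. Alignments under 30 codons trigger a warning (estimates are noisy,
and κ estimation often falls back).

## Significance and classification

The test behind "ω significantly different from 1" is a two-sided Fisher
exact test on [[round(Sd), round(Nd)], [round(S−Sd), round(N−Nd)]] — the
convention of pairwise Ka/Ks toolkits. Corrected counts can exceed sites;
negative cells are clamped to 0 and flagged. No multiple-testing correction
is applied by default (per-pair p < α is the reported quantity);
Benjamini–Hochberg is available behind a flag in the enrichment code and
trivially applicable to the Ka/Ks table.

Calibration: the null-calibration test (1,000 neutral replicates of 500
codons at κ = 2, t = 0.4 — sizes chosen once as the study condition)
measures the empirical rejection rate at α = 0.05; it comes out near 0.06,
i.e. the test is approximately calibrated but slightly anti-conservative at
this divergence. The residual inflation comes from multiple substitutions
per site and from sampling noise in the estimated site totals, both outside
the Fisher model; it grows with *t* (and is far larger if NG86 counts are
used, see above).

Labels: *fast_evolving* iff ω > 1 and p < α; *constrained* iff ω < 1 and
p < α; everything else *neutral*; pairs with undefined ω are tallied
separately. The report also carries the ratio-only counts (ω < 1, ω > 1)
mirroring the usual funnel presentation.

## GO tools

Only `is_a` edges are traversed; `part_of` is ignored (the conservative
reading when provenance of annotations is mixed). A term's level is 1 +
the *shortest* is_a path to its namespace root — shortest-path depth is
stable under DAG edits, unlike longest-path. Rollup propagates each
annotation to all level-k ancestors; with multiple parents a gene counts
toward several level-k terms, so per-namespace fractions can sum above 1
(documented behaviour, not a bug). Enrichment propagates annotations to
all ancestors first, then computes the upper-tail hypergeometric
probability via `scipy.stats.hypergeom.sf`; a study set not contained in
the population is a hard error.

## SNP calling

The caller starts from per-position allele counts (A/C/G/T/del/ins); read
mapping is deliberately out of scope, counts being the minimal sufficient
input for the thresholds. A site is called iff the two most frequent
alleles each have ≥ `min_reads_per_allele` (8) reads and
minor/(major+minor) ≥ `min_maf` (0.25); both bounds inclusive, verified at
the exact boundary in tests. The MAF denominator is the top-two-allele
depth (the caller emits bi-allelic variants); a `total`-depth denominator
is available behind a flag. Third and lower alleles are ignored for the
call but reported per site. Ties between equally frequent alleles break in
fixed allele order (A, C, G, T, del, ins) for determinism.

## SSR detection

Perfect repeats only: the mismatch model of commonly used SSR scanners is
under-specified, so the reproducible perfect-repeat mode is implemented and
stated prominently. Mononucleotide runs are excluded (motif lengths 2–6).
Maximal runs are found per motif length; a trailing partial repeat extends
the tract (so (AT)×7+A = 15 bp qualifies at 7.5 repeats) unless
`count_partial=False`. Both thresholds apply jointly (≥ 15 bp AND ≥ 3
repeats): length binds for 2–4-mers, repeat count for 5–6-mers. A run
whose motif is itself periodic (e.g. ATAT) is never reported — the shortest
period wins — and residual overlaps are resolved left-to-right, longest
tract first. Adjacent tracts of different motifs are reported separately.
Ambiguity codes break tracts. Every reported locus re-verifies as a
perfect (possibly partial-final) repeat of its motif by direct string
comparison, and canonical classes are invariant to reverse complementing
the input.

The SSR-planting generator rejects and regenerates backgrounds that either
contain spontaneous qualifying tracts or extend a planted tract beyond its
recorded span, so planted truth and detector output are comparable exactly
(precision = recall = 1 is the expected outcome, and a deviation means a
detector bug, not generator noise).

## Pipeline

Stage outputs are always materialised as TSV between stages so any stage
can be re-run and audited in isolation. Reports are JSON with sorted keys
and no timestamps; logging (timestamped, leveled) goes to stderr only.
Two runs with the same config and seed are byte-identical end to end — an
asserted property, not an aspiration. The synthetic end-to-end dataset
mirrors the study design: 100 ortholog pairs (10 at ω = 3, the rest
cycling through 0.1/0.5/1), five confounders per paralog filter, GO
annotations with the enriched term planted on the fast set (mirrored onto
the B-side partners, since orthologs share function), transition-rich
planted SNPs at 50% allele fraction and depth 60, and SSR tracts covering
every motif length plus a sub-threshold negative control.

## Problem sizes used by the validation suite

Chosen once as study conditions: ω-recovery uses 200 pairs × 2,000 codons
per ω value; null calibration 1,000 replicates × 500 codons; selection
power 50 pairs × 2,000 codons; funnel exactness 50 pairs with 7 + 4
planted violations; brute-force best-hit comparison 10,000 rows. All other
fixtures are small enough to verify by hand or exhaustive enumeration.

## Known limitations

* Approximate counting methods only; no ML codon models (branch/site
  models, gamma rates) and no >2-sequence analyses.
* The Fisher significance test is slightly anti-conservative at higher
  divergence (see calibration above).
* κ falls back to a constant on very short or extreme alignments rather
  than failing.
* The GO toy ontology generated for enrichment fixtures has a single
  namespace; three-namespace behaviour is exercised by hand-written
  fixtures only.
* SSR detection does not model imperfect or compound repeats; real
  catalogues built with mismatch-tolerant scanners will differ.
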