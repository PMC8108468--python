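# Methods

## Residue numbering and the Schiff-base check

All opsin positions are reported in bovine rhodopsin numbering: the
query is globally aligned to the packaged bovine rhodopsin sequence
(UniProt P02699, 348 aa) and each bovine position is mapped to the
aligned query residue, or to `UNALIGNED` if it falls in a gap. The
K296 check passes only when the mapped residue is exactly `K`; an
unaligned site or the ambiguity code `X` fails. This is deliberately
conservative — a fragment that does not cover the retinal-binding site
cannot be certified as an opsin.

Pairwise alignments use BLOSUM62 with affine gap costs of 11 to open
(charged on the first gap residue) and 1 to extend, the long-standing
default of protein search tools; nothing in the analyses suggested the
site mapping is sensitive to reasonable variations of these values, and
the parameters are exposed (`AlignmentParams`) rather than hard-coded.
Among co-optimal alignments the aligner's deterministic first traceback
is used, so every result is reproducible bit for bit. Global scores
are cross-checked in the tests against an independent three-matrix
(Gotoh) dynamic program on randomly sampled short sequence pairs.

## The mining pipeline

Stages run in the order ORF extraction → prescreen → K296 check →
length filter → class assignment → clustering. Placing the K296 check
before classification keeps obvious non-opsins out of the placement
trees; clustering last keeps per-class counts well defined. Each
stage's survivor count is logged, and the counts are monotone
non-increasing by construction.

* **ORF extraction** reports maximal ATG-to-stop reading frames in all
  six frames (default minimum 100 aa), with coordinates always on the
  forward strand. Frames that run off the contig edge without a stop
  are kept but flagged truncated.
* **Prescreen** takes the best Smith–Waterman score against any
  database record and converts it to a Karlin–Altschul E-value with the
  standard gapped-BLOSUM62 constants (λ = 0.267, K = 0.041); the
  default cut-off is E ≤ 1e-5, with a raw-score mode available. The
  prescreen is intentionally permissive: specificity comes from the
  K296 check, and the tests verify that opsin-like GPCR decoys pass the
  prescreen yet are rejected downstream.
* **Length filter**: Met start and length ≥ the mean database record
  length. Short transcripts are prone to misclassification; the filter
  can be disabled, in which case the flag is still recorded.
* **Class assignment** aligns the candidate with all database records
  (MAFFT), computes p-distances with pairwise deletion (gaps and `X`
  excluded), builds a neighbour-joining tree and assigns the class of
  the reference leaf with minimum patristic distance. Ties (within
  1e-9) are broken by majority class among tied leaves, then
  lexicographically. NJ on p-distances was chosen over a full ML tree
  because it is fast, dependency-light and deterministic; the decision
  rule is isolated so an ML backend could be swapped in. Leave-it-in
  placement of every database record returns its own class in the
  tests.
* **Clustering** is greedy longest-first at identity > 0.95 over the
  shorter sequence (cd-hit semantics): sorted by length, each peptide
  joins the first cluster whose founding representative it matches,
  else founds its own. Applied within a species across assemblies, so
  repeated assemblies of one species do not inflate counts.
  Re-clustering representatives yields singletons (idempotence).

## MWS-like substitution profiling

All grouped sequences are aligned together with the bovine reference in
one MAFFT run; the bovine row defines the column ↔ bovine-position map,
and columns that do not map to a bovine position are skipped (they
could not be reported in bovine numbering). At each mapped column,
a residue is called MWS-like when it occurs in ≥ 1 Baikal LWS row,
≥ 1 European MWS row, and 0 European LWS rows. Both thresholds are
parameters (`min_mws_carriers`, `max_euro_lws_carriers`), because the
verbal definition admits stricter readings; the default is the
permissive/strict combination just stated. Gaps and `X` never count as
occurrences on either side of the definition. Events are keyed by
(position, residue) — one column can yield several events. Carriers
are counted per sequence (transcript), not per species.

Co-occurrence of k chosen events compares the size of the carrier-set
intersection with the independence expectation Π(countᵢ/total); both
fractions are reported to one decimal in percent. With marginal counts
48, 30 and 19 over 102 sequences the expectation is 2.6%.

The caller is cross-checked against a naive triple-loop implementation
on randomized toy alignments, and is invariant to row and column
permutation.

## Depth model

Ordinary least squares of transcript count on untransformed depth in
metres (no log transform; the simplest model consistent with a linear
relationship). Adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2); the slope
p-value is two-sided from the t distribution with n − 2 df. Species
with zero opsins are included when present in the table; an
`exclude_zero` flag reruns without them. Coefficients are verified
against the normal equations on random datasets.

## Synthetic data: what it emulates, and what it does not

All templates derive from bovine rhodopsin by seeded point substitution
(no indels), with the initiator Met and Lys296 masked from mutation.
Class ancestors diverge at 25% of sites, database members at 8% within
class, so within-class identity cleanly exceeds between-class identity.
Because no indels are introduced, bovine numbering coincides with
sequence position in every planted sequence — which is what makes exact
truth bookkeeping possible.

* **Assemblies**: each planted peptide is back-translated with uniform
  synonymous codon choice (ORF finding is codon-usage-agnostic), given
  a stop codon and random UTR flanks — the 5' UTR ends in an in-frame
  stop so the planted CDS is exactly one maximal ORF — and placed on
  either strand. Decoys are opsin-like sequences (70% of template
  identity) with the 296-homologous site forced to Arg, reproducing the
  false-positive trap that homology-only screens fall into. Fragments
  are random 30–60% windows. A truth table records class, full-length
  status, strand and K296 state per contig.
* **Grouped sets**: the default layout mirrors the published study
  summary — 102 Baikal LWS sequences, 32 planted events, five with more
  than 10 carriers, top counts 48/30/19 whose carrier sets intersect in
  exactly 11 sequences, the second most common at tuning site 115 and
  further events at 90, 109 and 123. Planted, class-diagnostic and
  per-row background substitutions draw from disjoint column pools, and
  European LWS rows are never all mutated at one column; this
  guarantees the planted events are exactly the MWS-like substitutions
  present, so recovery can be asserted as equality rather than
  approximately.
* **Depth tables**: counts are round(intercept + slope·depth + noise)
  clipped at zero, over 43 species at depths uniform on 0–500 m. The
  defaults (slope −0.004 opsins/m, intercept 4.0, noise SD 1.24) were
  calibrated analytically so the population R² of the signal, including
  the rounding variance, sits near 0.17 — a weak but significant
  relationship. Rounding and zero-clipping attenuate single-sample
  fits slightly, and with n = 43 individual adjusted R² values scatter
  roughly ±0.1 around the population value, so checks are made on the
  mean across seeds and on the sign/significance of the slope.

What passing these tests does **not** show: real assemblies contain
sequencing error, chimeric contigs, alternative splicing and codon
bias; real opsin families contain indels, so bovine numbering shifts
along the sequence; and real reference databases are phylogenetically
structured rather than star-shaped around three ancestors. The
synthetic results certify the algorithms, not any particular species
inventory.

## Problem sizes and determinism

The test suite runs the mining pipeline end to end on 20 seeded
assemblies (6 contigs each: 3 LWS + 1 MWS + 2 decoys), the profiler on
the full 113-sequence study-shaped set once plus many small constructed
alignments, and the oracle suites on dozens of random instances each;
the whole suite completes in about three minutes on one CPU. Every
random draw flows from an explicit seed; MAFFT and the NJ construction
are deterministic for a fixed input, so all results are exactly
reproducible.

## Known limitations

* Class assignment trusts the reference database; a candidate from a
  class absent from the database is forced into the nearest present
  class.
* NJ placement with p-distances can misplace candidates under strong
  rate heterogeneity; the placement tree is returned for audit
  precisely because the class decision is a heuristic.
* The K296 check requires the alignment to cover position 296; heavily
  truncated genuine opsins are (by design) not certified.
* The E-value uses fixed Karlin–Altschul constants rather than
  composition-adjusted ones; it is a screen, not a significance claim.
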