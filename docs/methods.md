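# Methods

## Coordinate model

All coordinates are 1-based inclusive on the heavy (H) strand, the
convention of GenBank flat files and printed mitogenome tables. The genome
is circular; a feature with `end < start` wraps the origin and has length
`genome_length − start + 1 + end`. Light-strand (L) features keep H-strand
coordinates; their sense sequence is obtained by reverse complement at
extraction time.

The signed distance between consecutive features (sorted by start, the last
pairing with the first across the origin) is `start₂ − end₁ − 1` on the
circle: positive = intergenic spacer, negative = overlap, zero = abutting.
Each gap is attributed to the upstream feature of the pair. This purely
positional computation is authoritative; printed "intergenic" columns in
published tables are sometimes internally inconsistent with their own
coordinates, and no attempt is made to reproduce such inconsistencies. The
closure identity `Σ lengths + Σ signed gaps = genome_length` is an exact
telescoping consequence of the definition and is asserted on every
generated genome.

Derived quantities that depend on summed annotation lengths (e.g. the
13-PCG fraction of the reference genome, 11,392 / 17,381 = 65.54 %) use the
sums of the tabulated coordinates, not prose figures, where the two
disagree.

## Codon classification

Start codon = first three sense-strand nucleotides. Stop classification by
length mod 3 under the vertebrate mitochondrial code (translation table 2),
whose stop set is {TAA, TAG, AGA, AGG}: a complete terminal stop when the
length is a multiple of three; the incomplete stops `T--` (terminal T,
length ≡ 1) and `TA-` (terminal TA, length ≡ 2), which are completed to UAA
by post-transcriptional polyadenylation. Anything else classifies as `None`
with a warning rather than an error, since real annotations contain
irregular termini. Codons containing ambiguous bases are skipped with a
warning.

Codon counting pools sense-strand triplets read from the start codon of
every protein-coding gene, dropping the 1–2 nt of incomplete terminal
codons. RSCU of codon *c* in synonymous family *F* is
`count(c) / (Σ_{c'∈F} count(c') / |F|)`; a zero-total family reports RSCU 0
for all members. Percentages use the total of counted codons as
denominator (3,765 for the shipped reference counts). The stop codons form
one four-member RSCU family. Codons display in the RNA alphabet; parsers
accept T or U.

The amino-acid usage ranking reports computed family sums (ties broken
alphabetically). On the shipped reference counts the largest family sum is
leucine (587) while the single most frequent codon is AUU (isoleucine,
269); summaries that call isoleucine the most-used amino acid conflate
these two orderings.

## Composition and skews

Profiles count unambiguous A/C/G/T only (N excluded from denominators, a
warning above 1 % N). AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C), each
undefined (`None`) when its denominator is zero. Both skews negate under
reverse complement — the basis of the quantified antisymmetry property test
— so the default `strand_mode="h_strand"` of the skew table measures every
feature on the same physical strand, which is the only mode in which the
light-strand ND6 shows its characteristic inverted skew signs relative to
the heavy-strand genes. `sense` mode is available for coding-strand
composition. The skew table gives one row per PCG, rRNA, CR and CCR (the
CCR as its own row, never folded into the CR), plus a concatenated-PCG row
and a whole-genome row. Percentages print to 2 decimals, skews to 3.

Codon-position composition pools positions 1/2/3 over all PCG sense-strand
codons, excluding incomplete terminal codons.

## Control-region analysis

Motif scanning matches IUPAC patterns with a per-pattern substitution
budget, both strands on request, reporting all (including overlapping)
hits; it is validated against a brute-force sliding-window oracle. The
shipped motif library contains the canonical TACAT/ATGTA palindromes
(exact-match) and *provisional* 20-mer consensi for the F/E/D/C boxes and
CSB a/b/1 with one mismatch allowed. No published box sequences back those
placeholder patterns; the library is an editable TSV and reports name the
library used, so users of real control regions should substitute curated
patterns.

Domain partition anchors on the central conserved boxes: domain II spans
from the first to the last central-box hit, domain I is everything 5′ of
it, domain III everything 3′. Missing anchors raise a named error listing
what is absent, rather than guessing.

The tandem-repeat model is perfect-match: an array is a maximal run in
which every base equals the base one period earlier, reported once with its
smallest primitive unit, spanning `k` full copies plus a fractional tail
(`copy_number` = span/unit length to one decimal; `partial_len` = span mod
unit length). Arrays whose primitive period is below `min_unit`, and arrays
wholly contained in a longer one, are suppressed. Defaults `min_unit=5`,
`max_unit=250`, `min_copies=2.0` cover the unit-length range observed in
raptor pseudo-control regions (9–219 bp). The finder is exhaustively
cross-checked against an all-(start, period) search on regions up to
300 bp. A mismatch-tolerant (alignment-scored) repeat model is deliberately
out of scope; published repeat notations for these regions are reproducible
with the perfect-match model. CCR decomposition tiles the region into
repeat arrays and nonrepetitive (nr-CCR) gaps; the `5prime`/`3prime` anchor
of an array records which half of the region its midpoint falls in.

Note that `copy_number` rounds span/unit, so 12 copies + 8/11 of a unit
prints as 12.7; notations derived instead from ⌈copies⌉ counting can differ
in the final decimal.

## Alignment statistics

Site classification uses only unambiguous A/C/G/T cells: a column with
fewer than two such cells is excluded from all counts (and tallied as
`excluded`); one state = constant; two or more = variable; variable columns
with at least two states each in at least two taxa are
parsimony-informative, the rest singletons. `constant + variable` equals
the classified columns and `informative + singleton = variable` by
construction. Published site counts that do not satisfy these identities
cannot be reproduced without knowing the (unstated) gap convention used, so
real-alignment counts are not used as fixtures. Concatenated-PCG export
extracts sense strands in a fixed gene order, unaligned; alignment and tree
inference are external.

## Synthetic-mitogenome generator

The generator emulates the architecture of the reference vulture mitogenome
so that every pipeline stage can be exercised against planted truth.

* **Layout.** Two templates: `remnant_ccr_raptor` (39 features: 13 PCGs, 22
  tRNAs, 2 rRNAs, CR, CCR; ND6 plus eight tRNAs on the light strand) and
  `standard_avian` (38 features, single CR after tRNA-Glu). Gene lengths
  and inter-gene gaps default to the reference annotation, so default
  coordinates reproduce it exactly; both are configurable, and planted
  spacers/overlaps override individual adjacencies. Infeasible plans
  (negative segment arithmetic) raise a config error.
* **Sequence.** One explicitly seeded NumPy generator drives everything; no
  global state; identical (config, seed) give byte-identical output. PCG
  interiors are drawn codon-by-codon from a planted codon distribution
  (default: the reference codon frequencies with stops removed); the first
  codon is the declared start and the terminus the declared stop (`T--` and
  `TA-` plant their dangling nucleotides). Each PCG's start/stop is
  re-planted after assembly so declared codons survive gene overlaps, and
  the emitted genome is self-validated (closure, codon classification,
  motif and repeat re-verification) before being returned. tRNA/rRNA
  sequences are random-composition placeholders (secondary structure is out
  of scope) drawn, like spacers, from the configured H-strand base
  frequencies (default: the reference genome's overall composition, A
  24.55 %, C 31.59 %, G 14.37 %, T 29.49 %). ND6 is generated on its sense
  strand and reverse-complemented in, which is what reproduces the
  light-strand skew inversion.
* **Control region.** 1,202 bp by default, AT-rich background (T 33.1 %,
  C 25.9 %, A 23.5 %, G 17.5 %, the reference CR composition): a poly-C run
  at the 5′ end of domain I, a TACAT/ATGTA pair, F/E/D/C boxes defining
  domain II and CSB a/b/1 in domain III, at fixed offsets. Background
  positions are rejection-resampled (cap 1,000 iterations) until the
  planted motifs are the only matches of their own patterns and the planted
  poly-C is the only C-run at or above the detection threshold — so motif
  recovery on generator output is exact by construction, which is asserted
  over 100 seeds.
* **Pseudo-control region.** 619 bp by default, matching the reference
  annotation's CCR span: 125 bp nr-CCR, a 12×11 bp array (+8 bp partial), a
  120 bp insert, then a 5×44 bp array (+14 bp partial), using the two
  repeat units reported for this species. (The full published 6.9 × 44 bp
  array does not fit the annotated 619 bp span — the source's CCR length is
  internally inconsistent — so the default plants five full copies.)
  Nonrepetitive segments are rejection-resampled until the repeat finder
  recovers exactly the planted arrays, which also guarantees boundary
  characters do not extend an array.
* **Alignments.** Column classes (constant / parsimony-informative /
  singleton) are apportioned from the requested mix by largest remainder,
  so planted counts are exact; columns are then shuffled. Informative
  columns need ≥ 4 taxa (two states × two taxa each).

What the generator does *not* emulate: substitution processes along a tree,
indels, tRNA cloverleaf structure, heteroplasmy, and within-array repeat
degeneracy. Tests passing on synthetic data therefore validate the
*bookkeeping and detection machinery* — coordinates, codon pooling, skew
algebra, motif/repeat recovery — not the biological realism of any
particular sequence.

## Numerical conventions

Percentages are exact ratios reported to 2 decimals, skews to 3, repeat
copy numbers to 1; rounding is Python's round-half-even on Python floats
(the repeat finder casts NumPy integers before division so that printed
copy numbers match hand computation). Family RSCU sums are exact up to
floating rounding. Ties in amino-acid rankings break alphabetically; equal
repeat-array intervals resolve to the smaller unit. Degenerate inputs
(empty sequences, zero-total families, all-ambiguous columns) raise named
errors or report flagged zeros as documented per function.

## Problem sizes used in the test suite

Property suites run at sizes where the independent oracles are exact and
fast: repeat-finder oracle equivalence on 500 random regions ≤ 300 bp;
planted-cassette recovery on 500 seeded arrays (units 5–50 bp, 2–30
copies); site-classification oracle agreement on 1,000 alignments ≤ 8 taxa
× 40 columns; closure on 200 random circular annotations; skew
antisymmetry on 300 random sequences. The whole suite completes in well
under a minute on one CPU.

## Known limitations

* Whole-genome composition of the deposited reference sequence can only be
  verified with the downloaded FASTA (the package redistributes the
  annotation and codon counts, not the 17.4 kb sequence); the corresponding
  test states where to place it.
* The conserved-box/CSB library is provisional (see above).
* The repeat finder's perfect-match model will fragment arrays containing
  point mutations; such regions appear as alternating short arrays and
  nr segments rather than one degenerate array.
* GenBank import supports single-interval features only — sufficient for
  mitogenomes of this architecture, where join() features do not occur.
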