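# Methods

This note records the models, conventions and numerical choices behind
plastokit, and what the synthetic-data tests do and do not establish.

## Coordinates and circular semantics

All features live in 0-based half-open genome coordinates.  On a circular
molecule a feature may span the origin; it is stored as a single interval
with `end <= start`, read as `[start, n) + [0, end)`.  GFF3 (1-based closed)
and GenBank (1-based closed with join/complement locations) are converted at
the boundary; an origin-spanning gene written to GFF3 uses the common
`end > sequence length` convention for circular molecules and round-trips
exactly.  A GenBank `join` whose two segments abut the origin on a circular
record is collapsed into one wrapped interval; any other multi-segment
location is kept as `parts` and flags the gene as spliced (intron present).
Translation uses code 11 (plastid/bacterial); the alternative initiators GTG
and ATT are rendered as methionine only at an annotated start.  N is allowed
in sequences but a CDS with N in a terminal codon, or whose length is not a
multiple of 3, is excluded from the codon census with a logged reason rather
than an error.

## Inverted repeats and the quadripartite partition

An inverted-repeat pair is two disjoint intervals of equal length whose
sequences are exact reverse complements, not extendable in either direction
(mismatch tolerance 0: brown-algal IR copies are annotated as identical, and
exactness keeps maximality well defined).  Internally a pair lives on one
anti-diagonal `s = (x + y) mod n` of the complementarity relation
`seq[x] == complement(seq[y])`; a maximal run of matches on an anti-diagonal
either mirrors a second run (a two-copy repeat) or mirrors itself (a
palindrome, whose two halves form the maximal disjoint pair).  The search
seeds on canonical k-mer matches between the sequence and its reverse
complement (k = min(12, min_len) generally, 21 for kilobase-scale searches)
and extends per base, which reproduces the quadratic brute-force enumeration
exactly on fuzzed circles while staying fast on 130 kb genomes.

`detect_quadripartite` takes the longest pair at or above `min_ir = 1000` nt;
the default ignores the 84 nt hairpin and small dispersed repeats because
brown-algal IRs are kilobase-scale.  The two arcs between the copies become
the single-copy regions, the longer one labelled LSC; IRa is the copy whose
clockwise downstream arc is the SSC.  Ties (equal arcs, equal-length pairs)
break toward the smaller start coordinate, so the partition is deterministic
and rotation- and strand-invariant.  Base composition excludes N from the
denominator.

## Census and overlaps

Start/stop tallies are per feature occurrence: a gene duplicated inside the
IRs is counted once per copy, matching plain feature arithmetic.  Codons
outside the {ATG, GTG, ATT} / {TAA, TAG, TGA} sets are tallied as `other`
rather than rejected, for robustness to foreign annotations.  Overlaps are
computed as exact circular-interval intersections over all feature pairs
(O(n²), trivially fast at plastome gene counts); strandedness is recorded
but not filtered.

## Elements

The stem-loop is operationalized as a maximal perfect even-length palindrome
(zero loop), found by centre expansion on the circle; every reported interval
is re-verified to equal its own reverse complement.  Tandem arrays are
maximal runs of the periodicity relation `seq[i] == seq[i + u]` for unit
sizes 1–6, reported from the leftmost position with the lexicographically
smallest unit rotation and only for primitive units (so an (ATT)₄ array is
not also reported as (ATTATT)₂); an array needs at least 2 copies.

Ortholog comparison aligns the two CDS globally (match +1, mismatch −1, gap
open −4, extend −1) and canonicalizes gap placement to the 3'-most
score-equivalent position so indel coordinates are deterministic.  A gap
whose inserted/deleted segment is a whole number of copies of a primitive
1–6 nt unit, lying in or adjacent to an array of ≥ 2 copies, becomes a
polymorphism with signed Δnt = |unit|·(copies_A − copies_B) and a frame flag
(Δnt ≡ 0 mod 3).  Context arrays are reported within ±15 nt.  A homopolymer
cassette such as (AAA)ₙ(GAA)₃ is, correctly, described by its primitive unit
A; the codon-sized length change is identical either way.  Pairs below 50%
aligned identity are rejected as incomparable.

## Synteny

Genomes are reduced to their CDS and rRNA features in circular order (tRNAs
excluded by default, as gene-order comparisons of plastomes are usually drawn
for the larger genes; a flag includes them).  Names are matched exactly but
case-insensitively with a tiny alias table; duplicate names (IR copies) are
disambiguated by order of occurrence.  Both genomes are linearized at the
lexicographically smallest shared gene, and the comparator is traversed in
the direction that makes the anchor's strand agree, since circular start and
reading direction are both arbitrary.  Maximal strips (consecutive signed
values increasing by one with constant sign) are the collinear blocks;
strips are not merged across the linearization point.

## Recruitment

Classification is containment of canonical k-mers (default k = 21, threshold
0.5) — a deterministic, alignment-free analogue of read binning against
reference plastomes; k-mers containing N count toward the denominator and
never match, so an all-N read has containment 0.  Contig ordering votes with
unique anchors (k-mers occurring exactly once in the reference): each anchor
hit proposes an (orientation, offset) pair and the majority wins, ties
breaking toward forward and the smallest offset.  These defaults are module
decisions; no published cut-offs exist for the original binning step.

## Phylogeny

The marker set is the 23 plastid protein-coding genes shared across
published plastid genomes.  Families are aligned progressively: all pairwise
global alignments under BLOSUM62 with affine gaps (−10 open, −1 extend) give
p-distances, a UPGMA guide tree (deterministic tie-breaks) orders the
profile–profile merges, and profiles are aligned by dynamic programming with
column scores equal to the mean pairwise BLOSUM62 value (gaps contribute 0)
and a linear gap cost of 8 per column, with a fixed diagonal-up-left
traceback preference.  Maximum-likelihood and Bayesian inference are out of
scope; the implemented inference is distance/NJ plus the consensus machinery.

Concatenation keeps gap-containing sites.  Distances are Poisson-corrected
p-distances over shared non-gap columns (pairwise deletion); a saturated
pair (p ≥ 1) or a pair with no shared columns is an error.  Neighbor joining
breaks Q-matrix ties toward the smallest index pair and clamps negative
branch lengths to zero with a warning; on an additive matrix it reproduces
the generating tree and its metric exactly, which the tests verify against
exhaustive topology enumeration at five taxa and path-metric recomputation up
to eight.

Bootstrap consensus resamples alignment columns with replacement, builds one
NJ tree per replicate, and keeps bipartitions present in more than the
threshold (default 0.5) of replicates.  Internal edges shorter than 1e-9 are
collapsed before counting: NJ's deterministic tie-breaking would otherwise
hand an identical-sequence alignment the same arbitrary resolved topology in
every replicate and give 100% support to noise; with the collapse, a
signal-free alignment yields the star tree.  Supports are replicate
frequencies; consensus branch lengths are nominal.

## The simulator

The generator's defaults are the study conditions: a 130,383 nt circle
(LSC 76,598 / SSC 42,977 / IR 5,404), 69.38% A+T, 139 CDS + 28 tRNA + 6 rRNA
with no introns, overlaps rpl23–rpl4 8 nt, ftrB–ycf12 6 nt, ycf16–ycf24 4 nt
and psbC–psbD 53 nt, an 84 nt perfect palindrome between psaL and rbcR,
(ATT)₃ in ycf35 preceded by (AAT)₄ and (AAA)₄ in ilvB followed by (GAA)₃,
starts ATG×136 / GTG×2 (rps8, psbF) / ATT×1 (atpA) and stops TAA×116 /
TAG×21 / TGA×2.  Companion presets realize the three comparator genomes'
codon rows and structural differences (IR +92 nt, one extra tRNA and gene
length deltas for the Laminariales sister; petL and segment inversions for
the other two).  These are synthetic stand-ins constructed from the printed
summary statistics, not the GenBank records.

Construction notes:

- Gene bodies are random non-stop codons drawn at the target base
  composition; per-gene streams are seeded by `(gene_seed, crc32(name))`, so
  orthologs are identical across species apart from planted differences —
  which makes ortholog repeat comparisons exact by construction.
- Overlap geometry is constrained: on the same strand, a head-to-tail
  overlap that is a multiple of 3 would put gene A's stop codon in gene B's
  frame, so the 6 nt pair is realized as a convergent (3'–3') opposite-strand
  overlap, and the 4 nt pair forces gene A's stop to TGA (the classic ATGA
  motif).  Free bases around the junction are rejection-sampled until both
  frames are stop-free.
- The rRNA operon (16S, 23S, 5S) is placed once per IR copy, giving the six
  rRNA features; IRb is the exact reverse complement of IRa, and one spacer
  base at each junction is adjusted if needed so the planted pair is maximal.
- Spacer composition is solved after the genic sequence is fixed so the
  genome-wide A+T hits the target; empirically the realized value is within
  ~0.1 percentage point.
- Everything derives from `numpy.default_rng` streams keyed on the config,
  so identical configs give byte-identical FASTA/GFF3.

What the simulator does not emulate: real codon usage and amino-acid
content, sequencing error, IR boundary wobble, partial repeats, nested gene
structures, or genuine phylogenetic signal among the four stand-ins (their
marker distances are near-equal noise).  Passing tests therefore show the
measurement machinery is exact on genomes with the stated structure, not
that annotation of real sequencing data is error-free.

## Problem sizes

The test suite and the acceptance script run on: four 130 kb genomes,
oracle-equivalence fuzzing at 60–3,000 nt (200 circles for inverted repeats,
50 annotations for overlaps, kilobase strings for palindromes/tandem
arrays), 2,000 reads of 100 nt at a 60/40 target/decoy mix, 100–200 random
additive matrices of 4–8 taxa, and 100 bootstrap replicates over a 300-site
five-taxon family.  These sizes keep the full run in tens of seconds while
every check remains exact or truth-set based.
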