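# Methods

## Data model

A mitogenome is a circular DNA string with 0-based half-open gene features
on the H-strand coordinate frame (GFF3 input is converted at the boundary;
L-strand genes are reverse-complemented on extraction).  Gene orders are
circular token lists `(symbol, strand, cr_state)`; equality is invariant
under rotation but **not** reflection, because mitochondrial strands are
annotated, not symmetric.  A control-region copy is *remnant* when it lacks
all the conserved box motifs of a complete CR (or when the annotation says
so); remnancy is an annotation state, never a gene loss.

Order-type labels: `A` one CR; `B` two complete CRs; `C` one complete plus
one remnant CR; `T1/T2/T3` at least one duplicated non-CR gene (a surviving
duplicate Cytb ⇒ T1, else trnT ⇒ T2, else a duplicate within trnP–ND6–trnE
⇒ T3); `UN` otherwise.  The rule set is total.

## Local alignment and percent identity

Pairwise comparison uses affine-gap Smith–Waterman with the classical water
parameterisation: match +5, mismatch −4, gap open 10.0, gap extend 0.5, a
gap of length *L* costing `10 + 0.5·L`.  Percent identity is identical
columns over **all** alignment columns, gap columns included — the only
convention consistent with the published lark similarity ranges (e.g. a
one-insertion, three-substitution pair of 67/68-nt units gives
64/68 = 94.1%).  Determinism: among co-optimal alignments the end cell with
the smallest row-major `(i, j)` wins; the local traceback prefers diagonal
over up over left.  The global aligner used for mask encoding places
score-equivalent gap runs at the alignment ends, so a truncated haplotype
encodes as trailing dashes rather than an arbitrary interior gap.

Haplotypes are published as dot/dash masks against a reference row: `.` is
identity, `-` a gap, a letter a substitution (or an insertion where the
reference column is `-`); masks shorter than the reference are padded with
dashes (truncated final units).  Decode and encode are mutual inverses.

## Tandem-repeat detection and decomposition

Candidate periods come from the distance spectrum of repeated 8-mers.  For
each candidate period *p*, the 0/1 self-match track `s[i] == s[i+p]` is
segmented by a maximal-scoring-segment scan at the identity threshold, each
segment is tiled into units, a column-majority consensus is built, and the
boundaries are extended while flanking bases match the periodic
continuation of the consensus.  Flank extensions shorter than
`min_partial = 5` bases are trimmed as chance matches (a random flank base
matches with probability 1/4; runs of five are rare), so planted boundaries
are recovered exactly with high probability while genuinely truncated final
units (e.g. a 26-nt tail of a 61-nt period) are retained.  Calls must reach
`min_copies = 1.9` copies and `min_identity = 80%` mean full-unit-to-
consensus identity; overlapping calls are resolved by coverage score, then
smaller period, then position.  Divisors of the period whose re-tiling
still meets the identity threshold are reported as alternative sub-periods
— this is how a fused two-subunit array (64 = 2 × 32 with nine
substitutions between the halves) surfaces both readings.  Decomposition is
exact by construction: `5NR + units + 3NR` re-concatenates to the input.

Consensus building uses the modal unit length (ties toward the longest, so
a lone divergent or truncated unit cannot set the frame) and breaks column
ties toward the earliest contributing unit.

Similarity statistics run over distinct haplotypes, excluding (a) a
divergent initial unit — flagged when unit 1 falls below 90% identity to
the consensus of the remaining units while all remaining full-length units
stay at or above it — and (b) haplotypes whose deletion against the
consensus is internal; terminal truncations are kept because local
alignment trims them naturally.  This combination reproduces every
published within-species range.

## Secondary-structure proxy

Unit foldability is scored by Watson–Crick base-pair maximization
(Nussinov-style dynamic programming, hairpin loops ≥ 3 nt, A:T and G:C
pairs only), reported with a dot-bracket structure.  The count is a
stability *proxy*: thermodynamic free energies in kcal/mol depend on an
external folding parameter set and are deliberately not computed.  The
proxy preserves the qualitative observations that matter here, e.g. a unit
that folds poorly alone gains structure when fused with its partner
(`pairs(a+b) ≥ pairs(b)` holds for all strings).

## Homology scan

Seven query patterns (5NR, TR-unit consensus, 3NR, and their
concatenations) are scanned against the doubled genome sequence (so
origin-spanning homology is found) on both strands.  Exact 12-mer seed
matches nominate windows of pattern length plus a 25 bp margin; each window
is aligned locally and hits pass at ≥ 85% identity over ≥ 30 columns by
default — thresholds chosen as a clear floor under the one real positive
control (100% over 81 bp) while rejecting random 17 kb genomes, and
recorded as configuration, not biology.  Hits overlapping the source CR2
are suppressed; features overlap a hit at ≥ 1 bp intersection.

## TDRL enumeration

A scenario duplicates one contiguous block that contains and ends at the
CR, starting within the Cytb..CR window, then deletes exactly one copy of
each duplicated non-CR gene; both CR copies always survive (degradation to
a remnant is annotation, not loss).  Enumeration tries every block and
every per-gene copy choice and keeps those whose result equals the target
up to rotation, ordered shortest block first.  From the ancestral avian
order this yields exactly three blocks, whose duplication intermediates
classify as T3, T2 and T1 with 3, 4 and 5 losses respectively; the
loss count is reported as metadata, not used to rank scenarios.  The window
restriction is a configurable constraint, not a claim about mechanism.

## Parsimony mapping and the association test

Ancestral states use Hartigan's generalization of the Fitch algorithm: on
the up-pass each node keeps the states attained by the maximal number of
children and adds `children − max` changes; this is the exact minimum on
binary and multifurcating trees (the simpler intersection/union rule is
not, which is why it was not used).  The down-pass takes the parent's state
when possible, else the lexicographically smallest member, and changes are
the branches where the resolved states differ — their count equals the
up-pass minimum.  Branch lengths are ignored.

The Fisher exact test sums hypergeometric probabilities of all 2×2 tables
with the observed margins whose probability does not exceed the observed
one, with 1e-7 relative slack for floating-point ties.  The published
species-level contingency table is not part of this package's inputs; the
test takes a user-supplied table.

## Synthetic data

The generator emulates structure, not biology: random gene sequences of
plausible lengths (PCGs 300–1500 nt with a valid start and stop under the
vertebrate mitochondrial code, tRNAs 65–75 nt, rRNAs ~0.95/1.6 kb), a CR1
with fixed literal box motifs in domain order, and a remnant CR2 of
`five_nr + units + three_nr`.  CR2 defaults are lark-like: a 60-bp 5NR,
four copies of a 37-bp unit, an 81-bp 3NR (81 bp being the length of the
rrnS-homologous 3NR in the one published positive control), per-unit
substitution rate 0.01; options add a divergent first unit (substitution
rate 0.30, emulating the D_1/F_1/G_1 pattern), a period fused from two
halves diverged at ~28% of sites, and a verbatim copy of the 3NR at the
rrnS 5′ end.  All randomness derives from one integer seed with fixed
per-component sub-streams, so regeneration is byte-identical; consumers in
the test suite read simulator output only through FASTA/TSV/Newick, never
the in-memory truth record.

What passing on synthetic data does **not** show: real control regions have
base composition bias, heteroplasmy and concerted evolution that i.i.d.
random sequence lacks, so detector thresholds tuned here are defaults, not
guarantees, on real data.

## Numerical and edge-case choices

- Skew denominators exclude N and ambiguity codes; an empty denominator is
  reported as null, never zero.
- RSCU families with zero usage report 0 for all members; internal stop
  codons warn with their position and are excluded from counts.
- Incomplete stop codons (1–2 trailing nt) are reported as-is, not
  polyadenylation-completed.
- Degenerate inputs raise: empty sequences for alignment/skew, CDS < 6 nt,
  ambiguous rotation anchors, all-zero contingency tables, repeat calls
  outside their region.
- Problem sizes in the test suite (17 kb genomes, 50-replicate recovery
  sweeps, ≤ 10-tip exhaustive parsimony, ≤ 18-nt exhaustive folding) were
  chosen so each oracle comparison is exact yet the whole suite runs in
  seconds.

## Known limitations

- The tandem-repeat boundary is ambiguous by one or two bases when a flank
  base happens to continue the periodic pattern; the detector resolves this
  deterministically but cannot recover an unknowable truth.
- Identity-based exclusion rules reproduce the published ranges but the
  underlying convention for internal-deletion haplotypes was inferred, not
  stated.
- Single-duplication scenarios only; multi-event TDRL histories and
  intermolecular recombination models are out of scope.
- The fold score is a pair count, not an energy; values are comparable
  within this package only.
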