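# Methods

`plastarch` re-implements, as one tested pipeline, the comparative analysis
of chloroplast genome architecture across a clade of green algae: how gene
order, the large inverted repeat (IR), small repeats and nucleotide
composition change along a fixed reference phylogeny.  This note documents
the models and procedures, the parameters that matter, the numerical
choices, and what the synthetic data do and do not show.

## Genome model and coordinates

A genome is a circular nucleotide sequence plus an ordered list of gene
features (CDS/tRNA/rRNA), each with a strand and one or more exon spans.
Coordinates are 0-based and half-open throughout.  Origin-wrapping features
are represented as sub-intervals that jump across the origin; the wrap gap
is never counted as an intron.  Positions are partitioned coding > intron >
intergenic on overlap, so the three categories always sum to the genome
length.  Intron-encoded ORFs count as intron sequence by default (the
convention of the source study's per-genome breakdown), switchable with
`intron_orfs_as_coding`.  Intron typing (group I vs II) is read from
annotation qualifiers only — secondary-structure inference is out of scope.

## Signed gene orders and sidedness

Each genome is reduced to a circular permutation of gene symbols with
strand signs, restricted by default to the packaged 91-gene core set, with
one IR copy collapsed (features inside IRB dropped) and any residual
duplicate keeping its first occurrence clockwise from position 0.  The
sidedness index is

    C_s = (n − n_SB) / (n − 1),

where n_SB counts maximal runs of adjacent same-strand genes.  Runs are
counted circularly — the first and last runs merge when they share a strand
— because the molecules are circles; the source text does not state this
convention, so a `--linear` flag exposes the alternative.  C_s = 1 means all
genes on one strand; strictly alternating strands give C_s = 0.

Adjacencies are canonicalized so that (x, y) and (−y, −x) — the same
physical junction read from the two strands — map to one representative
(the lexicographically smaller rendering).  The shared-pair matrix keeps
pairs present in at least `min_share` taxa (default 5) and distinguishes
"pair absent" from "a member gene missing from that genome" (NA).

## Inverted-repeat detection and the quadripartite partition

The large IR is found as the longest pair of exact, non-overlapping,
reverse-complementary segments of length ≥ `min_len` (default 1,000 bp,
far below any real plastome IR), by indexing k-mers (k = 25) of the
sequence against its reverse complement and extending every novel seed
maximally along its anti-diagonal.  Only exact copies are considered — the
study-scale IR copies are identical, and exactness keeps detection
deterministic and testable; a mismatch-tolerant mode is deliberately
excluded.  Ties in length prefer a candidate containing *rrs* (the IR
normally encodes the rRNA operon), then the leftmost start.  Candidates
whose maximal extensions overlap (one long palindrome rather than two
separated copies) are rejected.  The two single-copy segments are named by
length: LSC (longer) and SSC (shorter).  The invariant
2·IR + LSC + SSC = genome length is asserted on every detection.

Gene partitioning assigns each gene to IR, LSC or SSC; a gene spanning an
IR/SC junction belongs to the single-copy side it reaches into.  The
packaged reference table gives each core gene's ancestral side relative to
the rDNA operon; genes found on the opposite single-copy side are flagged
as relocations.  The rDNA operon check audits the four internal adjacencies
of rrs–trnI(gau)–trnA(ugc)–rrl–rrf: an adjacency is broken when the two
genes are not adjacent in the collapsed order, not colinear in sign, or
(when coordinates are available) separated by more than 3,000 bp — a bound
motivated by the observation that an intact-looking linkage across a
3.2-kb spacer need not be cotranscribed.  Orientation reports whether
transcription (rrs → rrf) runs toward the SSC or the LSC.

## Reversal distance

The rearrangement distance between two circular signed gene orders is the
exact minimum number of inversions, computed by Hannenhalli–Pevzner theory.
Both orders are rotated/reflected so a shared anchor gene (default: the
lexicographically smallest shared symbol) sits first with positive sign;
the anchor is dropped, reducing circular distance to the linear distance of
the remaining permutation — anchor choice is provably irrelevant and is
also checked exhaustively in the tests.  The breakpoint graph gives

    d = (m + 1) − c + h + f

with c cycles, h hurdles, f the fortress indicator.  Unoriented components
are found via the interleaving graph of nontrivial cycles (a gray edge is
oriented iff its endpoint positions share parity); a component is a hurdle
iff its points are consecutive on the circular point order, and a fortress
requires an odd number of hurdles, all of which protect non-hurdles.  The
component machinery is O(m²) — clarity was preferred over the linear-time
algorithm, and m ≤ ~120 genes at plastome scale makes the cost irrelevant.
The whole computation is validated against a breadth-first-search oracle
over the inversion graph, exhaustively for all signed permutations of up to
six elements.  Genomes with unequal gene sets are restricted to their
symbol intersection (logged) before the distance matrix is built.

## Dollo parsimony

Binary characters (gene adjacencies, IR presence, gene presence) are traced
on the fixed rooted reference tree under the Dollo principle: one gain,
unlimited losses.  The minimal reconstruction is unique — gain at the MRCA
of the state-1 leaves, one loss on the branch to every maximal state-0
subtree inside the gained clade — and is checked in the tests against
exhaustive enumeration of all single-gain internal-state assignments.
Leaves scored NA (incomplete genomes) are excluded from gain placement and
reported as unknown subtrees rather than losses.  Polytomies are allowed; a
loss on a polytomy child counts once per branch.  Note the identifiability
limits inherent to parsimony: two sibling losses collapse into one deeper
loss, and a loss clade attached outside the MRCA of the remaining carriers
is reconstructed as "never gained".

## Repeat landscape

All maximal exact repeated pairs ≥ 30 bp, forward and palindromic
(reverse-complement), are found by seeding on shared 30-mers and extending
maximally; every maximal pair of length ≥ L contains a shared L-mer, so
seeding at the cutoff is complete.  Each emitted hit is re-verified by
string comparison and checked to be inextensible.  The two large IR copies
form one giant palindromic hit and are excluded from the small-repeat
summary by default (they are reported by the architecture stage); an
`--include-ir` switch reverses this.  Masking is non-overlapping: a
position counts once however many hits cover it.  Distinct elements for the
six-bin size histogram (30–39, 40–59, 60–89, 90–149, 150–249, ≥250 bp) are
merged components of overlapping hit intervals grouped by exact sequence
identity — an exact-match simplification of repeat-family clustering, and
labelled as such.  The G+C of repeated vs unique positions satisfies the
length-weighted identity with whole-genome G+C to 1e-9, which is asserted.
Detection treats the sequence as linear; the synthetic genomes never place
a repeat across the origin.

## Composition

A+T content is (A+T)/(A+C+G+T) × 100 with ambiguity codes excluded.  G+C by
codon position is computed over the concatenation of in-frame CDS
sequences; a CDS whose length is not divisible by 3 is an error naming the
gene.  Stop codons annotated within the CDS span are included.

## The synthetic plastome evolver

The simulator is the test bed for every stage.  The ancestor is a circular
quadripartite genome — by default 40 genes (8 in the IR, 5 of them the rDNA
operon transcribed toward the SSC; 4 SSC genes drawn from the ancestrally
SSC-side gene pool), ~45 kb, 65% A+T — chosen as a roughly one-quarter-scale
plastome so that whole-clade sweeps stay cheap while IRs (~8–17 kb) remain
far above the 1 kb detection floor.  Gene sequences are random codons at
the target composition: the simulator emulates architecture, not homology,
because no alignment stage exists downstream.

Evolution along a rooted tree draws Poisson event counts per branch
(default rates per branch: inversion 1.0, IR expansion 0.3, IR contraction
0.3, IR loss 0.15, repeat insertion 1.0; scaled by branch length when
present).  Inversions pick a uniform gene-segment within one region, so no
endpoint ever splits an IR copy; IRB is always derived as the mirror of
IRA, keeping the two copies exactly identical by construction.  Expansions
absorb the adjacent single-copy gene (with its spacer) into both IR copies;
contractions release a boundary gene (never an rDNA gene); IR loss deletes
IRB and merges the circle, irreversibly.  Repeat insertions copy a ≥30-bp
segment (length 30 + exponential, mean ~60 bp) elsewhere, forward or
reverse-complemented.  Infeasible events (e.g. expansion from a 1-gene SSC)
are skipped.  Every applied event is recorded with full parameters in a
truth log that replays from the ancestor to bit-identical tips; replay
determinism, including a JSON serialization round trip, is tested.

At realization, the first base of each single-copy block is adjusted when
it would extend the IR palindrome by one base, so the planted IR is exactly
maximal and sequence-level detection recovers its coordinates precisely.
This mutates at most two bases per genome, always outside the IR.

What passing synthetic tests show — and do not show.  The simulator
plants the event types the pipeline is meant to recover, so the tests
demonstrate correctness of detection, distance, partitioning and Dollo
mapping under the stated model: exact IR copies, inversions respecting IR
boundaries, no nucleotide substitution, no introns, no gene loss or
duplication outside the IR, no origin-spanning repeats.  Real plastomes
violate several of these (near-identical IR copies, annotation noise,
intron mobility); results on real data depend on annotation quality and on
the exact-match assumptions stated above.

## Problem sizes

The default test and analysis runs use 40-gene, ~45-kb genomes on 4–10-tip
trees, 200-replicate sweeps for inversion-count recovery, exhaustive
reversal-distance validation to m = 6 (50,362 permutations), and exhaustive
Dollo validation on random trees to 10 leaves — sizes chosen so the entire
suite completes in well under a minute while every check remains exact.

## Known limitations

- IR detection is exact-match and linear-sequence; an IR spanning the
  chosen origin of a real record would need rotation first.
- The reversal distance models inversions only — no translocations,
  transpositions, or rearrangement medians; no gene-order phylogeny
  inference.
- Dollo identifiability caveats above apply to any presence/absence
  character, including the IR itself.
- Repeat-family structure is approximated by exact-identity grouping; no
  degenerate (mismatch-tolerant) repeats.
- The packaged study table and tree are transcriptions; nodes not
  corroborated by the running text are polytomies, listed in the fixture
  manifest.
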