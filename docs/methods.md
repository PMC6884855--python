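# Methods

This note documents the models, algorithms and numerical choices behind
`nanobarcoder`, what the synthetic-data generator does and does not
emulate, and the design decisions taken where several readings were
defensible.

## Tag design and the mutant index

Tags are 13-nt sequences appended to both PCR primers; a specimen is
identified by its (forward, reverse) tag pair, so n forward × m reverse
tags address n·m products per flowcell. Because 1D nanopore errors are
indel-rich, tag sets are screened with full unit-cost edit distance, not
Hamming distance:

- candidate generation: rejection sampling of equal-length strings at
  pairwise Hamming distance ≥ 6 (Hamming lower-bounds Levenshtein for
  equal lengths and is what a first-pass generator screens);
- screens: no homopolymer run > 2 nt; no tag ending in a configurable
  3'-terminal motif (default `GG`, because the forward primer starts
  with it and the junction would be ambiguous); recursive elimination
  until all pairs differ by ≥ 3 edits of any type. Elimination order:
  repeatedly drop the candidate in the most sub-threshold pairs, ties
  broken lexicographically — deterministic and close to minimal loss.

Demultiplexing tolerates up to `max_errors` (default 2) tag errors by
precomputing every string reachable from any tag within that many
edits. A mutant reachable from two tags is ambiguous: it is excluded
from the index and recorded, so an erroneous tag never resolves to the
wrong specimen silently. Each original tag always maps to itself.

## Read simulation

The generator emulates the *structure* of a pooled tagged-amplicon 1D
run, not its signal level:

- product = 13-nt tag + 25-nt forward primer + 658-nt coding barcode +
  reverse-complemented 26-nt reverse primer + reverse-complemented
  13-nt tag = 735 nt; read orientation is random;
- community structure: species ancestors mutate a stop-codon-free root
  template at disjoint site blocks (so between-species p-distance ≥ the
  configured minimum, default 8%), specimens mutate their ancestor by at
  most half the intra-species ceiling (default ceiling 1%); all
  mutations avoid creating in-frame stops;
- errors: independent per-base substitution / insertion / deletion with
  configurable rates; indel rates are multiplied (default 2×) inside
  homopolymer runs ≥ 3 nt, reproducing nanopore's run-length weakness;
- anomalies: ligated double-amplicon reads (two products end to end),
  reads carrying tag pairs absent from the layout, and
  cross-contaminating reads (a well's tags on another specimen's
  template);
- coverage: log-normal per specimen (median 45×, σ = 0.6 by default) so
  the ≤ 10× and ≤ 50× re-pooling classes are populated.

Not modelled: realistic quality scores (the FASTQ carries a uniform
placeholder and the pipeline ignores qualities), context-dependent
substitution spectra, chimeras other than clean two-product ligations,
or carrier DNA. Consequently, passing tests show the *algorithms* are
correct under realistic error rates and structure; they do not certify
accuracy numbers on any particular real flowcell.

## Demultiplexing

Reads < 600 nt are discarded. Reads of 1300–2000 nt are searched for a
second product start (either primer in literal orientation) after
position 650 and split 13 nt upstream of the hit so the second product
keeps its tag; longer reads pass through flagged (only two-product
ligations are handled). Each unit is oriented by its better primer hit
within the first 100 bp, both primers must be found (semi-global
alignment, IUPAC-aware, error cap 6 for a 25–26-nt primer), and a 20-bp
flank outward of each primer is homopolymer-compressed (runs > 3 nt
truncated to 3) before every window of a length the mutant index can
resolve (13 ± 2 nt) is looked up, nearest-to-primer first. Both tags
must resolve uniquely; single-tag reads are deliberately unassigned. Bin
reads are stored primer-trimmed and forward-oriented. Coordinates are
0-based half-open throughout.

The misassignment profile of this scheme is conservative: an error must
convert one valid tag into (within 2 edits of) another for a read to
switch bins, which needs ≥ 3 well-placed errors in 13 nt. On the
validation study < 0.1% of demultiplexed reads are misassigned.

## Consensus calling

Draft: up to 100 reads are subsampled per bin (uniform, seeded) and
multiply aligned with zero gap-opening cost — substitution 1, gap 1 per
base — so indel evidence stays staggered across columns instead of being
collapsed into gapped blocks. The built-in engine is a center-star
progressive aligner (longest read as center, unit-cost pairwise
alignments merged on center coordinates); any engine producing
equivalent consensus may be substituted. Per column with ≥ 50% rule:
depth counts gaps; a gap-majority column emits nothing; the modal base
is called if it reaches 50% of depth (a tie at exactly 50% against gaps
still calls the base, since ambiguity is defined as *below* 50%); two
bases tying for the mode emit N (no evidence to choose). Bins under 5×
coverage yield no barcode; drafts with ≥ 1% N are rejected. The
low-coverage and ambiguity screens apply at the draft stage
(preliminary barcodes), not after polishing.

Polish: every bin read (not just the subsample) is aligned to the
draft; reads above 15% divergence (edit distance over alignment length,
sized for 1D error rates) are excluded and the columns re-voted with
the draft as alignment center. Reported coverage is always the full bin
read count, which is what re-pooling decisions need.

## Amino-acid correction and consolidation

COI translates without stop codons in one frame (invertebrate
mitochondrial code, table 5 — configurable), which makes residual
frameshifts detectable. The procedure here is a re-derivation of
reference-guided frame repair, not a byte-compatible port of any
existing script:

1. the barcode is globally aligned (unit cost) to its best reference —
   the library entry with highest global identity, minimum 70%; in
   validation runs the reference library is the simulation's own
   templates with leave-one-out matching, standing in for a public
   reference database;
2. if the alignment contains a run of ≥ 5 indel columns (runs separated
   by a single coincidentally-matching column are merged, since a
   contiguous insertion can be split by the aligner around one match),
   the barcode is rejected as irrecoverable;
3. otherwise each indel event is repaired conservatively: inserted
   bases are deleted, deleted bases are replaced by N — a base is never
   guessed. The repair position is chosen among candidates within
   `namino` codons (default 2) of the event by maximizing amino-acid
   identity to the reference translation over `namino` codons on each
   side; ties go leftmost. Events are processed right to left so
   upstream coordinates stay valid;
4. a final translation check replaces any remaining in-frame stop codon
   with NNN and reports the count.

With these conservative edits the choice of `namino` has little
residual effect (window sizes 1–3 agree to within 0.005% mean accuracy
on simulated frameshifts); the default follows the window that balances
context against locality.

Consolidation takes the two corrected tracks (draft-based and
polish-based), aligns them with an elevated gap-opening penalty (affine,
open 3, extend 1 — both inputs are translatable, so their alignment
should need no gaps), and rejects the barcode if any gap remains. Per
position: agreement keeps the base; a substitution conflict becomes N;
N in one track defers to the other track's determined base. The rule
exists to strip ambiguities — the draft track typically carries more
N — and does so at the cost of occasionally inheriting the other
track's error, so the consolidated mean accuracy can sit a hair below
the stronger single track while its ambiguity content is much lower. A
specimen with only one surviving track passes through flagged.

## QC

Per-base accuracy aligns a barcode to its reference and counts matches
over compared sites, where internal indels count as errors and columns
carrying N are excluded (ambiguity is reported separately, not as
error); terminal overhangs are trimmed. Barcodes diverging > 3% from
their reference are excluded from accuracy averaging before means are
taken — on real data such outliers are wet-lab artefacts (wrong product
amplified), not consensus errors. Full-length barcodes are compared to
short-read references on the 313-nt fragment delimited by the internal
degenerate primer pair; the fragment is located by the forward internal
primer site and extends 313 nt (the reverse primer binds beyond the
barcode's 3' end).

Demultiplexing error is estimated from reads resolving to tag pairs
absent from the layout (not estimable when every combination is used).
Contamination screening matches barcodes against a labelled reference
FASTA with the built-in aligner — no live remote database: best
non-target hit ≥ 95% identity → remove; no hit ≥ 95% and no target
taxon among the top 100 matches → inspect; else keep. Reference
barcodes are called from short-read sets by the dominant-sequence rule
(> 50× set coverage, > 10× sequence coverage, ≥ 5× dominance over the
runner-up). Secondary sequences (≥ 10 counts) matching another
cluster's barcode at ≥ 99% identity over ≥ 300 nt are reported; cluster
pairs supported by ≥ 2 source specimens are flagged as putative
paralogs (NuMTs) rather than sporadic contamination. Barcodes from
wells marked negative are reported for manual confirmation, never
auto-removed.

## mOTUs, congruence, richness

Distances are uncorrected p-distances with pairwise deletion of sites
carrying N or a gap in either sequence; unaligned inputs are multiply
aligned first. Objective clustering is single linkage with a strict
threshold: specimens share a mOTU iff connected by a chain of distances
< t — exactly the connected components of the graph {d < t}, which
fixes the semantics in degenerate equal-distance cases. Raising t never
increases the cluster count.

The match ratio between two partitions over the same specimens is
2·N_match/(N1+N2) with N_match counting clusters identical as sets; 1
iff the partitions are identical. For clusters incongruent at a base
threshold, a grid scan (default 1–10% in 0.1% steps) reports the
smallest threshold at which both clusterings agree on the cluster's
members, or "never".

Chao1: classical S_obs + F1²/(2·F2) when doubletons exist, else the
bias-corrected S_obs + F1(F1−1)/2; the estimate never falls below
S_obs. The coefficient of variation of the abundance distribution is
reported alongside but does not gate the formula choice. Accumulation
curves subsample specimens without replacement at each size over seeded
randomizations and report mean richness, singleton, doubleton and Chao1
values. Tree-based delimitation (PTP) is supported only as an export
hook (alignment + invocation recipe for external tools).

## Re-pooling

Coverage classes use inclusive boundaries: very_low ≤ 10×,
low = (10×, 50×], ok above; any QC flag (≥ 1% ambiguity, divergence
outlier) overrides to problem regardless of coverage. Plate maps are
plain-text 8×12 grids (V/L/!/. marks, o for negative wells) for
diff-ability; every specimen falls in exactly one class.

## Validation study and problem sizes

`nanobarcoder.study.run_study` fixes the desk-scale conditions used by
the test suite and `scripts/acceptance.py`: 50 specimens (10 species ×
5; intra ≤ 1%, inter ≥ 8%), 12% total read error with a 60% indel share
(substitution 4.8%, insertion 3.6%, deletion 3.6%), homopolymer indel
multiplier 2, a 10 × 8 tag layout with 50 of 80 combinations in use, 2%
ligated dimers, 1% unused-tag reads, 0.5% cross-contamination. True
coverage is log-normal (median 150×, σ = 0.35, floor 60×) so that after
demultiplexing losses every bin retains roughly ≥ 20×. These sizes keep
a full study run around ten seconds on one CPU while leaving every
measured rate (demultiplexing accuracy, per-stage accuracy, match
ratio) statistically meaningful at the scale of tens of specimens and
thousands of reads.

Known limitations: the center-star MSA is a heuristic (adequate because
consensus only needs column-wise majorities, not a phylogenetically
optimal alignment); homopolymer consensus errors of the G₄C₃ kind can
survive polishing and correction when a majority of reads drop the same
base — the residual per-base error of consolidated barcodes
(~0.01–0.07%) is concentrated there; and the error model's independence
assumptions understate the burstiness of real pores, so real demultiplex
rates vary more across runs than the simulation suggests.
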