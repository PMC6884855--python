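# nanobarcoder

Large-scale DNA barcoding from 1D nanopore amplicon reads: tag design,
error-tolerant demultiplexing, consensus calling, amino-acid-guided error
correction, QC against reference barcodes, mOTU delimitation, species
richness estimation, and re-pooling decisions.

## The problem

Specimen-rich inventories (a single Malaise trap can yield thousands of
flies) need one DNA barcode — the 658-nt 5' fragment of mitochondrial
COI — per specimen, cheaply. Pooling thousands of tagged PCR products on
one MinION flowcell makes the sequencing cheap, but 1D nanopore reads
carry ~10–15% errors dominated by indels, especially in homopolymers.
`nanobarcoder` implements the full analysis that turns such reads into
reference-quality barcodes and species counts:

1. **Tag design** (`tags`): 13-nt tags appended to both primers; all
   pairs differ by ≥ 3 edits *of any type* (Levenshtein, not just
   Hamming), no homopolymer runs > 2 nt, no tag ending in the motif that
   starts the forward primer. Demultiplexing tolerates up to 2 tag errors
   via a precomputed index of every reachable mutant string (ambiguous
   mutants are excluded).
2. **Demultiplexing** (`demux`): length filter (≥ 600 nt), primer search
   restricted to the first/last 100 bp, 20-bp flanks compressed for
   homopolymer runs > 3 nt, tag windows looked up in the mutant index;
   both tags must resolve. Reads of 1300–2000 nt are split in two, since
   two 735-nt products occasionally ligate during library preparation.
   Reads resolving to tag pairs absent from the plate layout estimate the
   demultiplexing error rate.
3. **Consensus** (`consensus`): a draft barcode from ≤ 100 subsampled
   reads via a zero-gap-opening-cost multiple alignment and a per-column
   ≥ 50% majority rule (gap-majority columns emit nothing; a modal base
   below 50% emits N); bins under 5× coverage or with ≥ 1% N are
   rejected. Polishing re-aligns *all* bin reads to the draft, drops
   reads above 15% divergence, and re-votes.
4. **Amino-acid correction** (`correct`): COI translates without stop
   codons, so frameshifts are detectable. Each consensus is aligned to
   its best reference; insertions are deleted and deletions filled with
   N, with the repair position chosen by amino-acid identity to the
   reference over `namino` (default 2) codons per side. Barcodes with
   ≥ 5 consecutive indels are rejected; residual stops become NNN. The
   two corrected tracks are **consolidated** by strict consensus
   (conflict → N, N defers to the determined base); if their alignment
   needs gaps even at an elevated gap-opening penalty, the barcode is
   rejected.
5. **QC** (`qc`): per-base accuracy against reference (e.g. Illumina)
   barcodes on the shared 313-nt fragment, with a > 3% divergence
   exclusion rule; contamination screening against a labelled library;
   the dominant-sequence rule for calling reference barcodes from
   short-read sets; secondary-signal screening for paralogs (NuMTs).
6. **mOTUs and richness** (`motu`): objective clustering = single
   linkage on uncorrected p-distances (pairwise deletion of N/gap
   sites) at 2–4% thresholds; congruence between partitions by the match
   ratio 2·N_match/(N1+N2); Chao1 richness
   S_obs + F1²/(2·F2) (bias-corrected fallback when F2 = 0) with
   rarefied accumulation curves.
7. **Re-pooling** (`repool`): specimens at ≤ 10× / ≤ 50× coverage or
   flagged by QC are selected for re-sequencing, with plate maps showing
   the wells to re-pool.

A first-class synthetic-data generator (`simulate`) produces tagged
amplicon read sets with known ground truth — configurable error model
with homopolymer-biased indels, ligated dimers, unused-tag reads and
cross-contamination — so every stage is testable end to end without any
download.

## Worked example

```bash
nanobarcoder simulate --specimens 8 --species 4 --seed 3 --outdir sim/
nanobarcoder demux --reads sim/reads.fastq --tags sim/tags.tsv \
    --layout sim/layout.csv --outdir bins/
nanobarcoder consensus --bins bins/ --min-cov 3 --seed 1 --outdir cons/
nanobarcoder correct --draft cons/draft.fasta --polished cons/polished.fasta \
    --reference sim/templates.fasta --outdir corr/
nanobarcoder cluster --barcodes corr/consolidated.fasta --out clusters.tsv
```

which prints, in order:

```
simulated 379 reads for 8 specimens into sim
assigned 254/379 read units to 8 bins
called 6 draft / 6 polished barcodes
consolidated 6 barcodes (0 rejections)
threshold 0.020: 4 mOTUs
threshold 0.030: 4 mOTUs
threshold 0.040: 4 mOTUs
```

Reading the numbers: of 379 read units, 254 resolve both tags and land
in the 8 specimen bins — with ~12% read error a substantial fraction of
reads always loses one of its two tags, which costs coverage but not
accuracy. Six of the 8 specimens pass the ≥ 5×-coverage / < 1%-ambiguity
screens (this small run draws low-coverage wells on purpose; the two
failures are exactly the wells a re-pooling pass would re-sequence), and
clustering the consolidated barcodes at 2–4% recovers exactly the 4
simulated species at every threshold.

The same flow is available as library calls
(`nanobarcoder.pipeline.run_read_pipeline`), which is how the test suite
and the validation study drive it.

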