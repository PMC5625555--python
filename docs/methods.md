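# Methods

This note documents the processing model implemented by `cagescan`, the
parameters and their defaults, the synthetic-data model used for testing,
and the numerical conventions. All coordinates are 0-based half-open
(BED convention) unless stated otherwise.

## Processing model

### Read preparation (`cagescan.read_prep`)

Input is paired 2×36 nt FASTQ. Read 1 (the CAGE mate) begins with a 6-nt
library barcode followed by a 3-nt linker; the remaining 27 nt are the
TSS-anchored cDNA sequence. Read 2 (the CAGEscan mate) begins with the 6
random-primer bases used to prime first-strand synthesis; the remaining
30 nt are transcript sequence.

1. **Extraction.** Read 1 must start with the configured barcode (default
   `GCTATA`) followed by the linker pattern (default `NNN`, where `N`
   matches any base). Matching pairs are trimmed — 9 nt off read 1, 6 nt
   off read 2 by default — and non-matching pairs are rejected as
   **Unextracted**. Trim lengths of 0 with an empty barcode/linker are
   permitted so the stage can be configured as the identity.
2. **Artefact filter.** A trimmed mate matching any sequence in the
   artefact library (empty linkers, adapter dimers) on the forward strand,
   or consisting of ≥ 90% of a single nucleotide (low-complexity rule,
   threshold configurable), rejects the pair as **Artefacts**.
3. **rDNA filter.** A trimmed mate matching the rDNA reference on either
   strand rejects the pair as **rDNA**. Multiple rDNA FASTA records are
   joined with 50 `N`s so no spurious match can span a record boundary.

Matching is exact-substring by default, generalised to a k-mismatch
Hamming infix scan when `max_mismatches > 0` (a sliding-window Hamming
comparison; we deliberately do not use an edit-distance library because
the contaminant model here is substitution-only, and indel-tolerant
matching would change the semantics). If the two mates of a pair trigger
different filters, the **earliest-stage category wins** (Artefacts before
rDNA), so every pair is counted exactly once.

### Pair filtering (`cagescan.pair_filter`)

Clean pairs are aligned externally; the toolkit consumes the SAM/BAM.
Secondary and supplementary alignments are ignored. A pair is **proper**
when, recomputed from coordinates (the aligner's 0x2 flag is not
trusted):

* both mates map to the same reference,
* the mates are on opposite strands in head-to-head (FR) orientation —
  the leftmost-starting mate is on the + strand, ties accepted,
* the outer span (max end − min start) is ≤ 2,000,000 bp, **inclusive**.

Pairs failing these tests are **NonProper**; clean pairs absent from the
alignment or with an unmapped mate are **NonAligned**. The 2 Mbp bound is
a conservative ceiling on mammalian transcription-unit length; it is a
single tunable (`--max-span`).

### BED12 pair model and deduplication (`cagescan.bed12`)

Each proper pair becomes one BED12 record: `chrom/start/end` span the
outer coordinates, `strand` is the CAGE mate's strand, `score` is the sum
of the two MAPQs, `thickStart/thickEnd` mark the 1-bp TSS (the CAGE
mate's 5′ base: its start on +, its end−1 on −), and the blocks are the
merged union of both mates' reference-consuming CIGAR operations, split
at `N` (intron) operations. Identical-coordinate pairs — same
`(chrom, strand, chromStart, chromEnd)` — are PCR/optical duplicates: of
*n* such records exactly 1 is kept (highest score, ties broken by
lexicographically smallest name) and *n*−1 are counted as **Duplicates**.

### Clustering

Seed peaks are stranded BED6 intervals, required to be non-overlapping
per strand (overlap at load time is an error, not silently merged). Each
deduplicated pair is assigned to the seed containing its TSS on the same
strand; a **CAGEscan cluster** is one seed's member set, with score =
member count, name and thick fields from the seed, and blocks = the
interval union of member blocks. Pairs whose TSS hits no seed are emitted
separately as unassigned. When no seed set is given, de novo seeds are
called by single-linkage clustering of the pairs' TSS positions per
(chrom, strand) with a join distance (default 20 bp).

**Meta-clusters** merge per-library clusters sharing a seed; the score is
the number of distinct contributing libraries, and the blocks are the
union across libraries. Seed coordinates must agree across libraries or
the merge is refused.

### QC and annotation (`cagescan.qc`)

The ledger partitions the library exactly:

```
Total = Unextracted + Artefacts + rDNA + NonAligned
      + NonProper + Duplicates + CAGEscanPairs
```

The partition is checked before the ledger is written (as
subject/predicate/object TSV triples); a violation is a hard error, never
a warning. Start-site annotation classifies each pair's TSS against
promoter and exon interval sets with precedence Promoter > Exon > Other
(a base in both counts as Promoter); intervals with strand `.` match both
strands. Library similarity is the Jaccard index over the sets of seed
peaks detected with at least `min_pairs` members (default 1); the
similarity of two empty sets is defined as 0. Technical replicates are
identified as each library's best off-diagonal match; an average-linkage
dendrogram leaf order is also provided for display.

## Simulator (`cagescan.simulate`)

The generator emits a complete synthetic experiment: a uniform random
genome (default 200 kb, one chromosome), 20 multi-exon transcript models,
one 30-bp TSS seed peak per transcript, raw FASTQ pairs, their SAM
alignments, and independently derived ground truth (per-pair labels and
the expected clusters).

Two RNG streams are used: a **structure** stream seeded by
`(seed, 0)` draws the genome, transcript layout and seed peaks; a
**noise** stream seeded by `(noise_seed or seed, 1)` draws read sampling,
duplicates, contaminants and per-base errors. Two runs sharing `seed`
but differing in `noise_seed` are therefore technical replicates of one
RNA source — same truth, independent reads.

Each generated pair carries a label from
`{clean, duplicate-of:<id>, artefact, rdna, improper, unextracted,
nonaligned}`. Clean pairs sample a TSS uniformly within the transcript's
seed peak and a read-2 position downstream within the spliced transcript;
duplicates are coordinate copies of an earlier clean pair with fresh
MAPQs; improper pairs place both mates on the same strand; unextracted,
artefact and rDNA pairs get corrupted or contaminant sequence and do not
appear in the SAM; nonaligned pairs appear as unmapped records.

Default rates — rDNA 0.30, duplicates 0.15, unextracted 0.10,
improper 0.05, artefacts 0.02, nonaligned 0.015 — are order-of-magnitude
choices typical of nanogram-scale total-RNA CAGEscan libraries, where
rDNA is the dominant contaminant; they are configuration, not estimates,
and every one is overridable.

`truth_clusters` computes the expected clusters by an independent path
(coordinate grouping of clean pairs, brute-force seed scan, bitmap
interval union) and is exact when `per_base_error = 0`.

**What the simulator does not emulate:** sequencing quality-score
structure (all bases get one fixed quality), indels, soft-clipping,
multi-mapping and mapping-quality variation tied to repeats, strand-
invasion artefacts, gene-expression distributions (transcript sampling is
uniform-ish per transcript, not a realistic expression law), and the
aligner itself — alignments are written from the truth, with per-base
error applied to the read sequences only. Consequently, at
`per_base_error > 0` the exact-substring artefact/rDNA filters are
partially evaded: an rDNA read with an error no longer matches the rDNA
reference and, being absent from the SAM, is counted **NonAligned**. The
ledger still partitions exactly; only the category attribution shifts, as
it would with a real aligner and stricter/looser filters.

## Numerical and format conventions

* **Inclusive span bound:** a pair with outer span exactly 2,000,000 is
  proper.
* **Score clamping:** BED scores are clamped to 1000 on strict output
  (`--strict-bed`, default) for browser compatibility; `--no-strict-bed`
  writes raw values (MAPQ sums and large member counts can exceed 1000).
  Clamping affects the written file only, never internal comparisons.
* **Tie-breaks** are always lexicographic on the record name, making
  every output a pure function of its input set (no dict-order or
  arrival-order dependence). Outputs are sorted by
  `(chrom, start, end, name)`.
* **Round-trips are bit-exact:** BED6/BED12 readers and writers are
  hand-rolled so that `read(write(x)) == x` field-for-field, including
  blockCount consistency checks on read.
* **Checksums:** the run manifest records SHA-256 of every input and
  output, so identical configs are verifiably identical runs.

## Problem sizes used in the test suite

The package's own verification (tests and `scripts/acceptance.py`) uses
synthetic libraries of 200–5,000 pairs. Rate-recovery checks use 5,000
pairs (100 transcripts × 50 pairs) with a 3-binomial-SD tolerance; at
that size, coincidental coordinate collisions among independent clean
pairs (~2 expected) are negligible against the tolerance (~97 pairs).
Replicate-identification checks use 5% per-base error, at which
within-source Jaccard similarity remains far above cross-source
similarity. These sizes were chosen for statistical resolution at
interactive runtimes, not tuned to any particular outcome.

## Limitations

* The toolkit consumes alignments; it does not wrap an aligner, and its
  accounting is only as good as the upstream mapping.
* Contaminant filtering is substitution-only (Hamming); indel-containing
  contaminant reads pass through to the aligner.
* The duplicate definition is purely coordinate-based; without unique
  molecular identifiers, genuinely independent molecules with identical
  coordinates are removed as duplicates (rare at these depths, common at
  very high depth on sharp TSSs).
* Single-linkage de novo seeding can chain nearby TSSs into one seed in
  dense promoter regions; curated seed sets are preferred when available.
* The simulator is a verification instrument, not a realism benchmark;
  conclusions about real libraries should come from real libraries.
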