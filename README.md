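# cagescan

A processing toolkit for **CAGEscan** libraries: paired-end 5′-CAGE
sequencing in which read 1 captures a capped transcript's 5′ end (the
transcription start site, TSS) and read 2 a random-primed position further
down the same cDNA. Because the two mates come from one molecule, a proper
pair is direct experimental evidence linking a promoter to the transcript
body it drives — the tool of choice for connecting "gene-orphan" promoter
regions, which CAGE atlases detect in large numbers, to their cognate
transcriptional units.

The package takes raw barcoded FASTQ pairs and their genome alignments
(SAM/BAM) and produces:

* **cleaned pairs** — barcode/linker verification and trimming, artefact
  and rDNA contaminant filtering, with per-stage rejection accounting;
* **CAGEscan pairs** — one BED12 record per proper pair (mates head-to-head
  on one reference within 2 Mbp), with score = MAPQ₁ + MAPQ₂ and the 1-bp
  TSS in the thick fields, deduplicated by coordinate identity (of *n*
  identical pairs, 1 is kept and *n*−1 are discarded as duplicates);
* **CAGEscan clusters** — BED12 transcript models collating all pairs whose
  TSS falls in one seed peak (a promoter-region interval such as a FANTOM5
  DPI peak, or seeds called de novo from the pairs' own 5′ ends); score =
  member pair count, blocks = union of member blocks;
* **meta-clusters** — per-seed merges across libraries, score = number of
  contributing libraries;
* **QC** — a ledger of (subject, predicate, object) triples partitioning
  every input pair into `Unextracted / Artefacts / rDNA / NonAligned /
  NonProper / Duplicates / CAGEscanPairs`; Promoter/Exon/Other fractions of
  pair start sites; and an inter-library Jaccard similarity matrix over
  detected seed peaks, which identifies technical replicates as nearest
  neighbours.

A first-class synthetic experiment generator (`cagescan simulate`) emits a
random genome, transcript models, seed peaks, FASTQ reads, SAM alignments
and the exact ground-truth clusters, so the whole pipeline is testable
without any external data. See `docs/methods.md` for the model, parameter
and design details.

## Worked example

Simulate a small library and run the pipeline end to end:

```sh
cagescan simulate --seed 1 --out-dir fx
cat > run.yaml <<EOF
library_id: demo
r1: fx/r1.fq
r2: fx/r2.fq
sam: fx/aln.sam
artefacts: fx/artefacts.fa
rdna: fx/rdna.fa
seeds: fx/truth/seeds.bed
out_dir: out
EOF
cagescan run --config run.yaml
```

which prints the QC ledger:

```
demo	Total	200
demo	Unextracted	21
demo	Artefacts	9
demo	rDNA	70
demo	NonAligned	3
demo	NonProper	7
demo	Duplicates	21
demo	CAGEscanPairs	69
```

Of 200 raw read pairs, 69 survive every filter; the seven categories sum
exactly to the total (this partition is enforced before anything is
written). The rDNA fraction dominates the losses, as is typical of
total-RNA libraries. `out/clusters.bed12` holds the assembled models, e.g.

```
chr1	1009	1728	peak_tx000@chr1:1698-1728-	7	-	1698	1728	0	7	36,30,30,30,30,30,54	0,44,97,266,569,632,665
```

a minus-strand cluster assembled from 7 deduplicated pairs (score column),
named after its seed peak, whose position is carried in the thick fields;
the 7 blocks are the union of the member pairs' aligned segments. Each
stage is also available as its own subcommand (`cagescan prep`,
`pairfilter`, `dedup`, `cluster`, `metacluster`, `annotate`, `jaccard`,
`qcstats`) on the previous stage's files.

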