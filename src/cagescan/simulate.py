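"""Self-contained synthetic CAGEscan experiments with ground truth.

The generator emulates the structure of a nanoCAGE paired-end library at
desk scale: a random genome with multi-exon transcripts, a promoter-region
seed peak at each transcript 5' end, and read pairs whose first mate starts
at a TSS drawn inside the peak (prefixed by barcode + linker) while the
second mate samples a random downstream position of the transcript
(prefixed by 6 random-primer bases), reverse-complemented per the inward FR
geometry. Reads are placed within single exons, mirroring an alignment
strategy that is not splice-aware; pairs whose two mates land in different
exons leave the intron as the gap between their BED12 blocks, which is the
method's point.

Contaminants and failure modes are injected at configured rates, one label
per pair: pairs without the barcode (``unextracted``), pairs matching the
artefact library (``artefact``), pairs from a distinct synthetic rDNA
contig (``rdna``), pairs that do not align (``nonaligned``), same-strand
alignments (``improper``) and exact coordinate copies of earlier clean
pairs (``duplicate-of:<id>``). Default rates are of the order seen in real
total-RNA nanoCAGE libraries, where the ribosomal repeat dominates the
losses.

Two random streams are kept separate: the *structure* stream (``seed``)
fixes the genome, transcripts and seed peaks, while the *noise* stream
(``noise_seed``, defaulting to the structure seed) drives read sampling,
contamination and sequencing errors. Two simulations sharing ``seed`` but
not ``noise_seed`` are technical replicates of the same truth.

``truth_clusters`` recomputes the expected cluster set from the truth
labels alone, with its own base-resolution bitmap union — deliberately
independent of the pipeline's interval arithmetic — and is exact whenever
``per_base_error`` is zero.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .bed12 import Bed12Record, SeedPeak, write_bed6, write_bed12
from .read_prep import reverse_complement

RDNA_CONTIG = "rDNA_synthetic"
_QUAL = "I"


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one synthetic library.

    Read geometry defaults to 2 x 36 nt with a 9-nt (barcode + linker) trim
    on read 1 and a 6-nt random-primer trim on read 2. Rates are per-pair
    probabilities and must leave room for clean pairs.
    """

    seed: int = 0
    noise_seed: int | None = None
    genome_length: int = 200_000
    n_transcripts: int = 20
    exons_per_transcript: tuple[int, int] = (1, 3)
    exon_length: tuple[int, int] = (300, 800)
    intron_length: tuple[int, int] = (100, 1500)
    tss_peak_width: int = 30
    pairs_per_transcript: tuple[int, int] = (5, 15)
    r1_len: int = 36
    r2_len: int = 36
    r1_trim: int = 9
    r2_trim: int = 6
    barcode: str = "GCTATA"
    duplicate_rate: float = 0.15
    artefact_rate: float = 0.02
    rdna_rate: float = 0.30
    improper_rate: float = 0.05
    unextracted_rate: float = 0.10
    nonaligned_rate: float = 0.015
    per_base_error: float = 0.0
    rdna_length: int = 2_000
    library_id: str = "sim"

    def validate(self) -> None:
        rates = (
            self.duplicate_rate,
            self.artefact_rate,
            self.rdna_rate,
            self.improper_rate,
            self.unextracted_rate,
            self.nonaligned_rate,
        )
        if any(not 0.0 <= r <= 1.0 for r in rates) or not 0.0 <= self.per_base_error <= 1.0:
            raise SimulationError("rates must lie in [0, 1]")
        if sum(rates) >= 1.0:
            raise SimulationError("contamination rates must sum to < 1")
        r1_payload = self.r1_len - self.r1_trim
        r2_payload = self.r2_len - self.r2_trim
        if r1_payload <= 0 or r2_payload <= 0:
            raise SimulationError("reads must be longer than their trims")
        if self.exon_length[0] < self.tss_peak_width + r1_payload:
            raise SimulationError("first/last exon too short for peak + read placement")
        if self.exon_length[0] < r2_payload:
            raise SimulationError("exons too short for read 2 placement")
        if self.genome_length < 5_000:
            raise SimulationError("genome_length too small")

    @property
    def r1_payload(self) -> int:
        return self.r1_len - self.r1_trim

    @property
    def r2_payload(self) -> int:
        return self.r2_len - self.r2_trim


@dataclass
class TruthSet:
    """Ground truth of one simulated library."""

    transcripts: list[Bed12Record]
    seeds: list[SeedPeak]
    labels: dict[str, str]  # read_id -> label
    pairs: dict[str, Bed12Record]  # read_id -> truth pair model (clean/duplicate)


@dataclass
class SamRecordSpec:
    """One SAM line of the simulated alignment, stored structurally."""

    qname: str
    flag: int
    ref: str | None
    pos: int  # 0-based; -1 when unmapped
    mapq: int
    cigar: str | None
    mate_pos: int
    seq: str


@dataclass
class SimResult:
    cfg: SimConfig
    genome: dict[str, str]
    artefact_refs: dict[str, str]
    r1: list[tuple[str, str, str]]  # (read_id, seq, qual)
    r2: list[tuple[str, str, str]]
    sam_records: list[SamRecordSpec]
    truth: TruthSet


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0.0:
        return seq
    bases = "ACGT"
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        alternatives = bases.replace(out[i], "") or bases
        out[i] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(out)


def _truth_pair_record(
    read_id: str,
    chrom: str,
    strand: str,
    cage_iv: tuple[int, int],
    scan_iv: tuple[int, int],
    mapq1: int,
    mapq2: int,
) -> Bed12Record:
    # block union written out longhand (two intervals only) so the truth
    # stays independent of the pipeline's interval code
    a, b = sorted([cage_iv, scan_iv])
    if b[0] <= a[1]:
        blocks: tuple = ((a[0], max(a[1], b[1])),)
    else:
        blocks = (a, b)
    tss = cage_iv[0] if strand == "+" else cage_iv[1] - 1
    return Bed12Record(
        chrom=chrom,
        start=blocks[0][0],
        end=blocks[-1][1],
        name=read_id,
        score=mapq1 + mapq2,
        strand=strand,
        thick_start=tss,
        thick_end=tss + 1,
        blocks=blocks,
    )


def _place_transcripts(cfg: SimConfig, rng: np.random.Generator):
    """Lay out non-overlapping multi-exon transcripts along the chromosome."""
    transcripts = []  # (name, strand, exons)
    cursor = 1_000
    for i in range(cfg.n_transcripts):
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.integers(cfg.exons_per_transcript[0], cfg.exons_per_transcript[1] + 1))
        exons = []
        pos = cursor
        for j in range(k):
            length = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
            exons.append((pos, pos + length))
            pos += length
            if j < k - 1:
                pos += int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
        cursor = pos + int(rng.integers(200, 1_001))
        if cursor > cfg.genome_length - 1_000:
            raise SimulationError(
                f"genome_length {cfg.genome_length} too small for {cfg.n_transcripts} transcripts"
            )
        transcripts.append((f"tx{i:03d}", strand, exons))
    return transcripts


def simulate(cfg: SimConfig) -> SimResult:
    """Generate one library: genome, reads, alignments, and truth."""
    cfg.validate()
    s_rng = np.random.default_rng([cfg.seed, 0])
    n_rng = np.random.default_rng([cfg.noise_seed if cfg.noise_seed is not None else cfg.seed, 1])

    chrom = "chr1"
    genome = {
        chrom: _random_seq(s_rng, cfg.genome_length),
        RDNA_CONTIG: _random_seq(s_rng, cfg.rdna_length),
    }
    artefact_refs = {
        "empty_construct": _random_seq(s_rng, 60),
        "primer_fw": _random_seq(s_rng, 40),
        "primer_rv": _random_seq(s_rng, 40),
    }

    layout = _place_transcripts(cfg, s_rng)
    transcripts: list[Bed12Record] = []
    seeds: list[SeedPeak] = []
    for name, strand, exons in layout:
        tx_start, tx_end = exons[0][0], exons[-1][1]
        if strand == "+":
            p_start, p_end = tx_start, tx_start + cfg.tss_peak_width
            tss = tx_start
        else:
            p_start, p_end = tx_end - cfg.tss_peak_width, tx_end
            tss = tx_end - 1
        # seed names carry their locus so that seed universes from different
        # simulations never collide by name
        peak = SeedPeak(
            chrom, p_start, p_end, f"peak_{name}@{chrom}:{p_start}-{p_end}{strand}", strand
        )
        seeds.append(peak)
        transcripts.append(
            Bed12Record(
                chrom=chrom,
                start=tx_start,
                end=tx_end,
                name=name,
                score=0,
                strand=strand,
                thick_start=tss,
                thick_end=tss + 1,
                blocks=tuple(exons),
            )
        )

    labels: dict[str, str] = {}
    truth_pairs: dict[str, Bed12Record] = {}
    r1_reads: list[tuple[str, str, str]] = []
    r2_reads: list[tuple[str, str, str]] = []
    sam_records: list[SamRecordSpec] = []
    clean_ids: list[str] = []

    mapq_choices = np.array([0, 20, 30, 37])
    linker_len = cfg.r1_trim - len(cfg.barcode)
    rates = np.array(
        [
            cfg.unextracted_rate,
            cfg.artefact_rate,
            cfg.rdna_rate,
            cfg.nonaligned_rate,
            cfg.improper_rate,
            cfg.duplicate_rate,
        ]
    )
    categories = ["unextracted", "artefact", "rdna", "nonaligned", "improper", "duplicate"]

    serial = 0

    def emit_fastq(read_id: str, seq1: str, seq2: str) -> None:
        seq1 = _mutate(seq1, n_rng, cfg.per_base_error)
        seq2 = _mutate(seq2, n_rng, cfg.per_base_error)
        r1_reads.append((read_id, seq1, _QUAL * len(seq1)))
        r2_reads.append((read_id, seq2, _QUAL * len(seq2)))

    def emit_mapped_pair(
        read_id: str,
        cage_iv: tuple[int, int],
        cage_strand: str,
        scan_iv: tuple[int, int],
        scan_strand: str,
        mapq1: int,
        mapq2: int,
        proper: bool,
    ) -> None:
        flag1 = 0x1 | 0x40
        flag2 = 0x1 | 0x80
        if proper:
            flag1 |= 0x2
            flag2 |= 0x2
        if cage_strand == "-":
            flag1 |= 0x10
            flag2 |= 0x20
        if scan_strand == "-":
            flag2 |= 0x10
            flag1 |= 0x20
        sam_records.append(
            SamRecordSpec(
                read_id, flag1, chrom, cage_iv[0], mapq1, f"{cage_iv[1]-cage_iv[0]}M",
                scan_iv[0], genome[chrom][cage_iv[0] : cage_iv[1]],
            )
        )
        sam_records.append(
            SamRecordSpec(
                read_id, flag2, chrom, scan_iv[0], mapq2, f"{scan_iv[1]-scan_iv[0]}M",
                cage_iv[0], genome[chrom][scan_iv[0] : scan_iv[1]],
            )
        )

    def sample_clean_geometry(strand: str, exons, rng) -> tuple[tuple[int, int], tuple[int, int]]:
        """Mate intervals for one clean pair: CAGE mate at a TSS inside the
        seed peak; downstream mate within one exon, inward-facing."""
        tx_start, tx_end = exons[0][0], exons[-1][1]
        if strand == "+":
            tss = int(rng.integers(tx_start, tx_start + cfg.tss_peak_width))
            cage_iv = (tss, tss + cfg.r1_payload)
            for _ in range(50):
                ex = exons[int(rng.integers(0, len(exons)))]
                lo = max(ex[0], tss)
                hi = ex[1] - cfg.r2_payload
                if hi >= lo:
                    p = int(rng.integers(lo, hi + 1))
                    return cage_iv, (p, p + cfg.r2_payload)
        else:
            tss = int(rng.integers(tx_end - cfg.tss_peak_width, tx_end))
            cage_iv = (tss - cfg.r1_payload + 1, tss + 1)
            for _ in range(50):
                ex = exons[int(rng.integers(0, len(exons)))]
                lo = ex[0]
                hi = min(ex[1] - cfg.r2_payload, cage_iv[0])
                if hi >= lo:
                    p = int(rng.integers(lo, hi + 1))
                    return cage_iv, (p, p + cfg.r2_payload)
        raise SimulationError("could not place a read pair inside the transcript")

    for name, strand, exons in layout:
        n_pairs = int(
            n_rng.integers(cfg.pairs_per_transcript[0], cfg.pairs_per_transcript[1] + 1)
        )
        for _ in range(n_pairs):
            read_id = f"{cfg.library_id}.read{serial:06d}"
            serial += 1
            u = n_rng.random()
            cum = np.cumsum(rates)
            idx = int(np.searchsorted(cum, u, side="right"))
            label = categories[idx] if idx < len(categories) else "clean"
            if label == "duplicate" and not clean_ids:
                label = "clean"

            if label == "unextracted":
                bad = "T" if cfg.barcode[0] != "T" else "A"
                seq1 = (
                    bad
                    + cfg.barcode[1:]
                    + _random_seq(n_rng, linker_len)
                    + _random_seq(n_rng, cfg.r1_payload)
                )
                seq2 = _random_seq(n_rng, cfg.r2_len)
                emit_fastq(read_id, seq1, seq2)
                labels[read_id] = "unextracted"
                continue

            prefix1 = cfg.barcode + _random_seq(n_rng, linker_len)
            primer2 = _random_seq(n_rng, cfg.r2_trim)

            if label == "artefact":
                ref = artefact_refs["empty_construct"]
                off = int(n_rng.integers(0, len(ref) - cfg.r2_payload + 1))
                seq1 = prefix1 + _random_seq(n_rng, cfg.r1_payload)
                seq2 = primer2 + ref[off : off + cfg.r2_payload]
                emit_fastq(read_id, seq1, seq2)
                labels[read_id] = "artefact"
                continue

            if label == "rdna":
                rd = genome[RDNA_CONTIG]
                off1 = int(n_rng.integers(0, len(rd) - cfg.r1_payload + 1))
                off2 = int(n_rng.integers(0, len(rd) - cfg.r2_payload + 1))
                seq1 = prefix1 + rd[off1 : off1 + cfg.r1_payload]
                seq2 = primer2 + reverse_complement(rd[off2 : off2 + cfg.r2_payload])
                emit_fastq(read_id, seq1, seq2)
                labels[read_id] = "rdna"
                continue

            if label == "nonaligned":
                seq1 = prefix1 + _random_seq(n_rng, cfg.r1_payload)
                seq2 = primer2 + _random_seq(n_rng, cfg.r2_payload)
                emit_fastq(read_id, seq1, seq2)
                labels[read_id] = "nonaligned"
                sam_records.append(
                    SamRecordSpec(read_id, 0x1 | 0x4 | 0x8 | 0x40, None, -1, 0, None, -1,
                                  seq1[cfg.r1_trim :])
                )
                sam_records.append(
                    SamRecordSpec(read_id, 0x1 | 0x4 | 0x8 | 0x80, None, -1, 0, None, -1,
                                  seq2[cfg.r2_trim :])
                )
                continue

            if label == "improper":
                # both mates on the forward strand: never head-to-head
                a = int(n_rng.integers(0, cfg.genome_length - 2_000))
                b = a + int(n_rng.integers(100, 1_000))
                cage_iv = (a, a + cfg.r1_payload)
                scan_iv = (b, b + cfg.r2_payload)
                seq1 = prefix1 + genome[chrom][cage_iv[0] : cage_iv[1]]
                seq2 = primer2 + genome[chrom][scan_iv[0] : scan_iv[1]]
                emit_fastq(read_id, seq1, seq2)
                labels[read_id] = "improper"
                mapq1, mapq2 = (int(mapq_choices[n_rng.integers(0, 4)]) for _ in range(2))
                emit_mapped_pair(read_id, cage_iv, "+", scan_iv, "+", mapq1, mapq2, proper=False)
                continue

            if label == "duplicate":
                original_id = clean_ids[int(n_rng.integers(0, len(clean_ids)))]
                original = truth_pairs[original_id]
                # same coordinates, fresh identity and mapping qualities
                mapq1, mapq2 = (int(mapq_choices[n_rng.integers(0, 4)]) for _ in range(2))
                tss = original.thick_start
                if original.strand == "+":
                    cage_iv = (tss, tss + cfg.r1_payload)
                    scan_iv = (original.end - cfg.r2_payload, original.end)
                    cage_strand, scan_strand = "+", "-"
                else:
                    cage_iv = (tss - cfg.r1_payload + 1, tss + 1)
                    scan_iv = (original.start, original.start + cfg.r2_payload)
                    cage_strand, scan_strand = "-", "+"
                labels[read_id] = f"duplicate-of:{original_id}"
            else:  # clean
                tx_strand = strand
                cage_strand = tx_strand
                scan_strand = "-" if tx_strand == "+" else "+"
                cage_iv, scan_iv = sample_clean_geometry(tx_strand, exons, n_rng)
                mapq1, mapq2 = (int(mapq_choices[n_rng.integers(0, 4)]) for _ in range(2))
                labels[read_id] = "clean"
                clean_ids.append(read_id)

            # FASTQ sequences follow read orientation: a reverse-strand
            # alignment was sequenced as the reverse complement of the
            # forward genome slice
            cage_slice = genome[chrom][cage_iv[0] : cage_iv[1]]
            scan_slice = genome[chrom][scan_iv[0] : scan_iv[1]]
            seq1 = prefix1 + (cage_slice if cage_strand == "+" else reverse_complement(cage_slice))
            seq2 = primer2 + (scan_slice if scan_strand == "+" else reverse_complement(scan_slice))
            emit_fastq(read_id, seq1, seq2)
            emit_mapped_pair(read_id, cage_iv, cage_strand, scan_iv, scan_strand,
                             mapq1, mapq2, proper=True)
            truth_pairs[read_id] = _truth_pair_record(
                read_id, chrom, cage_strand, cage_iv, scan_iv, mapq1, mapq2
            )

    truth = TruthSet(transcripts=transcripts, seeds=seeds, labels=labels, pairs=truth_pairs)
    return SimResult(
        cfg=cfg,
        genome=genome,
        artefact_refs=artefact_refs,
        r1=r1_reads,
        r2=r2_reads,
        sam_records=sam_records,
        truth=truth,
    )


def truth_clusters(truth: TruthSet) -> list[Bed12Record]:
    """Expected clusters from the truth labels, via an independent
    base-resolution bitmap union.

    Clean pairs are grouped by outer-coordinate identity (the pipeline's
    duplicate key), each group assigned to the seed containing its TSS by a
    brute-force scan, and the member blocks painted onto a bitmap whose
    runs become the cluster blocks. Exact for error-free simulations.
    """
    groups: dict[tuple, Bed12Record] = {}
    for read_id, rec in truth.pairs.items():
        if truth.labels[read_id] != "clean":
            continue
        groups.setdefault((rec.chrom, rec.strand, rec.start, rec.end), rec)

    per_seed: dict[str, list[Bed12Record]] = {}
    for rec in groups.values():
        for seed in truth.seeds:
            if (
                seed.chrom == rec.chrom
                and seed.strand == rec.strand
                and seed.start <= rec.thick_start < seed.end
            ):
                per_seed.setdefault(seed.name, []).append(rec)
                break

    clusters = []
    seed_by_name = {s.name: s for s in truth.seeds}
    for name, members in per_seed.items():
        seed = seed_by_name[name]
        lo = min(b[0] for m in members for b in m.blocks)
        hi = max(b[1] for m in members for b in m.blocks)
        bitmap = np.zeros(hi - lo, dtype=bool)
        for m in members:
            for s, e in m.blocks:
                bitmap[s - lo : e - lo] = True
        edges = np.flatnonzero(np.diff(np.concatenate(([0], bitmap.view(np.int8), [0]))))
        blocks = tuple(
            (int(edges[i]) + lo, int(edges[i + 1]) + lo) for i in range(0, len(edges), 2)
        )
        clusters.append(
            Bed12Record(
                chrom=seed.chrom,
                start=blocks[0][0],
                end=blocks[-1][1],
                name=name,
                score=len(members),
                strand=seed.strand,
                thick_start=seed.start,
                thick_end=seed.end,
                blocks=blocks,
            )
        )
    clusters.sort(key=lambda c: (c.chrom, c.start, c.end, c.name))
    return clusters


# ---------------------------------------------------------------------------
# Fixture writing


def write_fixture(sim: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the simulated experiment to disk.

    Emits genome.fa (including the synthetic rDNA contig), rdna.fa,
    artefacts.fa, r1.fq, r2.fq, aln.sam and the truth/ directory
    (transcripts.bed12, seeds.bed, labels.tsv, clusters.bed12). Returns the
    paths by role.
    """
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "rdna": out / "rdna.fa",
        "artefacts": out / "artefacts.fa",
        "r1": out / "r1.fq",
        "r2": out / "r2.fq",
        "sam": out / "aln.sam",
        "transcripts": out / "truth" / "transcripts.bed12",
        "seeds": out / "truth" / "seeds.bed",
        "labels": out / "truth" / "labels.tsv",
        "clusters": out / "truth" / "clusters.bed12",
        "config": out / "sim_config.tsv",
    }

    def write_fasta(path: Path, records: dict[str, str]) -> None:
        with open(path, "w") as fh:
            for name, seq in records.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    write_fasta(paths["genome"], sim.genome)
    write_fasta(paths["rdna"], {RDNA_CONTIG: sim.genome[RDNA_CONTIG]})
    write_fasta(paths["artefacts"], sim.artefact_refs)

    with open(paths["r1"], "w") as fh1, open(paths["r2"], "w") as fh2:
        for (rid, s1, q1), (_, s2, q2) in zip(sim.r1, sim.r2):
            fh1.write(f"@{rid}\n{s1}\n+\n{q1}\n")
            fh2.write(f"@{rid}\n{s2}\n+\n{q2}\n")

    chrom = "chr1"
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": chrom, "LN": sim.cfg.genome_length}],
    }
    with pysam.AlignmentFile(str(paths["sam"]), "w", header=header) as sam:
        for spec in sim.sam_records:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = spec.qname
            rec.flag = spec.flag
            rec.mapping_quality = spec.mapq
            rec.query_sequence = spec.seq
            rec.query_qualities = pysam.qualitystring_to_array(_QUAL * len(spec.seq))
            if spec.ref is not None:
                rec.reference_id = sam.header.get_tid(spec.ref)
                rec.reference_start = spec.pos
                rec.cigarstring = spec.cigar
                rec.next_reference_id = rec.reference_id
                rec.next_reference_start = spec.mate_pos
            else:
                rec.reference_id = -1
                rec.reference_start = -1
                rec.next_reference_id = -1
                rec.next_reference_start = -1
            sam.write(rec)

    with open(paths["transcripts"], "w") as fh:
        write_bed12(sim.truth.transcripts, fh)
    with open(paths["seeds"], "w") as fh:
        write_bed6(sim.truth.seeds, fh)
    with open(paths["labels"], "w") as fh:
        for rid in sorted(sim.truth.labels):
            fh.write(f"{rid}\t{sim.truth.labels[rid]}\n")
    with open(paths["clusters"], "w") as fh:
        write_bed12(truth_clusters(sim.truth), fh)
    with open(paths["config"], "w") as fh:
        for f in dataclasses.fields(sim.cfg):
            fh.write(f"{f.name}\t{getattr(sim.cfg, f.name)}\n")
    return paths
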