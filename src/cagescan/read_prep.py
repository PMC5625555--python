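"""Demultiplexing, trimming and contaminant filtering of raw CAGEscan read pairs.

A CAGEscan library is sequenced paired-end: read 1 (the CAGE read) starts with
a 6-nt sample barcode followed by the template-switching linker, then the 5'
end of a capped transcript; read 2 (the CAGEscan read) starts with 6 bases
contributed by the random primer, then downstream transcript sequence.

Cleanup proceeds in three stages, each with its own rejection category:

* ``Unextracted`` — the barcode/linker prefix was not found on read 1 (or a
  read is shorter than its trim length).
* ``Artefacts`` — either mate matches the artefact library (empty constructs,
  primers) or is low-complexity.
* ``rDNA`` — either mate matches the ribosomal DNA repeat, on either strand.

A pair is dropped as soon as either mate fails a filter; when the two mates
fail different filters, the pair is counted once under the earliest stage
(Artefacts before rDNA). Every input pair therefore lands in exactly one of
the three rejection categories or survives, which downstream accounting
relies on.

Sequence matching is deliberately simple: exact substring containment, or a
Hamming scan allowing ``max_mismatches`` mismatches, of the shorter sequence
against the longer. Base qualities are carried through the trims but never
used to filter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

VALID_BASES = frozenset("ACGTN")

#: Closed set of rejection categories, in pipeline order.
PREP_STAGES = ("Unextracted", "Artefacts", "rDNA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigError(ValueError):
    """Raised for an invalid or incomplete preparation configuration."""


@dataclass(frozen=True)
class RawReadPair:
    """One raw FASTQ record pair (read 1 = CAGE, read 2 = CAGEscan)."""

    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")
        for seq in (self.seq1, self.seq2):
            if not set(seq) <= VALID_BASES:
                bad = sorted(set(seq) - VALID_BASES)
                raise ValueError(f"{self.read_id}: non-IUPAC characters {bad}")


@dataclass(frozen=True)
class CleanReadPair:
    """A pair with the barcode/linker and random-primer prefixes removed."""

    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass(frozen=True)
class RejectionRecord:
    read_id: str
    stage: str
    cause: str = ""

    def __post_init__(self) -> None:
        if self.stage not in PREP_STAGES:
            raise ValueError(f"unknown rejection stage {self.stage!r}")


@dataclass
class PrepConfig:
    """Parameters of the cleanup.

    ``linker`` is a pattern over {A,C,G,T,N} where N matches any base; the
    default of three wildcards reflects a 9-nt prefix made of the 6-nt
    barcode plus a 3-nt linker whose sequence varies with the template
    switching oligonucleotide batch. ``artefact_refs`` maps names to
    sequences; ``rdna_ref`` is the ribosomal repeat stand-in. A read matches
    a reference when one is a substring of the other, allowing up to
    ``max_mismatches`` mismatches.
    """

    barcode: str = "GCTATA"
    linker: str = "NNN"
    r1_trim: int = 9
    r2_trim: int = 6
    artefact_refs: dict[str, str] = field(default_factory=dict)
    rdna_ref: str | None = None
    max_mismatches: int = 0
    low_complexity_threshold: float = 0.9

    def validate(self) -> None:
        if self.r1_trim < len(self.barcode):
            raise ConfigError("r1_trim must cover at least the barcode")
        if len(self.barcode) + len(self.linker) != self.r1_trim:
            raise ConfigError("barcode + linker lengths must equal r1_trim")
        # zero trims (with an empty barcode/linker) are allowed so that the
        # prep is a no-op on already-trimmed reads
        if self.r1_trim < 0 or self.r2_trim < 0:
            raise ConfigError("trim lengths must be non-negative")
        if not 0.0 < self.low_complexity_threshold <= 1.0:
            raise ConfigError("low_complexity_threshold must be in (0, 1]")
        if self.max_mismatches < 0:
            raise ConfigError("max_mismatches must be >= 0")


def _pattern_matches(pattern: str, seq: str, max_mismatches: int) -> bool:
    """Match a fixed-position pattern (N = wildcard) with <= k mismatches."""
    if len(seq) < len(pattern):
        return False
    mm = 0
    for p, s in zip(pattern, seq):
        if p != "N" and p != s:
            mm += 1
            if mm > max_mismatches:
                return False
    return True


def hamming_infix_match(query: str, reference: str, max_mismatches: int) -> bool:
    """True if the shorter of the two sequences occurs in the longer one
    with at most ``max_mismatches`` mismatches (no indels)."""
    short, long_ = (query, reference) if len(query) <= len(reference) else (reference, query)
    if not short:
        return False
    if max_mismatches == 0:
        return short in long_
    n, m = len(short), len(long_)
    for off in range(m - n + 1):
        mm = 0
        for a, b in zip(short, long_[off : off + n]):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            return True
    return False


def mononucleotide_fraction(seq: str) -> float:
    """Fraction of the read occupied by its most frequent base (0 if empty)."""
    if not seq:
        return 0.0
    return max(seq.count(b) for b in "ACGTN") / len(seq)


def extract_and_trim(pair: RawReadPair, cfg: PrepConfig) -> Union[CleanReadPair, RejectionRecord]:
    """Verify the barcode+linker prefix of read 1 and trim both mates.

    Read 1 loses its first ``r1_trim`` bases (barcode + linker), read 2 its
    first ``r2_trim`` bases (random-primer contribution). A pair whose
    prefix does not match, or whose reads are shorter than the trim lengths,
    is rejected as Unextracted — never silently truncated.
    """
    cfg.validate()
    if len(pair.seq1) < cfg.r1_trim or len(pair.seq2) < cfg.r2_trim:
        return RejectionRecord(pair.read_id, "Unextracted", "read shorter than trim length")
    prefix = cfg.barcode + cfg.linker
    if not _pattern_matches(prefix, pair.seq1, cfg.max_mismatches):
        return RejectionRecord(pair.read_id, "Unextracted", "barcode/linker not found")
    return CleanReadPair(
        read_id=pair.read_id,
        seq1=pair.seq1[cfg.r1_trim :],
        qual1=pair.qual1[cfg.r1_trim :],
        seq2=pair.seq2[cfg.r2_trim :],
        qual2=pair.qual2[cfg.r2_trim :],
    )


def artefact_hit(seq: str, cfg: PrepConfig) -> bool:
    """Single-mate artefact verdict: library match (forward strand) or
    low complexity."""
    if mononucleotide_fraction(seq) >= cfg.low_complexity_threshold:
        return True
    return any(
        hamming_infix_match(seq, ref, cfg.max_mismatches) for ref in cfg.artefact_refs.values()
    )


def rdna_hit(seq: str, cfg: PrepConfig) -> bool:
    """Single-mate rDNA verdict; both strands are checked since total-RNA
    contamination reads come from either strand of the repeat."""
    assert cfg.rdna_ref is not None
    return hamming_infix_match(seq, cfg.rdna_ref, cfg.max_mismatches) or hamming_infix_match(
        reverse_complement(seq), cfg.rdna_ref, cfg.max_mismatches
    )


def filter_artefacts(pair: CleanReadPair, cfg: PrepConfig) -> RejectionRecord | None:
    """Reject the pair if either mate matches the artefact library or is
    low-complexity; return None if it passes."""
    if not cfg.artefact_refs:
        raise ConfigError("artefact library is empty")
    for mate, seq in (("1", pair.seq1), ("2", pair.seq2)):
        if artefact_hit(seq, cfg):
            return RejectionRecord(pair.read_id, "Artefacts", f"mate {mate}")
    return None


def filter_rdna(pair: CleanReadPair, cfg: PrepConfig) -> RejectionRecord | None:
    """Reject the pair if either mate matches the rDNA reference (either
    strand); return None if it passes."""
    if cfg.rdna_ref is None:
        raise ConfigError("rDNA reference missing")
    for mate, seq in (("1", pair.seq1), ("2", pair.seq2)):
        if rdna_hit(seq, cfg):
            return RejectionRecord(pair.read_id, "rDNA", f"mate {mate}")
    return None


@dataclass(frozen=True)
class MateVerdict:
    """Per-mate filter outcome used to derive the pair-level decision."""

    read_id: str
    mate: int  # 1 or 2
    artefact: bool
    rdna: bool


def enforce_mate_consistency(verdicts: Iterable[MateVerdict]) -> dict[str, str | None]:
    """Combine per-mate verdicts into one decision per pair.

    A pair survives only if both mates pass both filters; otherwise it is
    recorded once, under the earliest stage at which either mate failed
    (Artefacts before rDNA). Raises ``ValueError`` on an orphan mate.
    """
    by_id: dict[str, dict[int, MateVerdict]] = {}
    for v in verdicts:
        by_id.setdefault(v.read_id, {})[v.mate] = v
    out: dict[str, str | None] = {}
    for read_id, mates in by_id.items():
        if set(mates) != {1, 2}:
            raise ValueError(f"orphan mate for read {read_id!r}")
        if mates[1].artefact or mates[2].artefact:
            out[read_id] = "Artefacts"
        elif mates[1].rdna or mates[2].rdna:
            out[read_id] = "rDNA"
        else:
            out[read_id] = None
    return out


def process_pair(pair: RawReadPair, cfg: PrepConfig) -> Union[CleanReadPair, RejectionRecord]:
    """Run the full prep on one pair: extract/trim, artefact filter, rDNA
    filter, with the earliest-stage rejection rule."""
    clean = extract_and_trim(pair, cfg)
    if isinstance(clean, RejectionRecord):
        return clean
    rej = filter_artefacts(clean, cfg)
    if rej is not None:
        return rej
    rej = filter_rdna(clean, cfg)
    if rej is not None:
        return rej
    return clean


# ---------------------------------------------------------------------------
# File-level plumbing


def read_fastq_pairs(r1: TextIO, r2: TextIO) -> Iterator[RawReadPair]:
    """Iterate over two synchronized FASTQ streams as RawReadPairs."""
    it1 = FastqGeneralIterator(r1)
    it2 = FastqGeneralIterator(r2)
    for rec1, rec2 in itertools.zip_longest(it1, it2):
        if rec1 is None or rec2 is None:
            raise ValueError("R1/R2 FASTQ files have different record counts")
        id1 = rec1[0].split()[0].removesuffix("/1")
        id2 = rec2[0].split()[0].removesuffix("/2")
        if id1 != id2:
            raise ValueError(f"mate id mismatch: {id1!r} vs {id2!r}")
        yield RawReadPair(id1, rec1[1].upper(), rec1[2], rec2[1].upper(), rec2[2])


def write_fastq_record(handle: TextIO, read_id: str, seq: str, qual: str) -> None:
    handle.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def prep_fastq(
    r1: TextIO,
    r2: TextIO,
    cfg: PrepConfig,
    out1: TextIO | None = None,
    out2: TextIO | None = None,
) -> tuple[dict[str, int], set[str]]:
    """Clean a whole library.

    Returns ``(counts, clean_ids)`` where counts has keys Total,
    Unextracted, Artefacts, rDNA and Clean, and clean_ids is the set of
    surviving read ids. Cleaned mates are written to ``out1``/``out2`` when
    given.
    """
    counts = {"Total": 0, "Unextracted": 0, "Artefacts": 0, "rDNA": 0, "Clean": 0}
    clean_ids: set[str] = set()
    for pair in read_fastq_pairs(r1, r2):
        counts["Total"] += 1
        result = process_pair(pair, cfg)
        if isinstance(result, RejectionRecord):
            counts[result.stage] += 1
            continue
        counts["Clean"] += 1
        clean_ids.add(result.read_id)
        if out1 is not None and out2 is not None:
            write_fastq_record(out1, result.read_id, result.seq1, result.qual1)
            write_fastq_record(out2, result.read_id, result.seq2, result.qual2)
    return counts, clean_ids


def load_fasta(path: str) -> dict[str, str]:
    """Read a (small) FASTA file into a name -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
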