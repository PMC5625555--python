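"""Classification of aligned read pairs into Non-aligned, Non-proper and proper.

The aligner is run upstream (BWA in the original workflow, with the maximum
insert length raised to 2 Mbp so that the two mates may fall in different
exons of the same gene); this module only consumes its SAM/BAM output. A
"proper" CAGEscan pair has both mates mapped to the same reference, in
head-to-head (FR, inward-facing) orientation, spanning at most
``max_span`` bases between the outermost aligned positions.

Properness is recomputed here from coordinates and strands rather than
trusted from the aligner's 0x2 flag bit, which keeps the classification
aligner-independent; the SAM flag is retained on each mate for reference.
Secondary (0x100) and supplementary (0x800) records are ignored — only the
primary alignment of each mate takes part.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import pysam

NON_ALIGNED = "NonAligned"
NON_PROPER = "NonProper"
PROPER = "Proper"

#: CIGAR operations that consume the reference (M, D, N, =, X).
_REF_CONSUMING = {0, 2, 3, 7, 8}
#: Reference-skip (intron) operation splitting alignment blocks.
_REF_SKIP = 3


@dataclass(frozen=True)
class AlignedMate:
    """One primary alignment of one mate.

    ``start``/``end`` are 0-based half-open over the reference span;
    ``blocks`` are the reference-consuming segments split at N (intron)
    operations. Unmapped mates carry ``mapped=False`` and no coordinates.
    """

    read_id: str
    role: str  # "CAGE" (read 1) or "CAGEscan" (read 2)
    ref_name: str | None
    start: int
    end: int
    strand: str
    mapq: int
    mapped: bool
    sam_flag: int = 0
    blocks: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.mapped:
            if self.start >= self.end:
                raise ValueError(f"{self.read_id}: empty alignment span")
            if not 0 <= self.mapq <= 255:
                raise ValueError(f"{self.read_id}: MAPQ {self.mapq} out of range")
            if not self.blocks:
                object.__setattr__(self, "blocks", ((self.start, self.end),))


@dataclass(frozen=True)
class AlignedPair:
    mate1: AlignedMate  # CAGE read
    mate2: AlignedMate  # CAGEscan read

    def __post_init__(self) -> None:
        if self.mate1.read_id != self.mate2.read_id:
            raise ValueError("mates belong to different reads")
        if self.mate1.role != "CAGE" or self.mate2.role != "CAGEscan":
            raise ValueError("mate roles must be (CAGE, CAGEscan)")

    @property
    def read_id(self) -> str:
        return self.mate1.read_id


@dataclass(frozen=True)
class ProperPairPolicy:
    """``max_span`` is inclusive: a pair whose outer span equals the limit
    is accepted, matching an aligner-side upper bound."""

    max_span: int = 2_000_000
    require_head_to_head: bool = True

    def __post_init__(self) -> None:
        if self.max_span <= 0:
            raise ValueError("max_span must be positive")


def is_proper_pair(pair: AlignedPair, policy: ProperPairPolicy = ProperPairPolicy()) -> bool:
    """Head-to-head test: same reference, opposite strands, the
    leftmost-starting mate on the + strand (ties accepted), outer span
    within the limit. Both mates must be mapped."""
    m1, m2 = pair.mate1, pair.mate2
    if not (m1.mapped and m2.mapped):
        raise ValueError("is_proper_pair requires both mates mapped")
    if m1.ref_name != m2.ref_name:
        return False
    if m1.strand == m2.strand:
        return False
    span = max(m1.end, m2.end) - min(m1.start, m2.start)
    if span > policy.max_span:
        return False
    if policy.require_head_to_head:
        fwd, rev = (m1, m2) if m1.strand == "+" else (m2, m1)
        if fwd.start > rev.start:
            return False
    return True


def classify_pair(pair: AlignedPair, policy: ProperPairPolicy = ProperPairPolicy()) -> str:
    """Exactly one label per pair: NonAligned if either mate is unmapped,
    NonProper if mapped but not head-to-head within the span limit, else
    Proper."""
    if not (pair.mate1.mapped and pair.mate2.mapped):
        return NON_ALIGNED
    return PROPER if is_proper_pair(pair, policy) else NON_PROPER


def _blocks_from_cigar(start: int, cigartuples) -> tuple[tuple[int, int], ...]:
    """Reference blocks of an alignment, split at N operations; M/D/=/X
    extend the current block."""
    blocks: list[tuple[int, int]] = []
    pos = start
    block_start = start
    for op, length in cigartuples:
        if op not in _REF_CONSUMING:
            continue
        if op == _REF_SKIP:
            if pos > block_start:
                blocks.append((block_start, pos))
            pos += length
            block_start = pos
        else:
            pos += length
    if pos > block_start:
        blocks.append((block_start, pos))
    return tuple(blocks)


def _mate_from_record(rec: pysam.AlignedSegment) -> AlignedMate:
    role = "CAGE" if rec.is_read1 else "CAGEscan"
    if rec.is_unmapped:
        return AlignedMate(
            read_id=rec.query_name,
            role=role,
            ref_name=None,
            start=-1,
            end=-1,
            strand=".",
            mapq=rec.mapping_quality,
            mapped=False,
            sam_flag=rec.flag,
        )
    try:
        start = rec.reference_start
        blocks = _blocks_from_cigar(start, rec.cigartuples)
        end = blocks[-1][1]
    except Exception as exc:  # malformed CIGAR
        raise ValueError(f"cannot parse alignment of {rec.query_name!r}: {exc}") from exc
    return AlignedMate(
        read_id=rec.query_name,
        role=role,
        ref_name=rec.reference_name,
        start=start,
        end=end,
        strand="-" if rec.is_reverse else "+",
        mapq=rec.mapping_quality,
        mapped=True,
        sam_flag=rec.flag,
        blocks=blocks,
    )


def read_pairs_from_sam(path: str) -> Iterator[AlignedPair]:
    """Stream mate-joined pairs from a SAM/BAM file.

    Primary records are joined by read id and first/second-in-pair flags;
    1-based SAM POS becomes a 0-based half-open interval whose end is
    derived from the CIGAR reference consumption. A read left without its
    mate at end of file raises ``ValueError``.
    """
    pending: dict[str, AlignedMate] = {}
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if not rec.is_paired:
                raise ValueError(f"unpaired record {rec.query_name!r}")
            mate = _mate_from_record(rec)
            other = pending.pop(rec.query_name, None)
            if other is None:
                pending[rec.query_name] = mate
                continue
            if mate.role == other.role:
                raise ValueError(f"two read-{mate.role} records for {rec.query_name!r}")
            m1, m2 = (mate, other) if mate.role == "CAGE" else (other, mate)
            yield AlignedPair(m1, m2)
    if pending:
        missing = sorted(pending)[:3]
        raise ValueError(f"orphan mates without partner records: {missing}")


@dataclass
class PairClassification:
    """Outcome of classifying a whole alignment file."""

    proper: list[AlignedPair] = field(default_factory=list)
    n_non_aligned: int = 0
    n_non_proper: int = 0

    @property
    def n_total(self) -> int:
        return len(self.proper) + self.n_non_aligned + self.n_non_proper


def classify_sam(path: str, policy: ProperPairPolicy = ProperPairPolicy()) -> PairClassification:
    """Classify every pair in a SAM/BAM file, keeping the proper ones."""
    out = PairClassification()
    for pair in read_pairs_from_sam(path):
        label = classify_pair(pair, policy)
        if label == PROPER:
            out.proper.append(pair)
        elif label == NON_ALIGNED:
            out.n_non_aligned += 1
        else:
            out.n_non_proper += 1
    return out
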