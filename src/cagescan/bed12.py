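"""BED12 pair models, deduplication, and promoter-seeded clustering.

Each proper pair becomes one BED12 record (a *CAGEscan pair*): the thick
interval marks the 1-bp transcription start site (the 5' end of the CAGE
mate), the score is the sum of the two mates' mapping qualities, and the
blocks are the merged reference segments of both mates — the gap between the
CAGE block and the downstream random-primed block is direct evidence that
one transcript connects the two regions.

PCR duplicates are pairs with identical genomic coordinates: within each
(chrom, strand, chromStart, chromEnd) group one record is kept and the other
n-1 are discarded.

Clustering collates all deduplicated pairs whose TSS falls inside the same
seed peak (a stranded promoter-region interval, e.g. a FANTOM5 DPI peak)
into one *CAGEscan cluster*: name, thickStart and thickEnd identify the
seed, the score counts the member pairs, and the blocks are the union of the
member blocks. Clusters for the same seed across several libraries merge
into a *meta-cluster* whose score counts the contributing libraries.
Alternatively, seeds can be called de novo from the TSSs themselves by
single-linkage clustering.

All coordinates are 0-based half-open, as in BED.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

from ._intervals import Interval, blocks_are_canonical, merge_blocks
from .pair_filter import AlignedPair

#: BED score field is bounded by the format; larger counts are clamped on
#: output unless strict BED is switched off.
BED_SCORE_MAX = 1000


@dataclass(frozen=True)
class Bed12Record:
    """A BED12 feature with absolute-coordinate blocks.

    Used for CAGEscan pairs (score = summed MAPQ, thick = 1-bp TSS),
    clusters (score = member pair count, thick = seed interval) and
    meta-clusters (score = contributing library count).
    """

    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str
    thick_start: int
    thick_end: int
    blocks: tuple[Interval, ...]
    item_rgb: str = "0"

    def validate(self) -> None:
        if not blocks_are_canonical(self.blocks):
            raise ValueError(f"{self.name}: blocks not sorted/merged: {self.blocks}")
        if self.blocks[0][0] != self.start or self.blocks[-1][1] != self.end:
            raise ValueError(f"{self.name}: blocks not flush with record span")
        if self.strand not in "+-":
            raise ValueError(f"{self.name}: invalid strand {self.strand!r}")
        if self.thick_start >= self.thick_end:
            raise ValueError(f"{self.name}: empty thick interval")

    @property
    def tss(self) -> int:
        """The TSS base marked by the thick interval (pair records only)."""
        return self.thick_start

    def coordinate_key(self) -> tuple[str, str, int, int]:
        """Duplicate-identity key: outer coordinates plus strand."""
        return (self.chrom, self.strand, self.start, self.end)

    def to_fields(self, strict_bed: bool = True) -> list[str]:
        score = min(self.score, BED_SCORE_MAX) if strict_bed else self.score
        sizes = ",".join(str(e - s) for s, e in self.blocks)
        starts = ",".join(str(s - self.start) for s, e in self.blocks)
        return [
            self.chrom,
            str(self.start),
            str(self.end),
            self.name,
            str(score),
            self.strand,
            str(self.thick_start),
            str(self.thick_end),
            self.item_rgb,
            str(len(self.blocks)),
            sizes,
            starts,
        ]


# Role-specific aliases, for signature readability.
PairRecord = Bed12Record
CAGEscanCluster = Bed12Record
MetaCluster = Bed12Record


@dataclass(frozen=True)
class SeedPeak:
    """A stranded promoter-region interval anchoring clustering."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"seed {self.name}: empty interval")
        if self.strand not in "+-":
            raise ValueError(f"seed {self.name}: invalid strand {self.strand!r}")


def pair_to_bed12(pair: AlignedPair) -> PairRecord:
    """Convert one proper pair to its BED12 model.

    The record strand is the CAGE mate's strand; the TSS is that mate's 5'
    end (alignment start on +, alignment end - 1 on -). Overlapping or
    adjacent mate blocks merge into one.
    """
    m1, m2 = pair.mate1, pair.mate2
    if not (m1.mapped and m2.mapped) or m1.ref_name != m2.ref_name:
        raise ValueError(f"{pair.read_id}: pair_to_bed12 requires a proper pair")
    blocks = tuple(merge_blocks(list(m1.blocks) + list(m2.blocks)))
    tss = m1.start if m1.strand == "+" else m1.end - 1
    return Bed12Record(
        chrom=m1.ref_name,
        start=blocks[0][0],
        end=blocks[-1][1],
        name=pair.read_id,
        score=m1.mapq + m2.mapq,
        strand=m1.strand,
        thick_start=tss,
        thick_end=tss + 1,
        blocks=blocks,
    )


def deduplicate(records: Iterable[PairRecord]) -> tuple[list[PairRecord], int]:
    """Collapse identical-coordinate pairs: when n records share a
    coordinate key, 1 is kept and n-1 are counted as duplicates.

    The kept record is the one with the highest score; ties go to the
    lexicographically smallest name, so the result is order-independent.
    Returns the kept records sorted by coordinate, and the duplicate count.
    """
    groups: dict[tuple, PairRecord] = {}
    n = 0
    for rec in records:
        n += 1
        key = rec.coordinate_key()
        best = groups.get(key)
        if best is None or (-rec.score, rec.name) < (-best.score, best.name):
            groups[key] = rec
    kept = sorted(groups.values(), key=lambda r: (r.chrom, r.start, r.end, r.strand, r.name))
    return kept, n - len(kept)


class SeedIndex:
    """Seeds indexed per (chrom, strand) for TSS containment lookup.

    Same-strand overlapping seeds are rejected at construction: DPI-style
    peak sets are non-overlapping per strand, and a silent tie-break here
    would hide upstream data errors.
    """

    def __init__(self, seeds: Iterable[SeedPeak]):
        self.seeds: list[SeedPeak] = list(seeds)
        names = [s.name for s in self.seeds]
        if len(set(names)) != len(names):
            raise ValueError("seed names are not unique")
        self._index: dict[tuple[str, str], tuple[list[int], list[SeedPeak]]] = {}
        by_key: dict[tuple[str, str], list[SeedPeak]] = {}
        for s in self.seeds:
            by_key.setdefault((s.chrom, s.strand), []).append(s)
        for key, group in by_key.items():
            group.sort(key=lambda s: s.start)
            for a, b in zip(group, group[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping same-strand seeds {a.name!r} and {b.name!r} on {key[0]}{key[1]}"
                    )
            self._index[key] = ([s.start for s in group], group)

    def __len__(self) -> int:
        return len(self.seeds)

    def lookup(self, chrom: str, strand: str, pos: int) -> SeedPeak | None:
        entry = self._index.get((chrom, strand))
        if entry is None:
            return None
        starts, group = entry
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and group[i].start <= pos < group[i].end:
            return group[i]
        return None


def assign_to_seed(record: PairRecord, seeds: SeedIndex) -> str | None:
    """Name of the unique same-strand seed containing the record's TSS
    base, or None if the TSS misses every seed."""
    hit = seeds.lookup(record.chrom, record.strand, record.tss)
    return hit.name if hit is not None else None


def build_clusters(
    records: Iterable[PairRecord], seeds: SeedIndex
) -> tuple[list[CAGEscanCluster], list[PairRecord]]:
    """Assemble one cluster per seed holding >= 1 deduplicated pair.

    Cluster blocks are the interval union of all member blocks; the span
    covers all members (it need not contain the whole seed); score = member
    count; name/thickStart/thickEnd come from the seed. Records whose TSS
    misses every seed are returned separately, never dropped silently.
    Output is sorted by (chrom, chromStart).
    """
    members: dict[str, list[PairRecord]] = {}
    unassigned: list[PairRecord] = []
    for rec in records:
        name = assign_to_seed(rec, seeds)
        if name is None:
            unassigned.append(rec)
        else:
            members.setdefault(name, []).append(rec)
    seed_by_name = {s.name: s for s in seeds.seeds}
    clusters = []
    for name, recs in members.items():
        seed = seed_by_name[name]
        blocks = tuple(merge_blocks([b for r in recs for b in r.blocks]))
        clusters.append(
            Bed12Record(
                chrom=seed.chrom,
                start=blocks[0][0],
                end=blocks[-1][1],
                name=seed.name,
                score=len(recs),
                strand=seed.strand,
                thick_start=seed.start,
                thick_end=seed.end,
                blocks=blocks,
            )
        )
    clusters.sort(key=lambda c: (c.chrom, c.start, c.end, c.name))
    return clusters, unassigned


def merge_meta(per_library_clusters: Mapping[str, Sequence[CAGEscanCluster]]) -> list[MetaCluster]:
    """Merge clusters across libraries into meta-clusters keyed by seed name.

    Block sets union across libraries; the score counts distinct
    contributing libraries (not pairs). A seed name carried with different
    coordinates by different libraries is a validation error.
    """
    by_seed: dict[str, dict] = {}
    for lib_id, clusters in per_library_clusters.items():
        for c in clusters:
            entry = by_seed.get(c.name)
            seed_coords = (c.chrom, c.strand, c.thick_start, c.thick_end)
            if entry is None:
                by_seed[c.name] = {"coords": seed_coords, "libs": {lib_id}, "blocks": list(c.blocks)}
            else:
                if entry["coords"] != seed_coords:
                    raise ValueError(
                        f"seed {c.name!r} has inconsistent coordinates across libraries"
                    )
                entry["libs"].add(lib_id)
                entry["blocks"].extend(c.blocks)
    metas = []
    for name, entry in by_seed.items():
        chrom, strand, t_start, t_end = entry["coords"]
        blocks = tuple(merge_blocks(entry["blocks"]))
        metas.append(
            Bed12Record(
                chrom=chrom,
                start=blocks[0][0],
                end=blocks[-1][1],
                name=name,
                score=len(entry["libs"]),
                strand=strand,
                thick_start=t_start,
                thick_end=t_end,
                blocks=blocks,
            )
        )
    metas.sort(key=lambda c: (c.chrom, c.start, c.end, c.name))
    return metas


def de_novo_seeds(records: Iterable[PairRecord], join_distance: int) -> list[SeedPeak]:
    """Call seeds from the pairs' own 5' ends by single-linkage clustering.

    TSS positions at most ``join_distance`` apart (per chrom and strand)
    join one seed spanning [min TSS, max TSS + 1). Seed names encode their
    locus as ``chrom:start..end,strand``.
    """
    if join_distance < 0:
        raise ValueError("join_distance must be >= 0")
    by_key: dict[tuple[str, str], list[int]] = {}
    for rec in records:
        by_key.setdefault((rec.chrom, rec.strand), []).append(rec.tss)
    seeds = []
    for (chrom, strand), positions in sorted(by_key.items()):
        positions.sort()
        run = [positions[0]]
        for pos in positions[1:]:
            if pos - run[-1] <= join_distance:
                run.append(pos)
            else:
                seeds.append(_seed_from_run(chrom, strand, run))
                run = [pos]
        seeds.append(_seed_from_run(chrom, strand, run))
    return seeds


def _seed_from_run(chrom: str, strand: str, run: list[int]) -> SeedPeak:
    start, end = run[0], run[-1] + 1
    return SeedPeak(chrom, start, end, f"{chrom}:{start}..{end},{strand}", strand)


# ---------------------------------------------------------------------------
# BED I/O (tab-delimited, bit-stable round trips)


def write_bed12(records: Iterable[Bed12Record], handle: TextIO, strict_bed: bool = True) -> None:
    for rec in records:
        handle.write("\t".join(rec.to_fields(strict_bed=strict_bed)) + "\n")


def read_bed12(handle: TextIO) -> list[Bed12Record]:
    records = []
    for line_no, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) != 12:
            raise ValueError(f"line {line_no}: expected 12 BED columns, got {len(f)}")
        start = int(f[1])
        sizes = [int(x) for x in f[10].split(",") if x != ""]
        offsets = [int(x) for x in f[11].split(",") if x != ""]
        if len(sizes) != int(f[9]) or len(offsets) != int(f[9]):
            raise ValueError(f"line {line_no}: blockCount disagrees with block lists")
        blocks = tuple((start + off, start + off + size) for off, size in zip(offsets, sizes))
        records.append(
            Bed12Record(
                chrom=f[0],
                start=start,
                end=int(f[2]),
                name=f[3],
                score=int(f[4]),
                strand=f[5],
                thick_start=int(f[6]),
                thick_end=int(f[7]),
                blocks=blocks,
                item_rgb=f[8],
            )
        )
    return records


def write_bed6(seeds: Iterable[SeedPeak], handle: TextIO, score: int = 0) -> None:
    for s in seeds:
        handle.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.name}\t{score}\t{s.strand}\n")


def read_bed6(handle: TextIO) -> list[SeedPeak]:
    seeds = []
    for line_no, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 6:
            raise ValueError(f"line {line_no}: expected >= 6 BED columns")
        seeds.append(SeedPeak(f[0], int(f[1]), int(f[2]), f[3], f[5]))
    return seeds
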