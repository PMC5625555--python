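"""Per-library QC accounting, TSS annotation, and inter-library similarity.

The QC ledger counts read pairs discarded at each stage of the pipeline —
Unextracted, Artefacts, rDNA, Non-aligned, Non-proper, Duplicates — plus the
surviving CAGEscan pairs; these categories partition the library exactly.
The ledger is exported as plain-text tab-delimited (subject, predicate,
object) triples.

TSS annotation assigns each pair's start site to Promoter, Exon or Other
with strict Promoter > Exon precedence (Other means non-promoter,
non-exon). Reproducibility across libraries is quantified by the Jaccard
index between the sets of seed peaks each library detects; for duplicated
samples the replicate should be the other library's nearest neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .bed12 import Bed12Record

#: Ledger categories in canonical (pipeline) order. Total is the number of
#: raw input pairs; the remaining seven partition it.
LEDGER_CATEGORIES = (
    "Total",
    "Unextracted",
    "Artefacts",
    "rDNA",
    "NonAligned",
    "NonProper",
    "Duplicates",
    "CAGEscanPairs",
)

REJECTION_CATEGORIES = LEDGER_CATEGORIES[1:-1]


@dataclass
class QCLedger:
    library_id: str
    total: int = 0
    unextracted: int = 0
    artefacts: int = 0
    rdna: int = 0
    non_aligned: int = 0
    non_proper: int = 0
    duplicates: int = 0
    cagescan_pairs: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "Total": self.total,
            "Unextracted": self.unextracted,
            "Artefacts": self.artefacts,
            "rDNA": self.rdna,
            "NonAligned": self.non_aligned,
            "NonProper": self.non_proper,
            "Duplicates": self.duplicates,
            "CAGEscanPairs": self.cagescan_pairs,
        }

    def check(self) -> None:
        """Enforce the partition invariant: every input pair is counted in
        exactly one category."""
        d = self.as_dict()
        parts = sum(d[c] for c in LEDGER_CATEGORIES[1:])
        if parts != self.total:
            raise ValueError(
                f"{self.library_id}: ledger categories sum to {parts}, Total is {self.total}"
            )
        if any(v < 0 for v in d.values()):
            raise ValueError(f"{self.library_id}: negative ledger count")


def emit_ledger(ledger: QCLedger, handle: TextIO) -> None:
    """Write the ledger as (library_id, category, count) triples, one line
    per category in canonical order. Refuses to write an inconsistent
    ledger."""
    ledger.check()
    for category, count in ledger.as_dict().items():
        handle.write(f"{ledger.library_id}\t{category}\t{count}\n")


def read_ledger(handle: TextIO) -> QCLedger:
    values: dict[str, int] = {}
    library_id = None
    for line in handle:
        line = line.rstrip("\n")
        if not line:
            continue
        lib, category, count = line.split("\t")
        library_id = lib
        values[category] = int(count)
    if library_id is None:
        raise ValueError("empty ledger file")
    return QCLedger(
        library_id=library_id,
        total=values.get("Total", 0),
        unextracted=values.get("Unextracted", 0),
        artefacts=values.get("Artefacts", 0),
        rdna=values.get("rDNA", 0),
        non_aligned=values.get("NonAligned", 0),
        non_proper=values.get("NonProper", 0),
        duplicates=values.get("Duplicates", 0),
        cagescan_pairs=values.get("CAGEscanPairs", 0),
    )


# ---------------------------------------------------------------------------
# TSS annotation


@dataclass(frozen=True)
class AnnotationInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."  # "." matches both strands


class AnnotationSet:
    """Promoter and exon interval sets for start-site classification."""

    def __init__(
        self,
        promoters: Iterable[AnnotationInterval],
        exons: Iterable[AnnotationInterval],
    ):
        self._trees: dict[str, dict[str, IntervalTree]] = {"Promoter": {}, "Exon": {}}
        for kind, ivs in (("Promoter", promoters), ("Exon", exons)):
            for iv in ivs:
                tree = self._trees[kind].setdefault(iv.chrom, IntervalTree())
                tree.addi(iv.start, iv.end, iv.strand)

    def _hits(self, kind: str, chrom: str, pos: int, strand: str) -> bool:
        tree = self._trees[kind].get(chrom)
        if tree is None:
            return False
        return any(h.data in (".", strand) for h in tree.at(pos))

    def classify(self, chrom: str, pos: int, strand: str) -> str:
        if self._hits("Promoter", chrom, pos, strand):
            return "Promoter"
        if self._hits("Exon", chrom, pos, strand):
            return "Exon"
        return "Other"


def annotation_intervals_from_bed6(handle: TextIO) -> list[AnnotationInterval]:
    out = []
    for line in handle:
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        strand = f[5] if len(f) >= 6 else "."
        out.append(AnnotationInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def classify_start(record: Bed12Record, ann: AnnotationSet) -> str:
    """Promoter if the TSS base falls in a same-strand (or unstranded)
    promoter interval; else Exon on the same rule; else Other."""
    return ann.classify(record.chrom, record.tss, record.strand)


def start_fractions(records: Sequence[Bed12Record], ann: AnnotationSet) -> dict[str, float]:
    """Fraction of pairs starting in a Promoter, Exon or Other region."""
    counts = {"Promoter": 0, "Exon": 0, "Other": 0}
    for rec in records:
        counts[classify_start(rec, ann)] += 1
    n = max(1, len(records))
    return {k: v / n for k, v in counts.items()}


# ---------------------------------------------------------------------------
# Jaccard similarity between libraries


def detected_peaks(clusters: Iterable[Bed12Record], min_pairs: int = 1) -> set[str]:
    """Seed names supported by at least ``min_pairs`` member pairs."""
    return {c.name for c in clusters if c.score >= min_pairs}


def jaccard(a: set, b: set) -> float:
    """|A n B| / |A u B|; 0 by convention when both sets are empty."""
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def jaccard_matrix(per_library_peaks: Mapping[str, set]) -> pd.DataFrame:
    """Symmetric matrix of Jaccard indices between the detected-peak sets
    of every pair of libraries, indexed by library id."""
    ids = list(per_library_peaks)
    if len(ids) < 2:
        raise ValueError("jaccard_matrix needs at least two libraries")
    values = np.zeros((len(ids), len(ids)))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if j < i:
                continue
            v = jaccard(per_library_peaks[a], per_library_peaks[b])
            values[i, j] = values[j, i] = v
    return pd.DataFrame(values, index=ids, columns=ids)


def best_match(matrix: pd.DataFrame, library_id: str) -> str:
    """The other library most similar to ``library_id``; ties break to the
    lexicographically smallest id."""
    row = matrix.loc[library_id].drop(library_id)
    if row.empty:
        raise ValueError("best_match needs a matrix with at least two libraries")
    top = row.max()
    return min(row[row == top].index)


def average_linkage_order(matrix: pd.DataFrame) -> list[str]:
    """Leaf order from average-linkage clustering of 1 - similarity, for
    readers who want the heatmap ordering."""
    from scipy.cluster.hierarchy import leaves_list, linkage
    from scipy.spatial.distance import squareform

    dist = 1.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    order = leaves_list(linkage(condensed, method="average"))
    return [matrix.index[i] for i in order]


def write_similarity_matrix(matrix: pd.DataFrame, handle: TextIO) -> None:
    matrix.to_csv(handle, sep="\t", index_label="library")
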