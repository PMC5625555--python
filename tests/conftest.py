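"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own interval and
orientation code: block unions are computed on per-base bitmaps, membership
by scanning every interval, properness by re-deriving the head-to-head
conditions from first principles.
"""

from __future__ import annotations

import numpy as np
import pytest

from cagescan.bed12 import Bed12Record
from cagescan.pair_filter import AlignedMate, AlignedPair


def bitmap_union(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Interval union via a per-base boolean bitmap (oracle)."""
    lo = min(s for s, _ in blocks)
    hi = max(e for _, e in blocks)
    bits = np.zeros(hi - lo, dtype=bool)
    for s, e in blocks:
        bits[s - lo : e - lo] = True
    edges = np.flatnonzero(np.diff(np.concatenate(([0], bits.view(np.int8), [0]))))
    return [(int(edges[i]) + lo, int(edges[i + 1]) + lo) for i in range(0, len(edges), 2)]


def oracle_is_proper(ref1, s1, e1, strand1, ref2, s2, e2, strand2, max_span) -> bool:
    """First-principles head-to-head test (oracle)."""
    if ref1 != ref2 or strand1 == strand2:
        return False
    if max(e1, e2) - min(s1, s2) > max_span:
        return False
    (fs, _), (rs, _) = ((s1, e1), (s2, e2)) if strand1 == "+" else ((s2, e2), (s1, e1))
    return fs <= rs


def make_mate(
    read_id="r1",
    role="CAGE",
    ref="chr1",
    start=100,
    end=136,
    strand="+",
    mapq=30,
    mapped=True,
    blocks=(),
) -> AlignedMate:
    return AlignedMate(
        read_id=read_id,
        role=role,
        ref_name=ref if mapped else None,
        start=start if mapped else -1,
        end=end if mapped else -1,
        strand=strand if mapped else ".",
        mapq=mapq,
        mapped=mapped,
        blocks=tuple(blocks),
    )


def make_pair(m1_kwargs: dict, m2_kwargs: dict, read_id="r1") -> AlignedPair:
    m1 = make_mate(read_id=read_id, role="CAGE", **m1_kwargs)
    m2 = make_mate(read_id=read_id, role="CAGEscan", **m2_kwargs)
    return AlignedPair(m1, m2)


def make_record(
    chrom="chr1",
    start=100,
    end=530,
    name="r1",
    score=50,
    strand="+",
    tss=None,
    blocks=None,
) -> Bed12Record:
    if blocks is None:
        blocks = ((start, end),)
    if tss is None:
        tss = start if strand == "+" else end - 1
    return Bed12Record(
        chrom=chrom,
        start=start,
        end=end,
        name=name,
        score=score,
        strand=strand,
        thick_start=tss,
        thick_end=tss + 1,
        blocks=tuple(blocks),
    )


@pytest.fixture(scope="session")
def small_sim():
    """One deterministic mixed-content library, reused across tests."""
    from cagescan.simulate import SimConfig, simulate

    return simulate(SimConfig(seed=3))


@pytest.fixture(scope="session")
def small_fixture_dir(small_sim, tmp_path_factory):
    """The same library written to disk."""
    from cagescan.simulate import write_fixture

    out = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(small_sim, out)
    return paths


@pytest.fixture(scope="session")
def small_pipeline_run(small_sim, small_fixture_dir, tmp_path_factory):
    """Full pipeline output for the shared library."""
    from cagescan.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline_out")
    paths = small_fixture_dir
    cfg = PipelineConfig(
        library_id="lib1",
        r1=str(paths["r1"]),
        r2=str(paths["r2"]),
        sam=str(paths["sam"]),
        out_dir=str(out),
        artefacts=str(paths["artefacts"]),
        rdna=str(paths["rdna"]),
        seeds=str(paths["seeds"]),
    )
    manifest = run_pipeline(cfg)
    return {"manifest": manifest, "out": out, "paths": paths, "cfg": cfg}
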