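"""BED12 pair models, deduplication, clustering and meta-clusters."""

from __future__ import annotations

import io
import random

import pytest

from cagescan.bed12 import (
    Bed12Record,
    SeedIndex,
    SeedPeak,
    assign_to_seed,
    build_clusters,
    de_novo_seeds,
    deduplicate,
    merge_meta,
    pair_to_bed12,
    read_bed6,
    read_bed12,
    write_bed6,
    write_bed12,
)

from conftest import bitmap_union, make_pair, make_record


class TestPairToBed12:
    def test_field_by_field_construction(self):
        pair = make_pair(
            dict(start=100, end=136, strand="+", mapq=20),
            dict(start=500, end=530, strand="-", mapq=30),
            read_id="read1",
        )
        rec = pair_to_bed12(pair)
        assert rec.to_fields() == [
            "chr1", "100", "530", "read1", "50", "+", "100", "101", "0", "2", "36,30", "0,400",
        ]

    def test_overlapping_mates_merge_to_one_block(self):
        pair = make_pair(
            dict(start=100, end=136, strand="+"), dict(start=120, end=156, strand="-")
        )
        rec = pair_to_bed12(pair)
        assert (rec.start, rec.end, rec.blocks) == (100, 156, ((100, 156),))

    def test_adjacent_mates_merge_to_one_block(self):
        pair = make_pair(
            dict(start=100, end=136, strand="+"), dict(start=136, end=166, strand="-")
        )
        assert pair_to_bed12(pair).blocks == ((100, 166),)

    def test_minus_strand_tss_is_rightmost_base(self):
        # the 5' end of a reverse-strand CAGE mate is its last genomic base
        pair = make_pair(
            dict(start=500, end=536, strand="-"), dict(start=100, end=130, strand="+")
        )
        rec = pair_to_bed12(pair)
        assert (rec.strand, rec.thick_start, rec.thick_end) == ("-", 535, 536)

    def test_score_is_sum_of_mapping_qualities(self):
        pair = make_pair(
            dict(start=100, end=136, strand="+", mapq=0),
            dict(start=500, end=530, strand="-", mapq=37),
        )
        assert pair_to_bed12(pair).score == 37


class TestDeduplicate:
    def test_n_identical_keep_one(self):
        records = [make_record(name=f"r{i}") for i in range(3)]
        kept, dups = deduplicate(records)
        assert len(kept) == 1 and dups == 2

    def test_empty_input(self):
        assert deduplicate([]) == ([], 0)

    def test_tie_break_highest_score_then_smallest_name(self):
        k1 = [
            make_record(name="a", score=40),
            make_record(name="b", score=50),
            make_record(name="c", score=50),
        ]
        k2 = [
            make_record(name="d", start=900, end=1000, score=10),
            make_record(name="e", start=900, end=1000, score=20),
        ]
        kept, dups = deduplicate(k1 + k2)
        assert dups == 3
        assert {r.name for r in kept} == {"b", "e"}

    def test_strand_is_part_of_the_key(self):
        records = [make_record(name="a", strand="+"), make_record(name="b", strand="-")]
        kept, dups = deduplicate(records)
        assert len(kept) == 2 and dups == 0

    def test_order_independent(self):
        rng = random.Random(5)
        records = [
            make_record(name=f"r{i}", start=100 + (i % 4) * 10, end=200 + (i % 4) * 10,
                        score=rng.randrange(0, 60))
            for i in range(40)
        ]
        kept1, d1 = deduplicate(records)
        shuffled = records[:]
        rng.shuffle(shuffled)
        kept2, d2 = deduplicate(shuffled)
        assert kept1 == kept2 and d1 == d2


class TestSeedAssignment:
    def test_tss_inside_seed(self):
        seeds = SeedIndex([SeedPeak("chr1", 95, 105, "s1", "+")])
        assert assign_to_seed(make_record(tss=100), seeds) == "s1"

    def test_half_open_right_edge(self):
        seeds = SeedIndex([SeedPeak("chr1", 95, 105, "s1", "+")])
        assert assign_to_seed(make_record(tss=105), seeds) is None
        assert assign_to_seed(make_record(tss=95), seeds) == "s1"

    def test_strand_mismatch_unassigned(self):
        seeds = SeedIndex([SeedPeak("chr1", 95, 105, "s1", "+")])
        rec = make_record(strand="-", tss=100)
        assert assign_to_seed(rec, seeds) is None

    def test_overlapping_same_strand_seeds_rejected_at_load(self):
        with pytest.raises(ValueError, match="overlapping"):
            SeedIndex([
                SeedPeak("chr1", 95, 105, "s1", "+"),
                SeedPeak("chr1", 100, 120, "s2", "+"),
            ])

    def test_opposite_strand_overlap_allowed(self):
        SeedIndex([
            SeedPeak("chr1", 95, 105, "s1", "+"),
            SeedPeak("chr1", 100, 120, "s2", "-"),
        ])

    def test_assignment_agrees_with_brute_force_scan(self):
        rng = random.Random(23)
        seeds = []
        pos = 0
        for i in range(50):
            pos += rng.randrange(5, 50)
            width = rng.randrange(1, 20)
            seeds.append(SeedPeak("chr1", pos, pos + width, f"s{i}", rng.choice("+-")))
            pos += width
        index = SeedIndex(seeds)
        for _ in range(500):
            tss = rng.randrange(0, pos + 50)
            strand = rng.choice("+-")
            rec = make_record(strand=strand, start=tss, end=tss + 60, tss=tss)
            expected = next(
                (s.name for s in seeds
                 if s.strand == strand and s.start <= tss < s.end),
                None,
            )
            assert assign_to_seed(rec, index) == expected


class TestBuildClusters:
    def test_singleton_cluster(self):
        seeds = SeedIndex([SeedPeak("chr1", 95, 105, "s1", "+")])
        rec = make_record(start=100, end=530, tss=100, blocks=((100, 136), (500, 530)))
        clusters, unassigned = build_clusters([rec], seeds)
        assert unassigned == []
        (c,) = clusters
        assert (c.start, c.end, c.score, c.name) == (100, 530, 1, "s1")
        assert (c.thick_start, c.thick_end) == (95, 105)
        assert c.blocks == rec.blocks

    def test_two_member_union(self):
        seeds = SeedIndex([SeedPeak("chr1", 95, 105, "s1", "+")])
        a = make_record(name="A", start=100, end=530, tss=100, blocks=((100, 136), (500, 530)))
        b = make_record(name="B", start=98, end=340, tss=98, blocks=((98, 134), (300, 340)))
        clusters, _ = build_clusters([a, b], seeds)
        (c,) = clusters
        assert (c.start, c.end, c.score) == (98, 530, 2)
        assert c.blocks == ((98, 136), (300, 340), (500, 530))

    def test_no_records_no_clusters(self):
        seeds = SeedIndex([SeedPeak("chr1", 95, 105, "s1", "+")])
        assert build_clusters([], seeds) == ([], [])

    def test_unassigned_records_preserved(self):
        seeds = SeedIndex([SeedPeak("chr1", 95, 105, "s1", "+")])
        rec = make_record(tss=500, start=500, end=560)
        clusters, unassigned = build_clusters([rec], seeds)
        assert clusters == [] and unassigned == [rec]

    def test_blocks_equal_bitmap_union_oracle_on_random_instances(self):
        rng = random.Random(31)
        for _ in range(25):
            seeds = SeedIndex([SeedPeak("chr1", 0, 200, "s1", "+")])
            records = []
            for i in range(rng.randrange(1, 15)):
                tss = rng.randrange(0, 200)
                nblocks = rng.randrange(1, 4)
                blocks, pos = [], tss
                for _ in range(nblocks):
                    length = rng.randrange(20, 80)
                    blocks.append((pos, pos + length))
                    pos += length + rng.randrange(1, 300)
                records.append(
                    make_record(name=f"r{i}", start=blocks[0][0], end=blocks[-1][1],
                                tss=tss, blocks=tuple(blocks))
                )
            clusters, _ = build_clusters(records, seeds)
            (c,) = clusters
            expected = bitmap_union([b for r in records for b in r.blocks])
            assert list(c.blocks) == expected
            assert c.score == len(records)

    def test_order_independence(self):
        rng = random.Random(37)
        seeds = SeedIndex([
            SeedPeak("chr1", 0, 50, "s1", "+"),
            SeedPeak("chr1", 1000, 1050, "s2", "+"),
        ])
        records = [
            make_record(name=f"r{i}", start=tss, end=tss + 100, tss=tss)
            for i, tss in enumerate(rng.choices(range(0, 50), k=10) + rng.choices(range(1000, 1050), k=10))
        ]
        c1, u1 = build_clusters(records, seeds)
        shuffled = records[:]
        rng.shuffle(shuffled)
        c2, u2 = build_clusters(shuffled, seeds)
        assert c1 == c2 and sorted(u1, key=lambda r: r.name) == sorted(u2, key=lambda r: r.name)

    def test_conservation_of_assigned_records(self):
        rng = random.Random(41)
        seeds = SeedIndex([SeedPeak("chr1", 100, 150, "s1", "+")])
        records = [
            make_record(name=f"r{i}", start=tss, end=tss + 60, tss=tss)
            for i, tss in enumerate(rng.choices(range(0, 400), k=60))
        ]
        clusters, unassigned = build_clusters(records, seeds)
        assert sum(c.score for c in clusters) + len(unassigned) == len(records)


class TestMergeMeta:
    def _cluster(self, name="s1", score=3, blocks=((100, 200),), thick=(95, 105)):
        return Bed12Record(
            chrom="chr1", start=blocks[0][0], end=blocks[-1][1], name=name, score=score,
            strand="+", thick_start=thick[0], thick_end=thick[1], blocks=tuple(blocks),
        )

    def test_score_counts_contributing_libraries(self):
        per_lib = {
            "lib1": [self._cluster(score=5)],
            "lib2": [self._cluster(score=1)],
            "lib3": [self._cluster(score=9)],
            "lib4": [],
            "lib5": [],
        }
        (meta,) = merge_meta(per_lib)
        assert meta.score == 3  # libraries, not pairs

    def test_single_library_identity_with_unit_scores(self):
        clusters = [self._cluster(name="s1"), self._cluster(name="s2", blocks=((500, 600),))]
        metas = merge_meta({"lib1": clusters})
        assert [m.name for m in metas] == ["s1", "s2"]
        assert all(m.score == 1 for m in metas)
        assert [m.blocks for m in metas] == [c.blocks for c in clusters]

    def test_disjoint_blocks_union_across_libraries(self):
        per_lib = {
            "lib1": [self._cluster(blocks=((100, 200),))],
            "lib2": [self._cluster(blocks=((300, 400),))],
        }
        (meta,) = merge_meta(per_lib)
        assert meta.blocks == ((100, 200), (300, 400))
        assert meta.score == 2

    def test_inconsistent_seed_coordinates_rejected(self):
        per_lib = {
            "lib1": [self._cluster(thick=(95, 105))],
            "lib2": [self._cluster(thick=(90, 105))],
        }
        with pytest.raises(ValueError, match="inconsistent"):
            merge_meta(per_lib)


class TestDeNovoSeeds:
    def test_single_linkage_grouping(self):
        records = [make_record(name=f"r{i}", start=t, end=t + 60, tss=t) for i, t in enumerate([100, 105, 300])]
        seeds = de_novo_seeds(records, join_distance=20)
        assert [(s.start, s.end) for s in seeds] == [(100, 106), (300, 301)]

    def test_single_tss_gives_1bp_seed(self):
        (seed,) = de_novo_seeds([make_record(start=100, end=160, tss=100)], 20)
        assert (seed.start, seed.end) == (100, 101)

    def test_join_distance_boundary_is_inclusive(self):
        recs = [make_record(name=f"r{t}", start=t, end=t + 60, tss=t) for t in (100, 121)]
        assert len(de_novo_seeds(recs, 20)) == 2
        assert len(de_novo_seeds(recs, 21)) == 1

    def test_strands_cluster_separately(self):
        recs = [
            make_record(name="a", start=100, end=160, tss=100, strand="+"),
            make_record(name="b", start=95, end=165, tss=104, strand="-"),
        ]
        assert len(de_novo_seeds(recs, 20)) == 2

    def test_negative_join_distance_rejected(self):
        with pytest.raises(ValueError):
            de_novo_seeds([], -1)


class TestBedIO:
    def test_bed12_round_trip_is_bit_exact(self):
        records = [
            make_record(name="a", start=100, end=530, tss=100, blocks=((100, 136), (500, 530))),
            make_record(name="b", start=90, end=190, tss=189, strand="-"),
        ]
        buf = io.StringIO()
        write_bed12(records, buf)
        text = buf.getvalue()
        back = read_bed12(io.StringIO(text))
        buf2 = io.StringIO()
        write_bed12(back, buf2)
        assert buf2.getvalue() == text
        assert back == records

    def test_bed6_round_trip(self):
        seeds = [SeedPeak("chr1", 95, 105, "s1", "+"), SeedPeak("chr2", 5, 25, "s2", "-")]
        buf = io.StringIO()
        write_bed6(seeds, buf)
        assert read_bed6(io.StringIO(buf.getvalue())) == seeds

    def test_score_clamped_to_bed_limit_unless_disabled(self):
        rec = make_record(score=1500)
        assert rec.to_fields(strict_bed=True)[4] == "1000"
        assert rec.to_fields(strict_bed=False)[4] == "1500"

    def test_malformed_block_count_rejected(self):
        line = "chr1\t100\t200\tx\t0\t+\t100\t101\t0\t2\t100\t0\n"
        with pytest.raises(ValueError, match="blockCount"):
            read_bed12(io.StringIO(line))

    def test_validator_flags_non_flush_blocks(self):
        rec = make_record(start=100, end=530, blocks=((100, 136), (500, 529)))
        with pytest.raises(ValueError, match="flush"):
            rec.validate()

    def test_validator_flags_unsorted_blocks(self):
        rec = make_record(start=100, end=530, blocks=((500, 530), (100, 136)))
        with pytest.raises(ValueError):
            rec.validate()
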