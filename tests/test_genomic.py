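"""Interval I/O, nearest-TSS annotation, and overlap arithmetic."""

import numpy as np
import pytest

from divatac.genomic import (
    BedParseError,
    Region,
    TSSRecord,
    annotate_nearest_tss,
    classify_distance,
    overlap_pairs,
    read_regions,
    read_tss,
    write_regions,
)


def write(tmp_path, text, name="f.bed"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadRegions:
    def test_three_column_line_maps_directly(self, tmp_path):
        regions = read_regions(write(tmp_path, "chr1\t100\t200\n"))
        assert regions == [Region("chr1", 100, 200, "region_1")]

    def test_empty_interval_rejected_with_line_number(self, tmp_path):
        with pytest.raises(BedParseError, match="line 1"):
            read_regions(write(tmp_path, "chr1\t200\t200\n"))

    def test_non_integer_coordinate_rejected(self, tmp_path):
        with pytest.raises(BedParseError, match="line 2"):
            read_regions(write(tmp_path, "chr1\t1\t2\nchr1\tx\t5\n"))

    def test_duplicate_ids_rejected(self, tmp_path):
        text = "chr1\t0\t10\tpeak\nchr1\t20\t30\tpeak\n"
        with pytest.raises(BedParseError, match="peak"):
            read_regions(write(tmp_path, text))

    def test_roundtrip(self, tmp_path):
        regions = [Region("chr2", 5, 50, "a", "+"), Region("chr2", 60, 80, "b")]
        p = tmp_path / "out.bed"
        write_regions(regions, p)
        assert read_regions(p) == regions


class TestRegionInvariants:
    @pytest.mark.parametrize("start,end", [(10, 10), (10, 5), (-1, 5)])
    def test_bad_intervals_rejected(self, start, end):
        with pytest.raises(ValueError):
            Region("chr1", start, end, "r")


class TestAnnotation:
    def test_plus_strand_downstream_is_positive(self):
        # midpoint 10,100 is 100 bp into the gene body -> promoter
        regions = [Region("chr1", 10_000, 10_200, "r")]
        tss = [TSSRecord("g", "chr1", 10_000, "+")]
        (ann,) = annotate_nearest_tss(regions, tss)
        assert (ann.signed_distance, ann.location_class) == (100, "promoter")

    def test_minus_strand_sign_convention(self):
        # midpoint 9,000 with a - strand TSS at 10,000 lies 1,000 bp in the
        # reading direction: outside the promoter window, inside the 2 kb
        # gap -> unassigned
        regions = [Region("chr1", 8_900, 9_100, "r")]
        tss = [TSSRecord("g", "chr1", 10_000, "-")]
        (ann,) = annotate_nearest_tss(regions, tss)
        assert (ann.signed_distance, ann.location_class) == (1_000, "unassigned")

    def test_distal_window(self):
        regions = [Region("chr1", 59_900, 60_100, "r")]
        tss = [TSSRecord("g", "chr1", 10_000, "+")]
        (ann,) = annotate_nearest_tss(regions, tss)
        assert ann.location_class == "distal"
        assert ann.signed_distance == 50_000

    def test_beyond_100kb_unassigned(self):
        regions = [Region("chr1", 200_000, 200_200, "r")]
        tss = [TSSRecord("g", "chr1", 10_000, "+")]
        (ann,) = annotate_nearest_tss(regions, tss)
        assert ann.location_class == "unassigned"

    def test_tie_breaks_to_smallest_gene_id(self):
        regions = [Region("chr1", 4_900, 5_100, "r")]  # midpoint 5,000
        tss = [
            TSSRecord("gB", "chr1", 4_000, "+"),
            TSSRecord("gA", "chr1", 6_000, "+"),
        ]
        (ann,) = annotate_nearest_tss(regions, tss)
        assert ann.gene_id == "gA"

    def test_chromosome_without_tss_unassigned(self):
        regions = [Region("chrX", 0, 100, "r")]
        tss = [TSSRecord("g", "chr1", 10, "+")]
        (ann,) = annotate_nearest_tss(regions, tss)
        assert ann.location_class == "unassigned"
        assert ann.gene_id is None

    def test_classes_partition_random_regions(self):
        rng = np.random.default_rng(0)
        regions = [
            Region("chr1", int(s), int(s) + 200, f"r{i}")
            for i, s in enumerate(rng.integers(0, 300_000, 200))
        ]
        tss = [
            TSSRecord(f"g{i}", "chr1", int(p), str(rng.choice(["+", "-"])))
            for i, p in enumerate(sorted(rng.integers(0, 300_000, 20)))
        ]
        anns = annotate_nearest_tss(regions, tss)
        assert len(anns) == len(regions)
        assert all(
            a.location_class in ("promoter", "distal", "unassigned")
            for a in anns
        )

    def test_mirrored_genome_gives_mirrored_classes(self):
        # reflecting all coordinates and flipping strands preserves the
        # strand-aware promoter geometry
        size = 1_000_000
        rng = np.random.default_rng(1)
        regions = [
            Region("chr1", int(s), int(s) + 300, f"r{i}")
            for i, s in enumerate(rng.integers(0, size - 300, 150))
        ]
        tss = [
            TSSRecord(f"g{i}", "chr1", int(p), str(rng.choice(["+", "-"])))
            for i, p in enumerate(rng.integers(0, size, 15))
        ]
        fwd = annotate_nearest_tss(regions, tss)
        m_regions = [
            Region("chr1", size - r.end, size - r.start, r.id) for r in regions
        ]
        flip = {"+": "-", "-": "+"}
        m_tss = [
            TSSRecord(t.gene_id, "chr1", size - 1 - t.tss, flip[t.strand])
            for t in tss
        ]
        mir = annotate_nearest_tss(m_regions, m_tss)
        # mirrored midpoints shift by one for even-length regions; allow the
        # class to differ only at exact window boundaries
        n_same = sum(
            a.location_class == b.location_class for a, b in zip(fwd, mir)
        )
        assert n_same >= len(fwd) - 2


class TestClassifyDistance:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (-2500, "promoter"),
            (500, "promoter"),
            (501, "unassigned"),
            (-2501, "distal"),
            (2000, "unassigned"),
            (2001, "distal"),
            (100_000, "distal"),
            (100_001, "unassigned"),
        ],
    )
    def test_window_boundaries(self, d, expected):
        assert classify_distance(d) == expected


class TestOverlapPairs:
    def test_half_open_adjacency_is_not_overlap(self):
        a = [Region("chr1", 0, 10, "a")]
        b = [Region("chr1", 10, 20, "b")]
        assert overlap_pairs(a, b) == []

    def test_contained_interval(self):
        a = [Region("chr1", 0, 10, "a")]
        b = [Region("chr1", 5, 8, "b")]
        assert overlap_pairs(a, b) == [("a", "b", 3)]

    def test_matches_brute_force_and_is_symmetric(self):
        rng = np.random.default_rng(2)
        def random_set(prefix, n):
            out = []
            for i in range(n):
                s = int(rng.integers(0, 500))
                out.append(
                    Region("chr1", s, s + int(rng.integers(1, 80)), f"{prefix}{i}")
                )
            return out

        for _ in range(20):
            a, b = random_set("a", 8), random_set("b", 8)
            expected = sorted(
                (x.id, y.id, min(x.end, y.end) - max(x.start, y.start))
                for x in a
                for y in b
                if min(x.end, y.end) - max(x.start, y.start) >= 1
            )
            assert sorted(overlap_pairs(a, b)) == expected
            assert len(overlap_pairs(a, b)) == len(overlap_pairs(b, a))


class TestReadTSS:
    def test_tsv_and_gtf_inputs(self, tmp_path):
        tsv = write(tmp_path, "gene_id\tchrom\ttss\tstrand\ng1\tchr1\t99\t+\n", "t.tsv")
        assert read_tss(tsv) == [TSSRecord("g1", "chr1", 99, "+")]
        gtf = write(
            tmp_path,
            'chr1\tsrc\tgene\t100\t500\t.\t-\t.\tgene_id "g2";\n',
            "t.gtf",
        )
        assert read_tss(gtf) == [TSSRecord("g2", "chr1", 499, "-")]

    def test_duplicate_gene_rejected(self, tmp_path):
        p = write(tmp_path, "g1\tchr1\t5\t+\ng1\tchr1\t9\t+\n", "d.tsv")
        with pytest.raises(ValueError, match="g1"):
            read_tss(p)
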