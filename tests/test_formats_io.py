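import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from znfpipe import (
    ArrayTrack,
    GeneModel,
    GenomicInterval,
    ParseError,
    Peak,
    PeakSet,
    TagLibrary,
    ValidationError,
    read_array_track,
    read_bed,
    read_gene_table,
    read_tags,
    write_array_track,
    write_bed,
    write_gene_table,
    write_tags,
)

from conftest import random_peakset


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "chrom,start,end",
        [("chr1", -1, 10), ("chr1", 10, 10), ("chr1", 10, 5), ("", 0, 10)],
    )
    def test_invariants_rejected(self, chrom, start, end):
        with pytest.raises(ValidationError):
            GenomicInterval(chrom, start, end)

    def test_one_based_round_trip_is_identity(self):
        """Converting half-open to 1-based inclusive and back changes nothing."""
        iv = GenomicInterval("chr2", 99, 250)
        start_1b, end_1b = iv.start + 1, iv.end  # 1-based inclusive
        assert GenomicInterval(iv.chrom, start_1b - 1, end_1b) == iv


class TestBed:
    def test_read_sorts_chromosomes_and_starts(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr19\t0\t100\nchr19\t200\t300\nchr1\t0\t50\n")
        ps = read_bed(p)
        assert [pk.interval.chrom for pk in ps] == ["chr1", "chr19", "chr19"]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert len(read_bed(p)) == 0

    def test_unsorted_input_matches_sort_oracle(self, tmp_path, rng):
        records = [
            (c, int(s), int(s) + 80, float(h))
            for c, s, h in zip(
                rng.choice(["chr3", "chr1", "chr2"], 30),
                np.arange(30) * 1000 + rng.integers(0, 100, 30),
                rng.normal(size=30),
            )
        ]
        p = tmp_path / "u.bed"
        p.write_text(
            "".join(f"{c}\t{s}\t{e}\tx\t{h}\n" for c, s, e, h in records)
        )
        ps = read_bed(p)
        oracle = sorted((c, s) for c, s, _, _ in records)
        assert [(pk.interval.chrom, pk.interval.start) for pk in ps] == oracle

    def test_round_trip_intervals_and_heights(self, tmp_path, rng):
        ps = random_peakset(rng, 40)
        out = tmp_path / "rt.bed"
        write_bed(ps, out)
        back = read_bed(out)
        assert [p.interval for p in back] == [p.interval for p in ps]
        # heights printed with 6 significant digits
        for a, b in zip(back, ps):
            assert a.height == pytest.approx(b.height, rel=1e-5)
        # ranks recomputed from heights
        by_rank = back.by_rank()
        assert all(
            by_rank[i].height >= by_rank[i + 1].height
            for i in range(len(by_rank) - 1)
        )

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\nchr1\tzzz\t200\n")
        with pytest.raises(ParseError, match=":2"):
            read_bed(p)

    def test_start_ge_end_rejected(self, tmp_path):
        p = tmp_path / "inv.bed"
        p.write_text("chr1\t100\t100\n")
        with pytest.raises(ValidationError):
            read_bed(p)


class TestPeakSet:
    def test_overlapping_peaks_rejected(self):
        with pytest.raises(ValidationError):
            PeakSet.from_intervals(
                "x",
                [GenomicInterval("c", 0, 100), GenomicInterval("c", 50, 150)],
            )

    def test_ranks_are_permutation(self, rng):
        ps = random_peakset(rng, 30)
        assert sorted(p.rank for p in ps) == list(range(1, len(ps) + 1))


class TestTracksTagsGenes:
    def test_tag_round_trip_and_depth(self, tmp_path):
        lib = TagLibrary(
            chroms=np.array(["chr1"] * 5, object),
            starts=np.arange(5) * 10,
            strands=np.array(["+", "-", "+", "-", "+"], object),
        )
        out = tmp_path / "t.tags"
        write_tags(lib, out)
        back = read_tags(out)
        assert back.depth == 5
        assert list(back.starts) == list(lib.starts)

    def test_unknown_strand_rejected(self, tmp_path):
        p = tmp_path / "bad.tags"
        p.write_text("chr1\t100\t*\n")
        with pytest.raises(ParseError):
            read_tags(p)

    def test_array_track_reorders_probes(self, tmp_path, rng):
        starts = rng.permutation(50) * 100
        p = tmp_path / "a.track"
        p.write_text(
            "".join(f"chrX\t{s}\t{s + 50}\t{s / 1000}\n" for s in starts)
        )
        t = read_array_track(p)
        got = t.probes["chrX"][0]
        assert list(got) == sorted(starts)

    def test_array_track_round_trip(self, tmp_path, rng):
        starts = np.arange(30, dtype=np.int64) * 100
        track = ArrayTrack(
            probes={"chr5": (starts, starts + 50, rng.normal(size=30))}
        )
        out = tmp_path / "rt.track"
        write_array_track(track, out)
        back = read_array_track(out)
        np.testing.assert_array_equal(back.probes["chr5"][0], starts)
        np.testing.assert_allclose(
            back.probes["chr5"][2], track.probes["chr5"][2]
        )

    def test_gene_table_round_trip(self, tmp_path):
        genes = [
            GeneModel(
                "g1",
                GenomicInterval("chr1", 0, 1000),
                "+",
                [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)],
                is_c2h2=True,
                finger_count=7,
                has_krab=True,
            )
        ]
        out = tmp_path / "g.tsv"
        write_gene_table(genes, out)
        back = read_gene_table(out)
        assert back[0] == genes[0]
        assert len(back[0].exons) == 2

    def test_missing_attribute_columns_warn_and_default(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(
            "gene_id\tchrom\tstrand\ttx_start\ttx_end\texon_starts\texon_ends\n"
            "g1\tchr1\t+\t0\t500\t0,300\t100,500\n"
        )
        with pytest.warns(UserWarning, match="defaulting"):
            genes = read_gene_table(p)
        assert genes[0].is_c2h2 is False and genes[0].finger_count == 0

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValidationError):
            GeneModel(
                "g",
                GenomicInterval("chr1", 0, 500),
                "+",
                [GenomicInterval("chr1", 0, 200), GenomicInterval("chr1", 100, 300)],
            )

    def test_final_exon_is_strandwise(self):
        exons = [GenomicInterval("c", 0, 100), GenomicInterval("c", 200, 300)]
        plus = GeneModel("p", GenomicInterval("c", 0, 300), "+", exons)
        minus = GeneModel("m", GenomicInterval("c", 0, 300), "-", exons)
        assert plus.final_exon.start == 200
        assert minus.final_exon.start == 0
        assert plus.tss == 0 and minus.tss == 299


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["chr1", "chr2"]),
            st.integers(0, 10_000),
            st.integers(1, 500),
            st.floats(-50, 50, allow_nan=False),
        ),
        min_size=0,
        max_size=30,
    )
)
def test_bed_round_trip_property(tmp_path_factory, raw):
    """read_bed(write_bed(x)) reproduces intervals for any disjointified set."""
    # disjointify per chromosome by re-spacing
    per_chrom: dict[str, int] = {}
    intervals, heights = [], []
    for chrom, _, width, h in sorted(raw):
        start = per_chrom.get(chrom, 0)
        intervals.append(GenomicInterval(chrom, start, start + width))
        heights.append(round(h, 3))
        per_chrom[chrom] = start + width + 10
    ps = PeakSet.from_intervals("prop", intervals, heights)
    out = tmp_path_factory.mktemp("bed") / "p.bed"
    write_bed(ps, out)
    back = read_bed(out)
    assert [p.interval for p in back] == [p.interval for p in ps]
    assert [p.height for p in back] == pytest.approx([p.height for p in ps])
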