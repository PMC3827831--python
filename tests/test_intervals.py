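"""Interval algebra, coverage pileup, and file round-trips."""

import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import bool_mask, mask_to_intervals
from mosaicmeth import (
    CoverageTrack,
    GeneModel,
    GenomeLayout,
    IntervalSet,
    merge_intervals,
    overlap_fraction,
    pileup_coverage,
    read_bed,
    read_bed_records,
    read_bedgraph,
    read_fasta,
    read_gene_models,
    subtract_intervals,
    write_bed,
    write_bed_records,
    write_bedgraph,
    write_fasta,
    write_gff3,
)


def iset(*ivs, contig="c"):
    return merge_intervals({contig: list(ivs)})


class TestMerge:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([(0, 10), (5, 20)], [(0, 20)]),
            ([], []),
            ([(0, 10), (10, 20)], [(0, 20)]),  # half-open adjacency merges
            ([(30, 40), (0, 10), (9, 12)], [(0, 12), (30, 40)]),
        ],
    )
    def test_examples(self, raw, expected):
        assert iset(*raw).get("c").tolist() == [list(t) for t in expected]

    def test_rejects_empty_interval(self):
        with pytest.raises(ValueError, match=r"\[5, 5\)"):
            merge_intervals({"c": [(5, 5)]})

    def test_rejects_out_of_bounds(self):
        layout = GenomeLayout(contigs=(("c", 100),))
        with pytest.raises(ValueError, match="outside contig bounds"):
            merge_intervals({"c": [(50, 150)]}, layout=layout)
        with pytest.raises(ValueError, match="unknown contig"):
            merge_intervals({"nope": [(0, 10)]}, layout=layout)


class TestSubtract:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([(0, 1000)], [(200, 300)], [(0, 200), (300, 1000)]),
            ([(0, 100)], [], [(0, 100)]),
            ([(0, 100)], [(0, 100)], []),
        ],
    )
    def test_examples(self, a, b, expected):
        res = subtract_intervals(iset(*a), iset(*b))
        assert res.get("c").tolist() == [list(t) for t in expected]

    def test_mismatched_contigs_error(self):
        with pytest.raises(ValueError, match="missing"):
            subtract_intervals(iset((0, 10)), merge_intervals({"other": [(0, 5)]}))


class TestOverlapFraction:
    def test_half_overlap(self):
        assert overlap_fraction(("c", 1000, 2000), iset((900, 1500))) == 0.5

    def test_contained_and_disjoint(self):
        assert overlap_fraction(("c", 100, 200), iset((0, 1000))) == 1.0
        assert overlap_fraction(("c", 100, 200), iset((5000, 6000))) == 0.0

    def test_zero_length_span_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            overlap_fraction(("c", 10, 10), iset((0, 100)))

    def test_monotone_under_domain_growth(self):
        span = ("c", 100, 400)
        small = iset((150, 200))
        big = iset((150, 200), (300, 420))
        assert overlap_fraction(span, big) >= overlap_fraction(span, small)


intervals_strategy = st.lists(
    st.tuples(st.integers(0, 999), st.integers(1, 1000)).map(
        lambda t: (min(t[0], t[1] - 1), max(t[0] + 1, t[1]))
    ),
    max_size=50,
)


class TestBooleanArrayOracle:
    """merge/subtract/intersect agree base-by-base with boolean arrays."""

    @given(intervals_strategy)
    def test_merge(self, raw):
        got = merge_intervals({"c": raw}).get("c").tolist()
        expected = mask_to_intervals(bool_mask(raw, 1000))
        assert got == [list(t) for t in expected]

    @given(intervals_strategy, intervals_strategy)
    def test_subtract_and_intersect(self, raw_a, raw_b):
        a, b = iset(*raw_a), iset(*raw_b)
        ma, mb = bool_mask(raw_a, 1000), bool_mask(raw_b, 1000)
        assert a.subtract(b).get("c").tolist() == [
            list(t) for t in mask_to_intervals(ma & ~mb)
        ]
        assert a.intersect(b).get("c").tolist() == [
            list(t) for t in mask_to_intervals(ma & mb)
        ]

    @given(intervals_strategy)
    def test_complement_partitions_contig(self, raw):
        layout = GenomeLayout(contigs=(("c", 1000),))
        a = iset(*raw)
        comp = a.complement(layout)
        assert a.total_bp + comp.total_bp == 1000
        assert a.intersect(comp).total_bp == 0


class TestPileup:
    def test_step_pattern(self):
        layout = GenomeLayout(contigs=(("c", 100),))
        track = pileup_coverage({"c": [(0, 5), (3, 8)]}, layout)
        s, e, d = track.get("c")
        assert s.tolist() == [0, 3, 5]
        assert e.tolist() == [3, 5, 8]
        assert d.tolist() == [1, 2, 1]

    def test_no_reads_gives_empty_track(self):
        layout = GenomeLayout(contigs=(("c", 100),))
        track = pileup_coverage({"c": []}, layout)
        assert track.get("c")[0].size == 0
        assert (track.depth_at("c", np.arange(100)) == 0).all()

    def test_identical_reads_stack(self):
        layout = GenomeLayout(contigs=(("c", 100),))
        track = pileup_coverage({"c": [(10, 20)] * 3}, layout)
        s, e, d = track.get("c")
        assert (s.tolist(), e.tolist(), d.tolist()) == ([10], [20], [3])

    def test_out_of_bounds_reads_dropped_with_warning(self, caplog):
        layout = GenomeLayout(contigs=(("c", 100),))
        with caplog.at_level("WARNING", logger="mosaicmeth"):
            track = pileup_coverage({"c": [(0, 10), (90, 110)]}, layout)
        assert "dropped 1" in caplog.text
        assert track.total_depth_bp() == 10

    @given(
        st.lists(
            st.tuples(st.integers(0, 180), st.integers(1, 40)).map(
                lambda t: (t[0], min(t[0] + t[1], 200))
            ),
            max_size=30,
        )
    )
    def test_depth_weighted_length_equals_read_lengths(self, reads):
        layout = GenomeLayout(contigs=(("c", 200),))
        track = pileup_coverage({"c": reads}, layout)
        assert track.total_depth_bp() == sum(e - s for s, e in reads)
        # per-base agreement with a direct count
        pos = np.arange(200)
        direct = np.zeros(200, dtype=int)
        for s, e in reads:
            direct[s:e] += 1
        assert (track.depth_at("c", pos) == direct).all()


class TestRoundTrips:
    def test_bed(self, tmp_path):
        original = merge_intervals(
            {"chr1": [(100, 200), (500, 700)], "chr2": [(0, 50)]}
        )
        p = tmp_path / "x.bed"
        write_bed(original, p, header="test")
        assert read_bed(p) == original

    def test_bed_line_format(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t100\t200\n")
        assert read_bed(p).get("chr1").tolist() == [[100, 200]]

    def test_bed_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t100\t200\nchr1\toops\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(p)

    def test_bed_records_preserves_duplicates(self, tmp_path):
        reads = {"c": np.array([[0, 36], [0, 36], [10, 46]])}
        p = tmp_path / "reads.bed"
        write_bed_records(reads, p)
        back = read_bed_records(p)
        assert back["c"].tolist() == reads["c"].tolist()

    def test_bedgraph(self, tmp_path):
        track = CoverageTrack.from_runs({"c": [(0, 10, 3), (10, 20, 1), (50, 60, 7)]})
        p = tmp_path / "x.bg"
        write_bedgraph(track, p, header="test")
        assert read_bedgraph(p) == track

    def test_fasta(self, tmp_path):
        seqs = {"c1": "ACGTACGTAC" * 13, "c2": "TTTTGGGG"}
        p = tmp_path / "g.fa"
        write_fasta(seqs, p, width=60)
        assert read_fasta(p) == seqs

    def test_gff3_round_trip_and_coordinates(self, tmp_path):
        genes = [
            GeneModel("gA", "chr1", "+", 100, 2000, 250, 1800),
            GeneModel("gB", "chr1", "-", 3000, 5000, 3200, 4800, isoform_count=3,
                      expression_class="stable"),
        ]
        p = tmp_path / "g.gff3"
        write_gff3(genes, p)
        back = read_gene_models(p, format="gff3")
        assert back == genes
        # 1-based closed on disk: gene at 101..2000 is span [100, 2000)
        line = next(l for l in p.read_text().splitlines() if "\tgene\t" in l)
        assert line.split("\t")[3:5] == ["101", "2000"]

    def test_bed12_thick_is_cds(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t100\t2000\tgA\t0\t+\t250\t1800\n")
        (gene,) = read_gene_models(p, format="bed12")
        assert (gene.span_start, gene.span_end) == (100, 2000)
        assert (gene.cds_start, gene.cds_end) == (250, 1800)
        assert gene.tss == 100

    def test_unknown_strand_rejected(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t100\t2000\tgA\t0\t.\t250\t1800\n")
        with pytest.raises(ValueError, match="strand"):
            read_gene_models(p, format="bed12")


class TestGeneModel:
    def test_strand_aware_ends(self):
        plus = GeneModel("g", "c", "+", 100, 200, 120, 180)
        minus = GeneModel("g", "c", "-", 100, 200, 120, 180)
        assert (plus.tss, plus.polya_site) == (100, 199)
        assert (minus.tss, minus.polya_site) == (199, 100)

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            GeneModel("g", "c", "*", 0, 10, 0, 10)
        with pytest.raises(ValueError, match="CDS"):
            GeneModel("g", "c", "+", 100, 200, 50, 180)
        with pytest.raises(ValueError, match="expression class"):
            GeneModel("g", "c", "+", 0, 10, 0, 10, expression_class="larval")


def test_merge_subtract_agree_with_bedtools(tmp_path):
    """Cross-check against an independent interval engine on one fixture."""
    rng = np.random.default_rng(5)
    raw_a = [(int(s), int(s) + int(l)) for s, l in zip(rng.integers(0, 900, 40), rng.integers(1, 120, 40))]
    raw_b = [(int(s), int(s) + int(l)) for s, l in zip(rng.integers(0, 900, 40), rng.integers(1, 120, 40))]
    a, b = iset(*raw_a), iset(*raw_b)
    bed_a, bed_b = tmp_path / "a.bed", tmp_path / "b.bed"
    write_bed(a, bed_a)
    write_bed(b, bed_b)
    out = subprocess.run(
        ["bedtools", "subtract", "-a", bed_a, "-b", bed_b],
        capture_output=True, text=True, check=True,
    ).stdout
    expected = [
        [int(f[1]), int(f[2])] for f in (l.split("\t") for l in out.splitlines())
    ]
    assert subtract_intervals(a, b).get("c").tolist() == expected
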