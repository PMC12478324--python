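"""Junction parsing, merging, filtering, strand assignment and orientation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spliceshape import (
    SJParseError,
    AnnotationError,
    assign_strand,
    filter_min_samples,
    junction_sites,
    merge_samples,
    parse_sj_tab,
    write_sj_tab,
)
from spliceshape.junctions import Junction

from conftest import make_junction


class TestParseSjTab:
    def test_maps_star_fields(self, sj_file):
        path = sj_file(["chr1\t100\t200\t1\t1\t0\t25\t3\t38"])
        (j,) = parse_sj_tab(path)
        assert (j.chrom, j.intron_start, j.intron_end) == ("chr1", 100, 200)
        assert j.strand == "+"
        assert j.unique_reads == 25  # multimapping column ignored
        assert j.max_overhang == 38
        assert j.n_samples == 1

    def test_strand_codes(self, sj_file):
        path = sj_file(
            [
                "chr1\t10\t20\t0\t0\t0\t1\t0\t5",
                "chr1\t30\t40\t2\t0\t0\t1\t0\t5",
            ]
        )
        j0, j1 = parse_sj_tab(path)
        assert j0.strand == "?"
        assert j1.strand == "-"

    def test_empty_file(self, sj_file):
        assert parse_sj_tab(sj_file([])) == []

    @pytest.mark.parametrize(
        "bad_line",
        [
            "chr1\t100\t200\t1\t1",  # 5 fields
            "chr1\tx\t200\t1\t1\t0\t25\t3\t38",  # non-integer coordinate
            "chr1\t100\t200\t1\t1\t0\t-5\t3\t38",  # negative count
            "chr1\t300\t200\t1\t1\t0\t5\t3\t38",  # start > end
        ],
    )
    def test_malformed_line_names_line_number(self, sj_file, bad_line):
        path = sj_file(["chr1\t10\t20\t1\t0\t0\t2\t0\t9", bad_line])
        with pytest.raises(SJParseError, match=":2"):
            parse_sj_tab(path)

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 10_000),
                st.integers(1, 500),
                st.sampled_from("+-?"),
                st.integers(0, 10_000),
                st.integers(0, 100),
            ),
            min_size=0,
            max_size=30,
        )
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_write_parse_round_trip(self, specs):
        import tempfile
        from pathlib import Path

        junctions = [
            Junction("chr1", s, s + length, strand, reads, 1, ovh, star_strand=strand)
            for s, length, strand, reads, ovh in specs
        ]
        with tempfile.TemporaryDirectory() as td:
            path = Path(td) / "sj.tab"
            write_sj_tab(junctions, path)
            parsed = parse_sj_tab(path)
        assert [(j.key, j.strand, j.unique_reads, j.max_overhang) for j in parsed] == [
            (j.key, j.strand, j.unique_reads, j.max_overhang) for j in junctions
        ]


class TestMergeSamples:
    def test_counts_summed_and_samples_counted(self):
        s1 = [make_junction(reads=10)]
        s2 = [make_junction(reads=15)]
        (m,) = merge_samples([s1, s2])
        assert m.unique_reads == 25
        assert m.n_samples == 2

    def test_present_in_one_of_three(self):
        s1 = [make_junction(reads=4)]
        (m,) = merge_samples([s1, [], []])
        assert m.n_samples == 1

    def test_disjoint_union(self):
        s1 = [make_junction(start=100, end=200)]
        s2 = [make_junction(start=300, end=400)]
        merged = merge_samples([s1, s2])
        assert len(merged) == 2
        assert all(m.n_samples == 1 for m in merged)

    def test_zero_read_record_not_a_detection(self):
        s1 = [make_junction(reads=0)]
        s2 = [make_junction(reads=5)]
        (m,) = merge_samples([s1, s2])
        assert m.n_samples == 1

    def test_max_overhang_is_maximum(self):
        s1 = [make_junction(reads=1, max_overhang=12)]
        s2 = [make_junction(reads=1, max_overhang=40)]
        (m,) = merge_samples([s1, s2])
        assert m.max_overhang == 40

    @given(st.permutations(list(range(4))))
    @settings(max_examples=24, derandomize=True, deadline=None)
    def test_permutation_invariant(self, order):
        samples = [
            [make_junction(start=100, end=200, reads=5 + i)] if i % 2 == 0 else
            [make_junction(start=300, end=400, reads=2 * i + 1)]
            for i in range(4)
        ]
        base = merge_samples(samples)
        permuted = merge_samples([samples[i] for i in order])
        assert [(j.key, j.unique_reads, j.n_samples) for j in base] == [
            (j.key, j.unique_reads, j.n_samples) for j in permuted
        ]


class TestFilterMinSamples:
    def test_default_threshold_removes_rare_junction(self):
        js = [make_junction(n_samples=2), make_junction(start=300, end=400, n_samples=5)]
        kept = filter_min_samples(js, 3)
        assert [j.intron_start for j in kept] == [300]

    def test_min_one_is_identity(self):
        js = [make_junction(n_samples=1), make_junction(start=5, end=9, n_samples=4)]
        assert filter_min_samples(js, 1) == js

    def test_monotone_in_threshold(self):
        js = [make_junction(start=i, end=i + 50, n_samples=n)
              for i, n in zip(range(1, 600, 100), (1, 2, 3, 4, 5, 6))]
        sizes = [len(filter_min_samples(js, t)) for t in range(1, 8)]
        assert sizes == sorted(sizes, reverse=True)


class TestAssignStrand:
    def test_strand_from_containing_gene(self, gtf_file):
        gtf = gtf_file([("chr1", 1, 1000, "+", "G1")])
        j = make_junction(strand="?", star_strand="?")
        retained, report = assign_strand([j], gtf)
        assert retained[0].strand == "+"
        assert report.retained == 1 and report.discarded == 0

    def test_conflicting_gene_strands_discarded(self, gtf_file):
        gtf = gtf_file([("chr1", 1, 1000, "+", "G1"), ("chr1", 1, 1000, "-", "G2")])
        retained, report = assign_strand([make_junction()], gtf)
        assert retained == []
        assert report.conflicting == 1

    def test_intergenic_discarded(self, gtf_file):
        gtf = gtf_file([("chr2", 1, 1000, "+", "G1")])
        retained, report = assign_strand([make_junction(chrom="chr1")], gtf)
        assert retained == []
        assert report.intergenic == 1

    def test_partial_overlap_is_not_containment(self, gtf_file):
        gtf = gtf_file([("chr1", 1, 150, "+", "G1")])
        retained, report = assign_strand([make_junction(start=100, end=200)], gtf)
        assert report.intergenic == 1

    def test_agreeing_genes_retained_and_counts_add_up(self, gtf_file):
        gtf = gtf_file(
            [("chr1", 1, 1000, "-", "G1"), ("chr1", 50, 900, "-", "G2"),
             ("chr1", 2000, 3000, "+", "G3")]
        )
        js = [make_junction(strand="?", star_strand="?"),
              make_junction(start=1500, end=1600, strand="?", star_strand="?"),
              make_junction(start=2100, end=2200, strand="?", star_strand="?")]
        retained, report = assign_strand(js, gtf)
        assert {j.strand for j in retained} == {"-", "+"}
        assert report.retained + report.discarded == len(js)

    def test_aligner_disagreement_counted_but_gtf_wins(self, gtf_file):
        gtf = gtf_file([("chr1", 1, 1000, "-", "G1")])
        retained, report = assign_strand([make_junction(strand="+")], gtf)
        assert retained[0].strand == "-"
        assert report.star_disagreements == 1

    def test_missing_gtf_is_input_error(self, tmp_path):
        with pytest.raises(AnnotationError):
            assign_strand([make_junction()], tmp_path / "nope.gtf")

    def test_gtf_without_genes_is_input_error(self, tmp_path):
        p = tmp_path / "empty.gtf"
        p.write_text("")
        with pytest.raises(AnnotationError):
            assign_strand([make_junction()], p)


class TestJunctionSites:
    def test_plus_strand_donor_left(self):
        donor, acceptor = junction_sites(make_junction(strand="+"))
        assert (donor.position, acceptor.position) == (100, 200)
        assert (donor.role, acceptor.role) == ("donor", "acceptor")

    def test_minus_strand_donor_right(self):
        donor, acceptor = junction_sites(make_junction(strand="-"))
        assert (donor.position, acceptor.position) == (200, 100)

    def test_sites_share_chrom_and_strand(self):
        for strand in "+-":
            donor, acceptor = junction_sites(make_junction(strand=strand))
            assert donor.chrom == acceptor.chrom
            assert donor.strand == acceptor.strand == strand

    def test_unresolved_strand_rejected(self):
        with pytest.raises(ValueError):
            junction_sites(make_junction(strand="?", star_strand="?"))
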