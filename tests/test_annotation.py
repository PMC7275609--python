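"""Gene-model parsing and splicing-event catalog construction."""

import pytest

from splicemark.annotation import (
    AnnotationError,
    GenomicInterval,
    Junction,
    build_cassette_events,
    build_site_groups,
    classify_terminal_events,
    junction_between,
    read_gene_models,
    transcript_junctions,
    write_refflat,
)
from .conftest import make_gene


class TestReadGeneModels:
    def test_refflat_three_exon_transcript(self, tmp_path):
        # hand-constructed refFlat line; coordinates are already 0-based
        line = (
            "G1\ttx1\tchr1\t+\t100\t600\t100\t600\t3\t"
            "100,300,500,\t200,400,600,\n"
        )
        path = tmp_path / "anno.refflat"
        path.write_text(line)
        models = read_gene_models(path, dialect="refflat")
        exons = models["G1"].transcripts["tx1"]
        assert [(e.start, e.end) for e in exons] == [
            (100, 200), (300, 400), (500, 600)
        ]

    def test_gtf_converts_one_based_inclusive(self, tmp_path):
        gtf = (
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\t'
            'gene_id "G1"; transcript_id "tx1";\n'
        )
        path = tmp_path / "anno.gtf"
        path.write_text(gtf)
        models = read_gene_models(path, dialect="gtf")
        (exon,) = models["G1"].transcripts["tx1"]
        assert (exon.start, exon.end) == (100, 200)

    def test_empty_file_gives_empty_collection(self, tmp_path):
        path = tmp_path / "empty.gtf"
        path.write_text("")
        assert read_gene_models(path, dialect="gtf") == {}

    def test_gtf_end_before_start_names_line(self, tmp_path):
        gtf = (
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\t'
            'gene_id "G1"; transcript_id "tx1";\n'
            'chr1\tsrc\texon\t300\t250\t.\t+\t.\t'
            'gene_id "G1"; transcript_id "tx1";\n'
        )
        path = tmp_path / "bad.gtf"
        path.write_text(gtf)
        with pytest.raises(AnnotationError, match="line 2"):
            read_gene_models(path, dialect="gtf")

    def test_unknown_dialect_rejected(self, tmp_path):
        path = tmp_path / "anno.bed"
        path.write_text("")
        with pytest.raises(AnnotationError, match="dialect"):
            read_gene_models(path, dialect="bed")

    def test_refflat_round_trip(self, tmp_path, cassette_gene):
        models = {"G1": cassette_gene}
        path = tmp_path / "out.refflat"
        write_refflat(models, path)
        back = read_gene_models(path, dialect="refflat")
        assert back["G1"].transcripts == cassette_gene.transcripts


class TestJunction:
    def test_strand_orientation_of_sites(self):
        plus = Junction.from_intron("chr1", 200, 500, "+")
        assert (plus.donor_site, plus.acceptor_site) == (199, 500)
        minus = Junction.from_intron("chr1", 200, 500, "-")
        assert (minus.donor_site, minus.acceptor_site) == (500, 199)
        # intron coordinates survive the round trip on both strands
        for j in (plus, minus):
            assert (j.intron_start, j.intron_end) == (200, 500)

    def test_order_invariant_enforced(self):
        with pytest.raises(AnnotationError):
            Junction("chr1", 500, 200, "+")
        with pytest.raises(AnnotationError):
            Junction("chr1", 200, 500, "-")


class TestCassetteEvents:
    def test_single_middle_exon_difference_yields_one_event(self, cassette_gene):
        events = build_cassette_events({"G1": cassette_gene})
        assert len(events) == 1
        ev = events[0]
        assert (ev.alt_exon.start, ev.alt_exon.end) == (300, 400)
        # the skip junction joins the two flanking exons
        assert ev.skip_junction == junction_between(
            GenomicInterval("chr1", 100, 200, "+"),
            GenomicInterval("chr1", 500, 600, "+"),
            "+",
        )
        assert ev.upstream_junction.donor_site == ev.skip_junction.donor_site
        assert ev.downstream_junction.acceptor_site == ev.skip_junction.acceptor_site

    def test_single_transcript_gene_yields_nothing(self):
        gene = make_gene("G1", "chr1", "+", {"tx": [(0, 10), (20, 30), (40, 50)]})
        assert build_cassette_events({"G1": gene}) == []

    def test_two_independent_middle_exons_yield_two_events(self):
        gene = make_gene(
            "G1",
            "chr1",
            "+",
            {
                "tx_full": [(0, 10), (20, 30), (40, 50), (60, 70), (80, 90)],
                "tx_skip2": [(0, 10), (40, 50), (60, 70), (80, 90)],
                "tx_skip4": [(0, 10), (20, 30), (40, 50), (80, 90)],
            },
        )
        events = build_cassette_events({"G1": gene})
        assert len(events) == 2
        assert {(e.alt_exon.start, e.alt_exon.end) for e in events} == {
            (20, 30), (60, 70)
        }

    def test_minus_strand_event_satisfies_shared_site_invariants(self):
        gene = make_gene(
            "G1",
            "chr1",
            "-",
            {
                "tx_inc": [(100, 200), (300, 400), (500, 600)],
                "tx_skip": [(100, 200), (500, 600)],
            },
        )
        (ev,) = build_cassette_events({"G1": gene})
        # invariant checks live in CassetteEvent.__post_init__; on the minus
        # strand the donor is the genomically rightmost site
        assert ev.skip_junction.donor_site == 500
        assert ev.upstream_junction.donor_site == 500


class TestSiteGroups:
    def test_one_donor_three_acceptors(self):
        juncs = [Junction.from_intron("chr1", 100, e, "+") for e in (200, 300, 400)]
        groups = build_site_groups(juncs)
        donor_groups = [g for g in groups if g.side == "donor"]
        assert len(donor_groups) == 1
        assert len(donor_groups[0].members) == 3
        assert [g for g in groups if g.side == "acceptor"] == []

    def test_all_distinct_sites_gives_empty_list(self):
        juncs = [
            Junction.from_intron("chr1", 100, 200, "+"),
            Junction.from_intron("chr1", 300, 400, "+"),
        ]
        assert build_site_groups(juncs) == []

    def test_cd44_like_topology(self):
        # E5->v8, E5->E16 share a donor; v10->E16, E5->E16 share an acceptor
        e5_v8 = Junction.from_intron("chr1", 1000, 2000, "+")
        e5_e16 = Junction.from_intron("chr1", 1000, 9000, "+")
        v10_e16 = Junction.from_intron("chr1", 5000, 9000, "+")
        groups = build_site_groups([e5_v8, e5_e16, v10_e16])
        by_side = {g.side: set(g.members) for g in groups}
        assert by_side["donor"] == {e5_v8, e5_e16}
        assert by_side["acceptor"] == {v10_e16, e5_e16}

    def test_output_is_a_partition_per_side(self):
        import itertools
        juncs = [
            Junction.from_intron("chr1", d, a, "+")
            for d, a in itertools.product((100, 300, 500), (700, 900, 1100))
        ]
        groups = build_site_groups(juncs)
        for side in ("donor", "acceptor"):
            side_groups = [g for g in groups if g.side == side]
            seen = [j for g in side_groups for j in g.members]
            assert len(seen) == len(set(seen))  # each junction in <= 1 group
            keyed = [(g.chrom, g.shared_site, g.strand) for g in side_groups]
            assert len(keyed) == len(set(keyed))


class TestTerminalEvents:
    def test_two_first_exons_one_event(self):
        # ARHGEF9-like: two transcripts starting at E1a vs E1b, both -> E3
        gene = make_gene(
            "G1",
            "chr1",
            "+",
            {
                "tx_a": [(100, 200), (900, 1000)],
                "tx_b": [(400, 500), (900, 1000)],
            },
        )
        events = classify_terminal_events({"G1": gene})
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "alternative_first"
        assert len(ev.candidates) == 2
        # every candidate is the first exon of some transcript, linked inward
        starts = {exon.start for exon, _ in ev.candidates}
        assert starts == {100, 400}

    def test_single_first_exon_no_event(self, cassette_gene):
        events = classify_terminal_events({"G1": cassette_gene})
        assert all(e.kind != "alternative_first" for e in events)

    def test_both_first_and_last_alternatives(self):
        gene = make_gene(
            "G1",
            "chr1",
            "+",
            {
                "tx_a": [(100, 200), (900, 1000)],
                "tx_b": [(400, 500), (1200, 1300)],
            },
        )
        events = classify_terminal_events({"G1": gene})
        assert {e.kind for e in events} == {
            "alternative_first", "alternative_last"
        }

    def test_minus_strand_first_exon_is_genomically_last(self):
        gene = make_gene(
            "G1",
            "chr1",
            "-",
            {
                "tx_a": [(100, 200), (900, 1000)],
                "tx_b": [(100, 200), (1200, 1300)],
            },
        )
        events = classify_terminal_events({"G1": gene})
        (first_ev,) = [e for e in events if e.kind == "alternative_first"]
        assert {exon.start for exon, _ in first_ev.candidates} == {900, 1200}


def test_transcript_junctions_count():
    gene = make_gene("G1", "chr1", "+", {"tx": [(0, 10), (20, 30), (40, 50)]})
    assert len(transcript_junctions(gene.transcripts["tx"], "+")) == 2
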