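import textwrap

import numpy as np
import pytest

from srexport.annotation import (
    AnnotationError, GenomeAnnotation, TranscriptModel, classify_exons,
    derive_regions, enumerate_apa_events, load_annotation, splice_sites,
    write_gtf,
)


def _write(tmp_path, text, name="test.gtf"):
    path = tmp_path / name
    path.write_text(textwrap.dedent(text).lstrip())
    return str(path)


GTF_BASIC = """
chr1\tsrc\tgene\t101\t400\t.\t+\t.\tgene_id "g1";
chr1\tsrc\ttranscript\t101\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\ttranscript\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t2";
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t2";
chr1\tsrc\tgene\t1001\t1400\t.\t-\t.\tgene_id "g2";
chr1\tsrc\ttranscript\t1001\t1400\t.\t-\t.\tgene_id "g2"; transcript_id "t3";
chr1\tsrc\texon\t1001\t1100\t.\t-\t.\tgene_id "g2"; transcript_id "t3";
chr1\tsrc\texon\t1301\t1400\t.\t-\t.\tgene_id "g2"; transcript_id "t3";
"""


class TestLoadAnnotation:
    def test_coordinate_conversion(self, tmp_path):
        ann = load_annotation(_write(tmp_path, GTF_BASIC))
        t1 = ann.transcripts["t1"]
        assert t1.exons[0] == (100, 200)  # GTF [101,200] -> half-open

    def test_minus_strand_transcript_order(self, tmp_path):
        ann = load_annotation(_write(tmp_path, GTF_BASIC))
        t3 = ann.transcripts["t3"]
        assert t3.exons == [(1300, 1400), (1000, 1100)]

    def test_gene_index_holds_all_isoforms(self, tmp_path):
        ann = load_annotation(_write(tmp_path, GTF_BASIC))
        assert sorted(ann.genes["g1"]) == ["t1", "t2"]

    def test_malformed_line_reports_line_number(self, tmp_path):
        bad = GTF_BASIC + "chr1\tonly\tthree\n"
        with pytest.raises(AnnotationError, match=":11"):
            load_annotation(_write(tmp_path, bad))

    def test_zero_exon_transcript_rejected(self):
        with pytest.raises(AnnotationError, match="zero exons"):
            TranscriptModel("tx", "gx", "chr1", "+", exons=[])

    def test_roundtrip_write_reload(self, tmp_path, tiny_annotation):
        path = str(tmp_path / "rt.gtf")
        write_gtf(tiny_annotation, path)
        reloaded = load_annotation(path)
        for tid, t in tiny_annotation.transcripts.items():
            r = reloaded.transcripts[tid]
            assert r.exons == t.exons
            assert r.cds == t.cds
            assert r.strand == t.strand


class TestDeriveRegions:
    def test_utr_cds_intron_partition(self):
        t = TranscriptModel("t1", "g1", "c", "+",
                            exons=[(0, 100), (200, 300)], cds=(50, 250))
        regs = derive_regions(GenomeAnnotation([t]))
        per = regs.intervals["g1"]
        assert per["five_prime_utr"] == [(0, 50)]
        assert per["cds"] == [(50, 100), (200, 250)]
        assert per["three_prime_utr"] == [(250, 300)]
        assert per["intron"] == [(100, 200)]

    def test_noncoding_gets_single_label(self):
        t = TranscriptModel("t1", "g1", "c", "+",
                            exons=[(0, 100), (200, 300)], cds=None)
        per = derive_regions(GenomeAnnotation([t])).intervals["g1"]
        assert set(per) == {"noncoding_exon", "intron"}

    def test_representative_is_longest_cds(self):
        a = TranscriptModel("tA", "g", "c", "+", exons=[(0, 300)], cds=(0, 90))
        b = TranscriptModel("tB", "g", "c", "+", exons=[(0, 300)], cds=(0, 150))
        regs = derive_regions(GenomeAnnotation([a, b]))
        assert regs.representative["g"] == "tB"

    def test_labels_partition_span(self, small_sim):
        _, genome, _ = small_sim
        regs = genome.regions
        for gid, per in regs.intervals.items():
            tid = regs.representative[gid]
            t = genome.annotation.transcripts[tid]
            total = sum(e - s for ivs in per.values() for s, e in ivs)
            span = t.span[1] - t.span[0]
            assert total == span, gid

    def test_minus_strand_utr_sides(self, tiny_annotation):
        per = derive_regions(tiny_annotation).intervals["gB"]
        # minus strand: 5'UTR genomically right of the CDS
        assert per["five_prime_utr"] == [(1380, 1400)]
        assert per["three_prime_utr"] == [(1000, 1050)]


class TestClassifyExons:
    def test_ordinals_plus_strand(self):
        exons = [(i * 200, i * 200 + 100) for i in range(5)]
        t = TranscriptModel("t", "g", "c", "+", exons=exons)
        classes = [x.ordinal_class for x in classify_exons(GenomeAnnotation([t]))]
        assert classes == ["first", "internal", "internal", "internal", "last"]

    def test_single_exon(self, tiny_annotation):
        feats = {x.exon_id: x for x in classify_exons(tiny_annotation)}
        assert feats["tC.1.E1"].ordinal_class == "single"

    def test_minus_strand_first_is_rightmost(self, tiny_annotation):
        feats = [x for x in classify_exons(tiny_annotation)
                 if x.transcript_id == "tB.1"]
        first = next(x for x in feats if x.ordinal_class == "first")
        assert first.span == (1300, 1400)

    def test_exact_partition(self, small_sim):
        _, genome, _ = small_sim
        feats = classify_exons(genome.annotation)
        total = sum(len(t.exons)
                    for t in genome.annotation.transcripts.values())
        assert len(feats) == total
        counts = {}
        for x in feats:
            counts[x.ordinal_class] = counts.get(x.ordinal_class, 0) + 1
        assert sum(counts.values()) == total


class TestSpliceSites:
    def test_plus_strand_conventions(self):
        t = TranscriptModel("t", "g", "c", "+", exons=[(0, 100), (200, 300)])
        sites = splice_sites(GenomeAnnotation([t]))
        assert ("5ss", "c", "+", 100) in sites
        assert ("3ss", "c", "+", 200) in sites

    def test_minus_strand_mirror(self):
        t = TranscriptModel("t", "g", "c", "-", exons=[(0, 100), (200, 300)])
        sites = splice_sites(GenomeAnnotation([t]))
        # upstream exon (transcript order) is (200,300): 5ss one base left
        assert ("5ss", "c", "-", 199) in sites
        assert ("3ss", "c", "-", 99) in sites

    def test_intronless_contributes_nothing(self, tiny_annotation):
        sites = splice_sites(tiny_annotation)
        assert not any(s[1] == "c" and 2000 <= s[3] < 2400 for s in sites)

    def test_deduplicated_across_isoforms(self):
        t1 = TranscriptModel("t1", "g", "c", "+", exons=[(0, 100), (200, 300)])
        t2 = TranscriptModel("t2", "g", "c", "+", exons=[(0, 100), (200, 350)])
        sites = splice_sites(GenomeAnnotation([t1, t2]))
        assert sum(1 for s in sites if s[0] == "5ss") == 1


class TestEnumerateApaEvents:
    def test_tandem_utr(self):
        long_ = TranscriptModel("tL", "g", "c", "+",
                                exons=[(0, 100), (1000, 2000)], cds=(10, 1050))
        short = TranscriptModel("tS", "g", "c", "+",
                                exons=[(0, 100), (1000, 1500)], cds=(10, 1050))
        events = enumerate_apa_events(GenomeAnnotation([long_, short]))
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "TandemUTR"
        assert ev.proximal_region == (1000, 1500)
        assert ev.distal_region == (1500, 2000)
        assert ev.isoform_ids == ("tS", "tL")

    def test_ale(self):
        a = TranscriptModel("tA", "g", "c", "+",
                            exons=[(0, 100), (1000, 1500)])
        b = TranscriptModel("tB", "g", "c", "+",
                            exons=[(0, 100), (3000, 3400)])
        events = enumerate_apa_events(GenomeAnnotation([a, b]))
        assert len(events) == 1
        assert events[0].kind == "ALE"
        assert events[0].proximal_region == (1000, 1500)
        assert events[0].distal_region == (3000, 3400)

    def test_identical_ends_no_event(self):
        a = TranscriptModel("tA", "g", "c", "+", exons=[(0, 100), (1000, 1500)])
        b = TranscriptModel("tB", "g", "c", "+", exons=[(0, 100), (1000, 1500)])
        # identical exon structures are rejected as duplicates of one model;
        # use a differing internal structure instead
        b = TranscriptModel("tB", "g", "c", "+", exons=[(0, 90), (1000, 1500)])
        events = enumerate_apa_events(GenomeAnnotation([a, b]))
        assert events == []

    def test_minus_strand_tandem(self):
        long_ = TranscriptModel("tL", "g", "c", "-",
                                exons=[(3000, 3100), (500, 2000)])
        short = TranscriptModel("tS", "g", "c", "-",
                                exons=[(3000, 3100), (1200, 2000)])
        events = enumerate_apa_events(GenomeAnnotation([long_, short]))
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "TandemUTR"
        assert ev.proximal_region == (1200, 2000)
        assert ev.distal_region == (500, 1200)
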