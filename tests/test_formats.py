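"""File IO contracts: VCF/BED/GFF parsing rules and the annotated writer."""

from __future__ import annotations

import pytest

from svannotate.annotate import AnnotationResult
from svannotate.core import SourceKind, SVType
from svannotate.formats import (
    FormatError,
    dedup_annotation_sites,
    read_bed,
    read_gff,
    read_merged_vcf,
    read_sv_vcf,
    write_annotated_vcf,
    write_merged_vcf,
)
from svannotate.merge import merge_callsets
from svannotate.synthetic import SimulationParams, simulate, write_study

HEADER = "##fileformat=VCFv4.1\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


def _vcf(tmp_path, body, name="calls.vcf"):
    path = tmp_path / name
    path.write_text(HEADER + body)
    return path


class TestReadSvVcf:
    def test_pos_and_end_converted_to_zero_based(self, tmp_path):
        path = _vcf(tmp_path, "chr1\t1000\tv1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=2000\n")
        [rec] = read_sv_vcf(path).records
        assert (rec.start, rec.end, rec.svtype) == (999, 1999, SVType.DEL)

    def test_indel_style_inference_and_min_size(self, tmp_path):
        ref = "A" * 30
        path = _vcf(tmp_path, f"chr1\t500\tv1\t{ref}\tA\t.\tPASS\t.\n")
        [rec] = read_sv_vcf(path).records
        assert (rec.svtype, rec.svlen) == (SVType.DEL, -29)
        assert len(read_sv_vcf(path, min_size=20).records) == 1
        assert len(read_sv_vcf(path, min_size=30).records) == 0

    def test_insertion_inference_from_alt_longer_than_ref(self, tmp_path):
        path = _vcf(tmp_path, "chr1\t500\tv1\tA\t" + "A" * 12 + "\t.\tPASS\t.\n")
        [rec] = read_sv_vcf(path).records
        assert (rec.svtype, rec.svlen, rec.end) == (SVType.INS, 11, rec.start)

    def test_tra_exempt_from_min_size_filter(self, tmp_path):
        path = _vcf(
            tmp_path,
            "chr1\t500\tv1\tN\t<TRA>\t.\tPASS\tSVTYPE=TRA;CHR2=chr2;END=800\n",
        )
        [rec] = read_sv_vcf(path, min_size=10**6).records
        assert (rec.svtype, rec.chrom2, rec.end) == (SVType.TRA, "chr2", 799)

    def test_bnd_alt_supplies_type_and_second_breakpoint(self, tmp_path):
        path = _vcf(tmp_path, "chr1\t500\tv1\tN\tN[chr2:3000[\t.\tPASS\t.\n")
        [rec] = read_sv_vcf(path).records
        assert (rec.svtype, rec.chrom2, rec.end) == (SVType.TRA, "chr2", 2999)

    def test_end_from_svlen_when_end_absent(self, tmp_path):
        path = _vcf(tmp_path, "chr1\t1000\tv1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;SVLEN=-250\n")
        [rec] = read_sv_vcf(path).records
        assert rec.end == rec.start + 250

    def test_empty_vcf_header_only(self, tmp_path):
        path = _vcf(tmp_path, "")
        cs = read_sv_vcf(path)
        assert cs.records == [] and cs.n_skipped == 0

    def test_missing_chrom_header_raises_naming_path(self, tmp_path):
        path = tmp_path / "broken.vcf"
        path.write_text("##fileformat=VCFv4.1\n")
        with pytest.raises(FormatError, match="broken.vcf"):
            read_sv_vcf(path)

    def test_malformed_lines_skipped_and_counted_not_raised(self, tmp_path):
        body = (
            "chr1\t1000\tv1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=2000\n"
            "chr1\tnot_a_pos\tv2\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL\n"
            "too\tfew\tcolumns\n"
        )
        cs = read_sv_vcf(_vcf(tmp_path, body))
        assert len(cs.records) == 1 and cs.n_skipped == 2

    def test_callset_id_defaults_to_file_stem(self, tmp_path):
        path = _vcf(tmp_path, "", name="sample.caller1.calls.vcf")
        assert read_sv_vcf(path).callset_id == "sample.caller1.calls"


class TestReadBed:
    def test_fourth_column_names_features(self, tmp_path):
        path = tmp_path / "reps.bed"
        path.write_text("chr1\t10\t20\trepA\n")
        [feat] = read_bed(path)
        assert (feat.chrom, feat.start, feat.end, feat.name) == ("chr1", 10, 20, "repA")
        assert feat.source_kind is SourceKind.BED

    def test_three_column_bed_named_after_file(self, tmp_path):
        path = tmp_path / "lowmap.bed"
        path.write_text("chr1\t10\t20\nchr2\t5\t9\n")
        feats = read_bed(path)
        assert [f.name for f in feats] == ["lowmap", "lowmap"]

    def test_name_sanitization(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text("chr1\t10\t20\tbad name;x\n")
        [feat] = read_bed(path)
        assert feat.name == "bad_name_x"

    def test_bad_lines_skipped(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text(
            "track name=x\n# comment\nchr1\tten\t20\tA\nchr1\t30\t30\tB\nchr1\t1\t2\tC\n"
        )
        assert [f.name for f in read_bed(path)] == ["C"]


class TestReadGff:
    def test_first_gene_attribute_wins(self, tmp_path):
        path = tmp_path / "g.gff"
        path.write_text(
            "chr1\tens\tgene\t100\t200\t.\t+\t.\tID=g1;gene=BRCA2;biotype=pc\n"
            "chr1\tens\tgene\t300\t400\t.\t+\t.\tgene=FIRST;gene=SECOND\n"
        )
        feats = read_gff(path)
        assert [f.name for f in feats] == ["BRCA2", "FIRST"]
        assert (feats[0].start, feats[0].end) == (99, 200)

    def test_missing_gene_key_falls_back_to_type_and_position(self, tmp_path):
        path = tmp_path / "g.gff"
        path.write_text("chr1\tens\texon\t100\t200\t.\t+\t.\tID=e1\n")
        [feat] = read_gff(path)
        assert feat.name == "exon:chr1:100"

    def test_short_lines_skipped(self, tmp_path):
        path = tmp_path / "g.gff"
        path.write_text("chr1\tens\tgene\t100\t200\n")
        assert read_gff(path) == []


def test_dedup_annotation_sites_keeps_first_and_distinguishes_types(tmp_path):
    body = (
        "chr1\t100\ta\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=200\n"
        "chr1\t100\tb\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=200\n"
        "chr1\t100\tc\tN\t<DUP>\t.\tPASS\tSVTYPE=DUP;END=200\n"
    )
    records = read_sv_vcf(_vcf(tmp_path, body)).records
    unique = dedup_annotation_sites(records)
    assert [r.record_id for r in unique] == ["a", "c"]
    assert dedup_annotation_sites([]) == []


class TestWriteAnnotatedVcf:
    def _annotate_nothing(self, records):
        return [
            AnnotationResult(event_id=r.record_id, overlapped_vcf=0, names=())
            for r in records
        ]

    def test_round_trip_outside_info_byte_identical(self, tmp_path):
        body = (
            "chr1\t1000\tv1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=2000\n"
            "chr2\t50\tv2\tN\t<INS>\t41\tq10\tSVTYPE=INS;SVLEN=120\n"
        )
        src = _vcf(tmp_path, body)
        cs = read_sv_vcf(src)
        out = tmp_path / "out.vcf"
        write_annotated_vcf(
            cs.records, self._annotate_nothing(cs.records), out, cs.header_lines
        )
        in_rows = [l for l in src.read_text().splitlines() if not l.startswith("#")]
        out_rows = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        for before, after in zip(in_rows, out_rows):
            b, a = before.split("\t"), after.split("\t")
            assert b[:7] == a[:7] and b[8:] == a[8:]
            assert a[7] == b[7] + ";overlapped_VCF=0;total_Annotations=0"
        # re-read reproduces the record fields
        reread = read_sv_vcf(out).records
        for x, y in zip(cs.records, reread):
            assert (x.chrom, x.start, x.end, x.svtype, x.svlen, x.chrom2) == (
                y.chrom,
                y.start,
                y.end,
                y.svtype,
                y.svlen,
                y.chrom2,
            )

    def test_annotated_row_formatting_and_header(self, tmp_path):
        src = _vcf(tmp_path, "chr1\t1000\tv1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=2000\n")
        cs = read_sv_vcf(src)
        out = tmp_path / "out.vcf"
        results = [
            AnnotationResult(event_id="v1", overlapped_vcf=1, names=("geneA", "rep1"))
        ]
        write_annotated_vcf(cs.records, results, out, cs.header_lines)
        text = out.read_text()
        assert "overlapped_VCF=1;total_Annotations=2;overlapped_Annotations=geneA,rep1" in text
        for key in ("overlapped_VCF", "total_Annotations", "overlapped_Annotations"):
            assert f"##INFO=<ID={key}," in text

    def test_total_annotations_equals_name_count_on_every_row(self, tmp_path):
        study = simulate(SimulationParams(n_true_svs=40, seed=9))
        from svannotate.annotate import annotate_events

        events = merge_callsets(study.callsets)
        results = annotate_events(
            events,
            [study.features.genes, study.features.repeats_named],
            [study.features.known_svs],
        )
        out = tmp_path / "ann.vcf"
        write_annotated_vcf(events, results, out)
        for line in out.read_text().splitlines():
            if line.startswith("#"):
                continue
            info = dict(
                kv.partition("=")[::2] for kv in line.split("\t")[7].split(";")
            )
            total = int(info["total_Annotations"])
            if total == 0:
                assert "overlapped_Annotations" not in info
            else:
                assert total == len(info["overlapped_Annotations"].split(","))

    def test_length_mismatch_rejected(self, tmp_path):
        src = _vcf(tmp_path, "chr1\t1000\tv1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=2000\n")
        cs = read_sv_vcf(src)
        with pytest.raises(ValueError):
            write_annotated_vcf(cs.records, [], tmp_path / "o.vcf", cs.header_lines)


def test_merged_vcf_round_trip(tmp_path, tiny_study, tiny_events):
    path = tmp_path / "merged.vcf"
    ids = [cs.callset_id for cs in tiny_study.callsets]
    write_merged_vcf(tiny_events, ids, path)
    events, callset_ids = read_merged_vcf(path)
    assert callset_ids == ids
    assert len(events) == len(tiny_events)
    for orig, back in zip(tiny_events, events):
        assert (orig.chrom, orig.start, orig.end, orig.chrom2) == (
            back.chrom,
            back.start,
            back.end,
            back.chrom2,
        )
        assert {(m.callset_id, m.start, m.end, m.svtype) for m in orig.members} == {
            (m.callset_id, m.start, m.end, m.svtype) for m in back.members
        }


def test_written_callset_vcf_agrees_with_cyvcf2(tmp_path, tiny_study):
    """Independent parser cross-check of the VCF writer/reader pair."""
    import cyvcf2

    study = tiny_study
    paths = write_study(study, tmp_path)
    path = paths["callsets"][0]
    ours = read_sv_vcf(path).records
    theirs = list(cyvcf2.VCF(str(path)))
    assert len(ours) == len(theirs)
    for mine, v in zip(ours, theirs):
        assert mine.chrom == v.CHROM
        assert mine.start == v.POS - 1
        assert mine.end == v.INFO["END"] - 1
        assert mine.svtype.value == v.INFO["SVTYPE"]
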