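"""Readers/writers: dialect handling, coordinate conventions, round trips."""

import pytest

from xcitrio import variant_io
from xcitrio.model import (
    EscapeSummary,
    Locus,
    LocusKind,
    PhasedSnp,
    SkipLog,
    SnpStatus,
    Source,
    StratumCall,
)
from conftest import obs


def test_tsv_row_maps_to_observation(tmp_path):
    path = tmp_path / "obs.tsv"
    path.write_text(
        "sample_id\tsource\tscaffold\tposition\tref\talt\treads_ref\treads_alt\n"
        "daughter\ttranscriptome\tScaffoldX1\t1042\tA\tG\t12\t9\n"
    )
    records = variant_io.read_allele_observations(path, "tsv")
    assert len(records) == 1
    record = records[0]
    assert record.coverage == 21
    assert record.position == 1042
    assert record.source == Source.TRANSCRIPTOME


def test_tsv_bad_line_names_line_number(tmp_path):
    path = tmp_path / "obs.tsv"
    path.write_text(
        "sample_id\tsource\tscaffold\tposition\tref\talt\treads_ref\treads_alt\n"
        "daughter\ttranscriptome\tScaffoldX1\tnot_a_number\tA\tG\t12\t9\n"
    )
    with pytest.raises(variant_io.ParseError, match=":2"):
        variant_io.read_allele_observations(path, "tsv")


def test_observation_round_trip(tmp_path):
    records = [
        obs(position=100, reads_ref=5, reads_alt=0),
        obs(position=200, ref="C", alt="T", reads_ref=0, reads_alt=50),
    ]
    path = tmp_path / "out.tsv"
    variant_io.write_allele_observations(records, path)
    assert variant_io.read_allele_observations(path, "tsv") == records


def _write_vcf(path, lines):
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
        "##contig=<ID=ScaffoldX1,length=100000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        "daughter_transcriptome\n"
    )
    path.write_text(header + "".join(lines))


def test_vcf_allele_depths_parsed(tmp_path):
    path = tmp_path / "in.vcf"
    _write_vcf(path, ["ScaffoldX1\t500\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/1:0,50\n"])
    records = variant_io.read_allele_observations(path, "vcf")
    assert len(records) == 1
    assert (records[0].reads_ref, records[0].reads_alt) == (0, 50)
    assert records[0].sample_id == "daughter"
    assert records[0].source == Source.TRANSCRIPTOME


def test_vcf_multiallelic_site_skip_logged(tmp_path):
    path = tmp_path / "in.vcf"
    _write_vcf(
        path,
        [
            "ScaffoldX1\t500\t.\tA\tG,T\t.\tPASS\t.\tGT:AD\t1/2:0,3,4\n",
            "ScaffoldX1\t700\t.\tC\tT\t.\tPASS\t.\tGT:AD\t0/1:6,7\n",
        ],
    )
    skip_log = SkipLog()
    records = variant_io.read_allele_observations(path, "vcf", skip_log)
    assert len(records) == 1
    assert skip_log.count("multiallelic") == 1


def test_tsv_conflicting_allele_pairs_dropped(tmp_path):
    # same sample+site reported with two different alt alleles => >2 alleles
    path = tmp_path / "obs.tsv"
    path.write_text(
        "sample_id\tsource\tscaffold\tposition\tref\talt\treads_ref\treads_alt\n"
        "daughter\ttranscriptome\tScaffoldX1\t100\tA\tG\t5\t3\n"
        "daughter\ttranscriptome\tScaffoldX1\t100\tA\tT\t5\t2\n"
        "daughter\ttranscriptome\tScaffoldX1\t200\tA\tG\t5\t3\n"
    )
    skip_log = SkipLog()
    records = variant_io.read_allele_observations(path, "tsv", skip_log)
    assert len(records) == 1
    # multiallelic-drop count + retained count = total input records
    assert skip_log.count("multiallelic") + len(records) == 3


def test_bed_coordinates_normalized(tmp_path):
    path = tmp_path / "genes.bed"
    path.write_text("ScaffoldX1\t99\t200\tgeneA\n")
    (gene,) = variant_io.read_gene_annotation(path, "bed")
    assert (gene.start, gene.end) == (100, 200)
    assert gene.end - gene.start + 1 == 200 - 99  # length preserved


def test_gff3_gene_with_exons(tmp_path):
    path = tmp_path / "genes.gff3"
    path.write_text(
        "##gff-version 3\n"
        "ScaffoldX1\ttest\tgene\t100\t500\t.\t+\t.\tID=geneA;Name=GENEA\n"
        "ScaffoldX1\ttest\texon\t100\t200\t.\t+\t.\tID=geneA.e1;Parent=geneA\n"
        "ScaffoldX1\ttest\texon\t400\t500\t.\t+\t.\tID=geneA.e2;Parent=geneA\n"
    )
    (gene,) = variant_io.read_gene_annotation(path, "gff3")
    assert gene.gene_name == "GENEA"
    assert gene.exons == ((100, 200), (400, 500))


def test_empty_annotation_file_warns(tmp_path, caplog):
    path = tmp_path / "empty.bed"
    path.write_text("")
    with caplog.at_level("WARNING"):
        assert variant_io.read_gene_annotation(path, "bed") == []
    assert any("no gene records" in r.message for r in caplog.records)


def test_stratum_map_order_and_errors(tmp_path):
    path = tmp_path / "map.tsv"
    path.write_text(
        "gene\tscaffold\tposition\tstratum\n"
        "g3\ts1\t300\told\n"
        "g1\ts1\t100\told\n"
        "g2\ts1\t200\tnew\n"
    )
    stratum_map = variant_io.read_stratum_map(path)
    assert [g.gene_id for g in stratum_map] == ["g1", "g2", "g3"]

    path.write_text("gene\tscaffold\tposition\tstratum\ng1\ts1\t100\tmedium\n")
    with pytest.raises(variant_io.ParseError, match="medium"):
        variant_io.read_stratum_map(path)

    path.write_text(
        "gene\tscaffold\tposition\tstratum\ng1\ts1\t100\told\ng1\ts1\t200\tnew\n"
    )
    with pytest.raises(ValueError, match="duplicate"):
        variant_io.read_stratum_map(path)


def test_stratum_map_all_unknown_is_valid(tmp_path):
    path = tmp_path / "map.tsv"
    path.write_text(
        "gene\tscaffold\tposition\tstratum\ng1\ts1\t100\tunknown\ng2\ts1\t200\tunknown\n"
    )
    assert len(variant_io.read_stratum_map(path)) == 2


def _locus(locus_id, position, status, conflict=False):
    snp = PhasedSnp(
        scaffold="ScaffoldX1",
        position=position,
        ref_allele="A",
        alt_allele="G",
        maternal_allele="A",
        paternal_allele="G",
        maternal_reads=40,
        paternal_reads=10,
        status=status,
    )
    return Locus(
        locus_id=locus_id,
        kind=LocusKind.INTERGENIC,
        scaffold="ScaffoldX1",
        position=position,
        snps=[snp],
        status=status,
        conflict_flag=conflict,
        mean_paternal_fraction=0.2,
        stratum=StratumCall.OLD,
    )


def test_report_round_trip(tmp_path):
    loci = [
        _locus("L1", 100, SnpStatus.ESCAPER, conflict=True),
        _locus("L2", 900, SnpStatus.PATERNAL_INACTIVATED),
    ]
    summary = EscapeSummary(2, 1, 0, 1, 0, 0.5, 0.2, 0.2)
    path = tmp_path / "report.tsv"
    variant_io.write_report(loci, summary, path)
    df = variant_io.read_report(path)
    assert len(df) == 2
    assert list(df["locus"]) == ["L1", "L2"]
    assert list(df["status"]) == ["escaper", "paternal_inactivated"]
    assert list(df["conflict_flag"]) == ["conflict", "."]
    # writing the parsed rows again is field-for-field stable
    path2 = tmp_path / "report2.tsv"
    variant_io.write_report(loci, summary, path2)
    assert path.read_text() == path2.read_text()


def test_report_empty_loci_header_only(tmp_path):
    path = tmp_path / "report.tsv"
    variant_io.write_report([], None, path)
    df = variant_io.read_report(path)
    assert df.empty
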