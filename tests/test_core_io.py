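"""Domain types, coordinate conventions, and file round trips."""

import numpy as np
import pytest

from scarscape.core import (CNSegment, GenomeSpec, SVRecord, VariantRecord,
                            variant_class)
from scarscape.io import (read_cn_segments, read_svs, read_variants,
                          write_cn_segments, write_svs, write_variants)


@pytest.mark.parametrize("ref,alt,expected", [
    ("A", "T", "SNV"),
    ("AT", "GC", "MNV"),
    ("A", "AT", "InDel"),
    ("ATG", "A", "InDel"),
])
def test_variant_class_from_alleles(ref, alt, expected):
    assert variant_class(ref, alt) == expected
    assert VariantRecord("chr1", 10, ref, alt).vclass == expected


def test_variant_record_rejects_long_indels_and_bad_positions():
    with pytest.raises(ValueError, match="50 bp"):
        VariantRecord("chr1", 1, "A" + "T" * 51, "A")
    with pytest.raises(ValueError, match="position"):
        VariantRecord("chr1", 0, "A", "T")


def test_cn_segment_rounds_ties_to_even():
    assert CNSegment("chr1", 1, 10, 2.0).cn_round == 2
    assert CNSegment("chr1", 1, 10, 2.5).cn_round == 2
    assert CNSegment("chr1", 1, 10, 3.5).cn_round == 4
    assert CNSegment("chr1", 1, 10, 2.6).cn_round == 3


def test_sv_record_size_and_tra_consistency():
    sv = SVRecord("DEL", "chr1", 1_000_000, "chr1", 1_050_000)
    assert sv.size == 50_000
    tra = SVRecord("TRA", "chr1", 100, "chr5", 200)
    assert tra.size is None
    with pytest.raises(ValueError, match="TRA"):
        SVRecord("TRA", "chr1", 100, "chr1", 200)
    with pytest.raises(ValueError, match="TRA"):
        SVRecord("DEL", "chr1", 100, "chr5", 200)


def test_empty_variant_tsv_roundtrip(tmp_path):
    path = tmp_path / "empty.tsv"
    write_variants([], path)
    assert read_variants(path) == []


def test_variant_tsv_roundtrip_is_lossless(tmp_path, rng):
    records = []
    for i in range(50):
        kind = i % 3
        if kind == 0:
            ref, alt = "C", "T"
        elif kind == 1:
            ref, alt = "AT", "GC"
        else:
            ref, alt = "A", "A" + "AT" * int(rng.integers(1, 10))
        records.append(VariantRecord(
            chrom=f"chr{1 + i % 3}", pos=int(rng.integers(1, 10 ** 8)),
            ref=ref, alt=alt, alt_reads=int(rng.integers(0, 100)),
            gnomad_exome_af=float(rng.random()) if i % 4 == 0 else None,
            gnomad_genome_af=float(rng.random()) if i % 5 == 0 else None,
            trinucleotide="ACA" if ref == "C" else None,
            coding=bool(i % 2), gene="TP53" if i % 7 == 0 else None,
            effect="missense" if i % 7 == 0 else None,
            repeat_unit_len=2 if kind == 2 else None,
            repeat_count=5 if kind == 2 else None,
        ))
    path = tmp_path / "variants.tsv"
    write_variants(records, path)
    assert read_variants(path) == records


def test_variant_tsv_gzip_transparent(tmp_path):
    records = [VariantRecord("chr1", 5, "C", "G", alt_reads=9)]
    path = tmp_path / "v.tsv.gz"
    write_variants(records, path)
    assert read_variants(path) == records


def test_malformed_variant_row_names_line(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("chrom\tpos\tref\talt\nchr1\tnotanint\tA\tT\n")
    with pytest.raises(ValueError, match="line 2"):
        read_variants(path)


def test_long_indels_rejected_with_warning_count(tmp_path):
    ok = VariantRecord("chr1", 10, "A", "AT")
    path = tmp_path / "v.tsv"
    long_alt = "A" + "T" * 60
    header = "chrom\tpos\tref\talt\n"
    path.write_text(header + f"chr1\t10\tA\tAT\nchr1\t20\t{long_alt}\tA\n")
    with pytest.warns(UserWarning, match="1 InDel"):
        records = read_variants(path)
    assert records == [ok]


def test_unknown_chromosome_kept_with_warning(tmp_path, mini_genome):
    path = tmp_path / "v.tsv"
    path.write_text("chrom\tpos\tref\talt\nchrUn\t10\tA\tT\n")
    with pytest.warns(UserWarning, match="chrUn"):
        records = read_variants(path, genome=mini_genome)
    assert len(records) == 1


def test_vcf_reading_one_record_per_alt(tmp_path):
    vcf = tmp_path / "t.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=GNOMAD_EX_AF,Number=1,Type=Float,Description="x">\n'
        '##INFO=<ID=TNC,Number=1,Type=String,Description="x">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ttumor\n"
        "chr1\t100\t.\tC\tT,G\t.\tPASS\tGNOMAD_EX_AF=0.0001;TNC=ACA\tAD\t50,12\n"
    )
    records = read_variants(vcf, format="vcf")
    assert [r.alt for r in records] == ["T", "G"]
    assert records[0].trinucleotide == "ACA"
    assert records[0].gnomad_exome_af == pytest.approx(0.0001)
    assert records[0].alt_reads == 12


def test_seg_reader_sorts_rounds_and_rejects_overlaps(tmp_path):
    path = tmp_path / "a.seg"
    path.write_text("chrom\tstart\tend\tcn\n"
                    "chr2\t1\t100\t2.5\n"
                    "chr1\t500\t900\t3.2\n"
                    "chr1\t1\t400\t2.0\n")
    segs = read_cn_segments(path)
    assert [(s.chrom, s.start) for s in segs] == [
        ("chr1", 1), ("chr1", 500), ("chr2", 1)]
    assert [s.cn_round for s in segs] == [2, 3, 2]

    bad = tmp_path / "b.seg"
    bad.write_text("chrom\tstart\tend\tcn\n"
                   "chr1\t1\t400\t2.0\nchr1\t300\t600\t2.0\n")
    with pytest.raises(ValueError, match="overlap"):
        read_cn_segments(bad)


def test_seg_roundtrip(tmp_path, rng):
    segs = []
    pos = 1
    for _ in range(20):
        end = pos + int(rng.integers(10, 10_000))
        segs.append(CNSegment("chr1", pos, end, float(rng.uniform(0, 6))))
        pos = end + 1
    path = tmp_path / "r.seg"
    write_cn_segments(segs, path)
    assert read_cn_segments(path) == segs


def test_bedpe_roundtrip_and_coordinate_conversion(tmp_path, rng):
    records = []
    for i in range(20):
        t = ["DEL", "DUP", "INV_HH", "INV_TT", "INS", "TRA"][i % 6]
        p1 = int(rng.integers(1, 10 ** 7))
        if t == "TRA":
            records.append(SVRecord(t, "chr1", p1, "chr2",
                                    int(rng.integers(1, 10 ** 7)), baf=0.5))
        else:
            records.append(SVRecord(t, "chr1", p1, "chr1",
                                    p1 + int(rng.integers(1, 10 ** 6)),
                                    baf=float(rng.uniform(0.1, 1))))
    path = tmp_path / "r.bedpe"
    write_svs(records, path)
    assert read_svs(path) == records
    # BEDPE starts on disk are exactly pos-1 (0-based half-open)
    lines = path.read_text().splitlines()
    first = lines[1].split("\t")
    assert int(first[1]) == records[0].pos1 - 1


def test_bedpe_inversion_orientation_from_strands(tmp_path):
    path = tmp_path / "inv.bedpe"
    path.write_text(
        "chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\t"
        "strand1\tstrand2\tsvtype\tbaf\n"
        "chr1\t99\t100\tchr1\t1999\t2000\tsv0\t.\t+\t+\tINV\t0.4\n"
        "chr1\t99\t100\tchr1\t1999\t2000\tsv1\t.\t-\t-\tINV\t0.4\n")
    recs = read_svs(path)
    assert [r.svtype for r in recs] == ["INV_HH", "INV_TT"]


def test_genome_spec_defaults_and_override():
    g = GenomeSpec.grch37()
    assert g.callable_genomic_bases == 2_858_674_662
    assert g.callable_coding_bases == 28_711_682
    assert "Y" not in g.autosomal_chroms()
    custom = GenomeSpec(chroms={"chr1": 10}, callable_genomic_bases=10,
                        callable_coding_bases=1)
    assert custom.callable_genomic_bases == 10
    with pytest.raises(ValueError):
        GenomeSpec(chroms={}, callable_genomic_bases=0)
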