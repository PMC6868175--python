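"""Readers and writers for the standard per-sample file formats.

Supported formats:

* small variants: tab-separated table (documented header below) or VCF 4.x;
* copy-number segments: SEG-style TSV (chrom, start, end, cn);
* structural variants: BEDPE (0-based half-open starts, converted to the
  internal 1-based convention on read).

All text readers/writers handle ``.gz`` paths transparently. Every writer
emits a header line naming its columns, and each reader/writer pair is a
lossless round trip on those columns.
"""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .core import CNSegment, GenomeSpec, SVRecord, VariantRecord, variant_class

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "vclass", "alt_reads",
    "gnomad_exome_af", "gnomad_genome_af", "trinucleotide", "coding",
    "gene", "effect", "repeat_unit_len", "repeat_count",
]

SEG_COLUMNS = ["chrom", "start", "end", "cn"]

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "svtype", "baf",
]

# breakend strand orientations implied by each intrachromosomal type
_TYPE_STRANDS = {
    "DEL": ("+", "-"),
    "DUP": ("-", "+"),
    "INS": ("+", "-"),
    "INV_HH": ("+", "+"),
    "INV_TT": ("-", "-"),
    "TRA": ("+", "-"),
}


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_optional(value: str, cast):
    if value == "" or value == ".":
        return None
    return cast(value)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


# ---------------------------------------------------------------------------
# small variants
# ---------------------------------------------------------------------------

def read_variants(path, format: str = "tsv",
                  genome: Optional[GenomeSpec] = None) -> list[VariantRecord]:
    """Read somatic small variants from a TSV table or a VCF.

    One record per ALT allele. The variant class is derived from the allele
    lengths; InDels longer than 50 bp are dropped with a warning giving the
    rejected count. Records on chromosomes absent from ``genome`` (when one
    is given) are kept but flagged with a warning.
    """
    if format == "tsv":
        records, rejected = _read_variants_tsv(path)
    elif format == "vcf":
        records, rejected = _read_variants_vcf(path)
    else:
        raise ValueError(f"unknown variant format {format!r}")
    if rejected:
        warnings.warn(f"{rejected} InDel record(s) longer than 50 bp rejected")
    if genome is not None and genome.chroms:
        unknown = {r.chrom for r in records} - set(genome.chroms)
        if unknown:
            warnings.warn(f"records on chromosome(s) not in genome: {sorted(unknown)}")
    return records


def _read_variants_tsv(path):
    records: list[VariantRecord] = []
    rejected = 0
    with _open_text(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in ("chrom", "pos", "ref", "alt") if c not in header]
                if missing:
                    raise ValueError(f"variant TSV header missing column(s) {missing}")
                continue
            row = dict(zip(header, fields))
            try:
                rec = VariantRecord(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    vclass=None,
                    alt_reads=int(row.get("alt_reads", "0") or 0),
                    gnomad_exome_af=_parse_optional(row.get("gnomad_exome_af", ""), float),
                    gnomad_genome_af=_parse_optional(row.get("gnomad_genome_af", ""), float),
                    trinucleotide=row.get("trinucleotide") or None,
                    coding=row.get("coding", "0") in ("1", "True", "true"),
                    gene=row.get("gene") or None,
                    effect=row.get("effect") or None,
                    repeat_unit_len=_parse_optional(row.get("repeat_unit_len", ""), int),
                    repeat_count=_parse_optional(row.get("repeat_count", ""), int),
                )
            except ValueError as exc:
                if "longer than 50 bp" in str(exc):
                    rejected += 1
                    continue
                raise ValueError(f"malformed variant row at line {lineno}: {exc}") from exc
            except KeyError as exc:
                raise ValueError(f"malformed variant row at line {lineno}: missing {exc}") from exc
            records.append(rec)
    if header is None:
        raise ValueError("variant TSV has no header line")
    return records, rejected


_VCF_INFO_KEYS = {
    "gnomad_exome_af": "GNOMAD_EX_AF",
    "gnomad_genome_af": "GNOMAD_WG_AF",
    "trinucleotide": "TNC",
    "gene": "GENE",
    "effect": "EFFECT",
    "repeat_unit_len": "REP_LEN",
    "repeat_count": "REP_CNT",
}


def _read_variants_vcf(path):
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    rejected = 0
    vcf = VCF(str(path))
    for var in vcf:
        for alt in var.ALT:
            alt_reads = 0
            if var.gt_alt_depths is not None and len(var.gt_alt_depths):
                alt_reads = max(0, int(var.gt_alt_depths[-1]))
            elif var.INFO.get("ALT_READS") is not None:
                alt_reads = int(var.INFO["ALT_READS"])
            info = {k: var.INFO.get(v) for k, v in _VCF_INFO_KEYS.items()}
            try:
                rec = VariantRecord(
                    chrom=var.CHROM, pos=var.POS, ref=var.REF, alt=alt,
                    alt_reads=alt_reads,
                    gnomad_exome_af=info["gnomad_exome_af"],
                    gnomad_genome_af=info["gnomad_genome_af"],
                    trinucleotide=info["trinucleotide"],
                    coding=bool(var.INFO.get("CODING", 0)),
                    gene=info["gene"],
                    effect=info["effect"],
                    repeat_unit_len=(None if info["repeat_unit_len"] is None
                                     else int(info["repeat_unit_len"])),
                    repeat_count=(None if info["repeat_count"] is None
                                  else int(info["repeat_count"])),
                )
            except ValueError as exc:
                if "longer than 50 bp" in str(exc):
                    rejected += 1
                    continue
                raise
            records.append(rec)
    return records, rejected


def write_variants(records: Iterable[VariantRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join(_fmt(getattr(r, c)) for c in VARIANT_COLUMNS) + "\n")


# ---------------------------------------------------------------------------
# copy-number segments
# ---------------------------------------------------------------------------

def read_cn_segments(path) -> list[CNSegment]:
    """Read a SEG-style table; returns segments sorted by (chrom, start).

    Overlapping segments on the same chromosome are an input error; Y
    segments are kept here and excluded by the consumers that require it.
    """
    segments: list[CNSegment] = []
    with _open_text(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in SEG_COLUMNS if c not in header]
                if missing:
                    raise ValueError(f"SEG header missing column(s) {missing}")
                continue
            row = dict(zip(header, fields))
            try:
                segments.append(CNSegment(
                    chrom=row["chrom"], start=int(row["start"]),
                    end=int(row["end"]), cn=float(row["cn"]),
                ))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"malformed SEG row at line {lineno}: {exc}") from exc
    if header is None:
        raise ValueError("SEG file has no header line")
    segments.sort(key=lambda s: (s.chrom, s.start, s.end))
    offenders = []
    for a, b in zip(segments, segments[1:]):
        if a.chrom == b.chrom and b.start <= a.end:
            offenders.append(f"{a.chrom}:{a.start}-{a.end} overlaps {b.chrom}:{b.start}-{b.end}")
    if offenders:
        raise ValueError("overlapping segments: " + "; ".join(offenders))
    return segments


def write_cn_segments(segments: Iterable[CNSegment], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{_fmt(s.cn)}\n")


# ---------------------------------------------------------------------------
# structural variants
# ---------------------------------------------------------------------------

def read_svs(path) -> list[SVRecord]:
    """Read structural variants from BEDPE.

    BEDPE starts are 0-based half-open; breakend positions are taken as
    ``start + 1``. Inversion orientation comes from the svtype column when
    it already distinguishes INV_HH/INV_TT, otherwise from the strand pair
    (++ head-to-head, -- tail-to-tail).
    """
    records: list[SVRecord] = []
    with _open_text(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in ("chrom1", "start1", "chrom2", "start2", "svtype")
                           if c not in header]
                if missing:
                    raise ValueError(f"BEDPE header missing column(s) {missing}")
                continue
            row = dict(zip(header, fields))
            try:
                svtype = row["svtype"]
                if svtype == "INV":
                    strands = (row.get("strand1", "+"), row.get("strand2", "+"))
                    svtype = "INV_HH" if strands == ("+", "+") else "INV_TT"
                rec = SVRecord(
                    svtype=svtype,
                    chrom1=row["chrom1"], pos1=int(row["start1"]) + 1,
                    chrom2=row["chrom2"], pos2=int(row["start2"]) + 1,
                    baf=_parse_optional(row.get("baf", ""), float),
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"malformed BEDPE row at line {lineno}: {exc}") from exc
            records.append(rec)
    if header is None:
        raise ValueError("BEDPE file has no header line")
    return records


def write_svs(records: Iterable[SVRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(BEDPE_COLUMNS) + "\n")
        for i, r in enumerate(records):
            s1, s2 = _TYPE_STRANDS[r.svtype]
            fh.write("\t".join([
                r.chrom1, str(r.pos1 - 1), str(r.pos1), r.chrom2,
                str(r.pos2 - 1), str(r.pos2), f"sv{i}", ".", s1, s2,
                r.svtype, _fmt(r.baf),
            ]) + "\n")


# ---------------------------------------------------------------------------
# generic TSV helpers used by the pipeline outputs
# ---------------------------------------------------------------------------

def write_table(df, path, provenance: Optional[Sequence[str]] = None) -> None:
    """Write a DataFrame as TSV with optional '#'-prefixed provenance lines."""
    with _open_text(path, "wt") as fh:
        for line in provenance or ():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path):
    import pandas as pd

    with _open_text(path) as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
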