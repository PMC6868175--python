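"""Domain types shared by every analysis stage.

Coordinates are 1-based inclusive throughout (VCF convention). BEDPE input,
which is 0-based half-open, is converted on read and back on write.

Small variants are classified from their allele lengths: equal-length
single-base substitutions are SNVs, equal-length multi-base substitutions
are MNVs, anything with a length change is an InDel. InDels longer than
50 bp are outside the scope of the small-variant analyses and are rejected
by the readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

MAX_INDEL_LEN = 51  # max(len(ref), len(alt)) for a <=50 bp InDel

VARIANT_CLASSES = ("SNV", "MNV", "InDel")
SV_TYPES = ("TRA", "INV_HH", "INV_TT", "DUP", "DEL", "INS")

#: Default number of callable (ACGT) bases in the GRCh37 reference genome,
#: the denominator of the genome-wide mutations-per-Mbp rate.
CALLABLE_GENOMIC_BASES = 2_858_674_662
#: Default summed length of distinct non-overlapping coding regions
#: (protein-coding, fully supported transcripts), denominator of coding TMB.
CALLABLE_CODING_BASES = 28_711_682


def variant_class(ref: str, alt: str) -> str:
    """Classify a ref/alt allele pair as SNV, MNV, or InDel."""
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    return "InDel"


@dataclass(slots=True)
class VariantRecord:
    """One somatic small variant (SNV, MNV, or InDel <=50 bp)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: Optional[str] = None
    alt_reads: int = 0
    gnomad_exome_af: Optional[float] = None
    gnomad_genome_af: Optional[float] = None
    trinucleotide: Optional[str] = None
    coding: bool = False
    gene: Optional[str] = None
    effect: Optional[str] = None
    repeat_unit_len: Optional[int] = None
    repeat_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.alt_reads < 0:
            raise ValueError("alt_reads must be >= 0")
        derived = variant_class(self.ref, self.alt)
        if self.vclass is None:
            self.vclass = derived
        elif self.vclass != derived:
            raise ValueError(
                f"vclass {self.vclass!r} inconsistent with alleles "
                f"{self.ref}>{self.alt} (expected {derived})"
            )
        if self.vclass == "InDel" and max(len(self.ref), len(self.alt)) > MAX_INDEL_LEN:
            raise ValueError(
                f"InDel longer than 50 bp at {self.chrom}:{self.pos}"
            )

    @property
    def indel_length(self) -> int:
        """Net inserted/deleted length (0 for substitutions)."""
        return abs(len(self.ref) - len(self.alt))


@dataclass(slots=True)
class SVRecord:
    """One somatic structural variant.

    ``svtype`` is TRA (interchromosomal), DEL, DUP, INS, or an inversion
    split by breakend orientation into head-to-head (INV_HH, ++ strands)
    and tail-to-tail (INV_TT, -- strands). ``size`` is |pos2 - pos1| and
    undefined for translocations.
    """

    svtype: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    baf: Optional[float] = None
    size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        inter = self.chrom1 != self.chrom2
        if (self.svtype == "TRA") != inter:
            raise ValueError(
                f"svtype TRA requires distinct chromosomes (and vice versa): "
                f"{self.svtype} {self.chrom1}:{self.pos1}-{self.chrom2}:{self.pos2}"
            )
        if self.svtype == "TRA":
            self.size = None
        else:
            self.size = abs(self.pos2 - self.pos1)
            if self.size < 1:
                raise ValueError("intrachromosomal SV must span >= 1 bp")
        if self.baf is not None and not (0.0 <= self.baf <= 1.0):
            raise ValueError(f"baf must be in [0,1], got {self.baf}")


def round_half_even(x: float) -> int:
    """Round to nearest integer with ties to even (banker's rounding)."""
    return int(round(x))


@dataclass(slots=True)
class CNSegment:
    """Absolute copy-number segment with its rounded integer state."""

    chrom: str
    start: int
    end: int
    cn: float
    cn_round: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start > end at {self.chrom}:{self.start}")
        if self.cn < 0:
            raise ValueError("copy number must be >= 0")
        if self.cn_round is None:
            self.cn_round = round_half_even(self.cn)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SampleData:
    """All per-sample inputs consumed by the downstream stages."""

    sample_id: str
    variants: list[VariantRecord] = field(default_factory=list)
    svs: list[SVRecord] = field(default_factory=list)
    segments: list[CNSegment] = field(default_factory=list)
    purity: Optional[float] = None
    chord_score: Optional[float] = None
    metadata: dict = field(default_factory=dict)


@dataclass
class GenomeSpec:
    """Chromosome names/lengths and the callable-base denominators.

    The default callable constants correspond to the GRCh37 reference; both
    are overridable, and the miniature test genome scales them to its own
    size so that simulated per-Mbp rates stay on the intended scale.
    """

    chroms: dict[str, int] = field(default_factory=dict)
    callable_genomic_bases: int = CALLABLE_GENOMIC_BASES
    callable_coding_bases: int = CALLABLE_CODING_BASES

    def __post_init__(self) -> None:
        if self.callable_genomic_bases <= 0 or self.callable_coding_bases <= 0:
            raise ValueError("callable base counts must be positive")

    @property
    def total_length(self) -> int:
        return sum(self.chroms.values())

    def autosomal_chroms(self) -> list[str]:
        """Chromosome names with Y excluded (Y is dropped from all
        copy-number work)."""
        return [c for c in self.chroms if c.rstrip() not in ("Y", "chrY")]

    @classmethod
    def mini(cls) -> "GenomeSpec":
        """Three-chromosome 370 Mbp test genome.

        Callable denominators equal its physical size (all bases callable)
        with a 1% coding fraction, so simulated rates expressed per Mbp are
        recovered by the TMB formulas without rescaling.
        """
        chroms = {"chr1": 150_000_000, "chr2": 120_000_000, "chr3": 100_000_000}
        total = sum(chroms.values())
        return cls(
            chroms=chroms,
            callable_genomic_bases=total,
            callable_coding_bases=total // 100,
        )

    @classmethod
    def grch37(cls) -> "GenomeSpec":
        """GRCh37 chromosome sizes with the default callable constants."""
        sizes = {
            "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
            "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
            "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
            "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
            "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
            "21": 48129895, "22": 51304566, "X": 155270560, "Y": 59373566,
        }
        return cls(chroms=sizes)
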