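"""Tumor mutational burden, the microsatellite-instability rule, and
purity-versus-burden correlations.

TMB is the total small-variant count divided by the callable megabases:

* genomic: (SNV + MNV + InDel) / (callable_genomic_bases / 1e6)
* coding:  the coding analogue with the coding denominator.

A sample is called MSI when it carries more than 11,436 genomic InDels
(<=50 bp) that sit in microsatellites: a repeat unit of 2-4 bp repeated
at least 4 times, or a homopolymer (unit 1 bp) repeated at least 5 times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from scipy import stats

from .core import GenomeSpec, SampleData, VariantRecord

MSI_INDEL_THRESHOLD = 11_436


@dataclass
class MutationCounts:
    """Genome-wide and coding small-variant counts per class."""

    snv_g: int = 0
    indel_g: int = 0
    mnv_g: int = 0
    snv_c: int = 0
    indel_c: int = 0
    mnv_c: int = 0

    def __post_init__(self) -> None:
        for name in ("snv", "indel", "mnv"):
            g = getattr(self, f"{name}_g")
            c = getattr(self, f"{name}_c")
            if g < 0 or c < 0:
                raise ValueError("counts must be non-negative")
            if c > g:
                raise ValueError(f"coding {name} count exceeds genome-wide count")

    @classmethod
    def from_variants(cls, variants: Iterable[VariantRecord]) -> "MutationCounts":
        counts = cls()
        for v in variants:
            key = {"SNV": "snv", "InDel": "indel", "MNV": "mnv"}[v.vclass]
            setattr(counts, f"{key}_g", getattr(counts, f"{key}_g") + 1)
            if v.coding:
                setattr(counts, f"{key}_c", getattr(counts, f"{key}_c") + 1)
        return counts


@dataclass
class MsiCall:
    qualifying_indels: int
    is_msi: bool
    threshold: int = MSI_INDEL_THRESHOLD


def tmb(counts: MutationCounts, genome: GenomeSpec, scope: str = "genomic") -> float:
    """Mutations per callable megabase for the requested scope."""
    if scope == "genomic":
        total = counts.snv_g + counts.mnv_g + counts.indel_g
        denom = genome.callable_genomic_bases / 1e6
    elif scope == "coding":
        total = counts.snv_c + counts.mnv_c + counts.indel_c
        denom = genome.callable_coding_bases / 1e6
    else:
        raise ValueError(f"unknown TMB scope {scope!r}")
    return total / denom


def indel_qualifies_for_msi(v: VariantRecord) -> bool:
    """Microsatellite criterion for one InDel (repeat fields required)."""
    if v.vclass != "InDel":
        return False
    if v.repeat_unit_len is None or v.repeat_count is None:
        raise ValueError(
            f"InDel at {v.chrom}:{v.pos} lacks repeat annotation; supply a "
            "reference sequence to derive it"
        )
    return (2 <= v.repeat_unit_len <= 4 and v.repeat_count >= 4) or (
        v.repeat_unit_len == 1 and v.repeat_count >= 5
    )


def annotate_repeats(v: VariantRecord, chrom_seq: str) -> VariantRecord:
    """Fill repeat_unit_len / repeat_count by maximal exact tandem-repeat
    extension of the inserted/deleted unit around the event.

    ``chrom_seq`` is the full reference sequence of ``v.chrom`` (0-based
    indexing internally).
    """
    if v.vclass != "InDel":
        return v
    longer, shorter = (v.ref, v.alt) if len(v.ref) > len(v.alt) else (v.alt, v.ref)
    unit = longer[len(shorter):]
    if not unit:
        return v
    unit_len = len(unit)
    # anchor immediately after the shared prefix base(s); scan reference
    anchor = v.pos - 1 + len(shorter)
    count = 0
    i = anchor
    while chrom_seq[i:i + unit_len] == unit:
        count += 1
        i += unit_len
    i = anchor - unit_len
    while i >= 0 and chrom_seq[i:i + unit_len] == unit:
        count += 1
        i -= unit_len
    v.repeat_unit_len = unit_len
    v.repeat_count = count
    return v


def classify_msi(
    variants: Iterable[VariantRecord],
    threshold: int = MSI_INDEL_THRESHOLD,
) -> MsiCall:
    """Count microsatellite InDels and call MSI when the count exceeds the
    threshold (strictly greater)."""
    qualifying = sum(1 for v in variants
                     if v.vclass == "InDel" and indel_qualifies_for_msi(v))
    return MsiCall(qualifying_indels=qualifying,
                   is_msi=qualifying > threshold,
                   threshold=threshold)


def purity_burden_correlation(cohort: Iterable[SampleData]):
    """Spearman correlation of per-class variant counts against tumor
    purity across the cohort.

    Returns a DataFrame with one row per class (SNV, InDel, MNV, SV); rho
    is reported as missing when the inputs are all tied.
    """
    import pandas as pd

    samples = [s for s in cohort if s.purity is not None]
    if len(samples) < 3:
        raise ValueError("need >= 3 samples with purity")
    purity = [s.purity for s in samples]
    rows = []
    for cls in ("SNV", "InDel", "MNV", "SV"):
        if cls == "SV":
            counts = [len(s.svs) for s in samples]
        else:
            counts = [sum(1 for v in s.variants if v.vclass == cls) for s in samples]
        if len(set(counts)) == 1 or len(set(purity)) == 1:
            rows.append({"vclass": cls, "rho": None, "p": None})
            continue
        rho, p = stats.spearmanr(purity, counts)
        rows.append({"vclass": cls, "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows)
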