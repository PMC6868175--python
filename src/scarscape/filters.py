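"""Heuristic post-filters on somatic small variants and structural variants.

Small variants are removed when supported by too few alternative reads or
when their population allele frequency points to a residual germline call:
alt reads <= 3, gnomAD exome AF >= 0.001, or gnomAD genome AF >= 0.005
(all thresholds overridable). Missing gnomAD annotations count as frequency
0 — absence of evidence never discards a somatic call. Structural variants
are kept when their B-allele frequency is >= 0.1 or unannotated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

from .core import SVRecord, VariantRecord


@dataclass
class FilterThresholds:
    max_alt_reads_remove: int = 3
    gnomad_exome_af: float = 0.001
    gnomad_genome_af: float = 0.005
    sv_min_baf: float = 0.1

    def __post_init__(self) -> None:
        for name in ("gnomad_exome_af", "gnomad_genome_af", "sv_min_baf"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")


#: Consequence severity ranking, most deleterious first. Labels not listed
#: rank last (with a warning).
EFFECT_SEVERITY = [
    "nonsense", "frameshift",
    "splice",
    "missense", "inframe_indel",
    "synonymous",
    "noncoding",
]
_SEVERITY_RANK = {e: i for i, e in enumerate(EFFECT_SEVERITY)}


def apply_heuristic_filters(
    variants: Iterable[VariantRecord],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the small-variant removal rules.

    Returns the retained variants and a report counting removals per
    criterion; a variant failing several criteria increments each matching
    counter but is removed once (``removed_total``).
    """
    th = thresholds or FilterThresholds()
    retained: list[VariantRecord] = []
    report = {
        "low_alt_reads": 0,
        "gnomad_exome": 0,
        "gnomad_genome": 0,
        "removed_total": 0,
        "retained": 0,
    }
    for v in variants:
        low_reads = v.alt_reads <= th.max_alt_reads_remove
        exome_hit = v.gnomad_exome_af is not None and v.gnomad_exome_af >= th.gnomad_exome_af
        genome_hit = v.gnomad_genome_af is not None and v.gnomad_genome_af >= th.gnomad_genome_af
        if low_reads:
            report["low_alt_reads"] += 1
        if exome_hit:
            report["gnomad_exome"] += 1
        if genome_hit:
            report["gnomad_genome"] += 1
        if low_reads or exome_hit or genome_hit:
            report["removed_total"] += 1
        else:
            retained.append(v)
            report["retained"] += 1
    return retained, report


def filter_svs_by_baf(
    svs: Iterable[SVRecord],
    thresholds: FilterThresholds | None = None,
) -> list[SVRecord]:
    """Keep SVs with BAF >= threshold; SVs without a BAF are retained."""
    th = thresholds or FilterThresholds()
    return [s for s in svs if s.baf is None or s.baf >= th.sv_min_baf]


def most_deleterious_per_gene(
    variants: Iterable[VariantRecord],
) -> dict[str, str]:
    """Collapse coding variants to one effect per gene, keeping the most
    deleterious consequence under :data:`EFFECT_SEVERITY`."""
    best: dict[str, tuple[int, str]] = {}
    unknown: set[str] = set()
    for v in variants:
        if v.gene is None or v.effect is None:
            continue
        rank = _SEVERITY_RANK.get(v.effect)
        if rank is None:
            unknown.add(v.effect)
            rank = len(EFFECT_SEVERITY)
        cur = best.get(v.gene)
        if cur is None or rank < cur[0]:
            best[v.gene] = (rank, v.effect)
    if unknown:
        warnings.warn(f"unknown effect label(s) ranked last: {sorted(unknown)}")
    return {gene: eff for gene, (_, eff) in best.items()}
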