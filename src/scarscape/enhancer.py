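"""Enhancer- versus gene-enrichment of paired amplified loci.

For a locus pair (gene body, putative enhancer — e.g. AR and the
AR-enhancer ~629 kbp upstream, or MYC and the PCAT1 locus), each sample's
region copy number is the maximum copy number of the overlapping
segments. The per-sample log2 enhancer/gene copy ratio is compared
against the 1:1 null (log-ratio 0, no fitted parameters); samples whose
externally studentized residual exceeds +1 are enhancer-enriched, below
-1 gene-enriched, otherwise balanced. Studentization is leave-one-out:
each sample's ratio is divided by the root mean square of the other
samples' ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import CNSegment, SampleData


@dataclass
class LocusPair:
    name: str
    gene_region: tuple[str, int, int]       # chrom, start, end (1-based)
    enhancer_region: tuple[str, int, int]

    def __post_init__(self) -> None:
        for chrom, start, end in (self.gene_region, self.enhancer_region):
            if start > end:
                raise ValueError(f"empty region {chrom}:{start}-{end}")


def load_locus_pairs(path) -> list[LocusPair]:
    """Read locus pairs from a BED-like file with columns
    chrom/start/end/pair_name/role (role in {gene, enhancer}); BED starts
    are 0-based and converted."""
    regions: dict[str, dict[str, tuple]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, role = line.split("\t")[:5]
            regions.setdefault(name, {})[role] = (chrom, int(start) + 1, int(end))
    pairs = []
    for name, roles in regions.items():
        if "gene" not in roles or "enhancer" not in roles:
            raise ValueError(f"locus pair {name!r} missing gene or enhancer row")
        pairs.append(LocusPair(name=name, gene_region=roles["gene"],
                               enhancer_region=roles["enhancer"]))
    return pairs


def region_cn(segments: Sequence[CNSegment],
              region: tuple[str, int, int]) -> float | None:
    """Maximum copy number over segments overlapping the region; None when
    nothing overlaps (the sample is then excluded with a warning)."""
    chrom, start, end = region
    best = None
    for seg in segments:
        if seg.chrom == chrom and seg.end >= start and seg.start <= end:
            if best is None or seg.cn > best:
                best = seg.cn
    return best


def studentized_log_ratios(log_ratios: np.ndarray) -> np.ndarray:
    """Externally studentized residuals against the zero-mean null:
    t_i = r_i / RMS(r_{j != i})."""
    r = np.asarray(log_ratios, dtype=np.float64)
    n = r.size
    if n < 3:
        raise ValueError("need >= 3 samples for studentization")
    total_sq = (r ** 2).sum()
    t = np.empty(n)
    for i in range(n):
        s = np.sqrt((total_sq - r[i] ** 2) / (n - 1))
        t[i] = 0.0 if s == 0 else r[i] / s
    return t


def classify_enhancer_gene(cohort: Iterable[SampleData], pair: LocusPair,
                           threshold: float = 1.0) -> pd.DataFrame:
    """Classify every sample as enhancer-enriched, gene-enriched, or
    balanced for one locus pair.

    Samples with a missing or zero region copy number are excluded with a
    warning. Returns a table with cn_enhancer, cn_gene, log2_ratio, t,
    and category per retained sample.
    """
    ids, e_cn, g_cn = [], [], []
    excluded = []
    for sample in cohort:
        e = region_cn(sample.segments, pair.enhancer_region)
        g = region_cn(sample.segments, pair.gene_region)
        if e is None or g is None or e <= 0 or g <= 0:
            excluded.append(sample.sample_id)
            continue
        ids.append(sample.sample_id)
        e_cn.append(e)
        g_cn.append(g)
    if excluded:
        warnings.warn(f"excluded sample(s) without positive copy number at "
                      f"{pair.name}: {excluded}")
    if len(ids) < 3:
        raise ValueError("need >= 3 samples with both region CNs > 0")
    e_cn = np.array(e_cn)
    g_cn = np.array(g_cn)
    ratios = np.log2(e_cn) - np.log2(g_cn)
    t = studentized_log_ratios(ratios)
    category = np.where(t > threshold, "enhancer-enriched",
                        np.where(t < -threshold, "gene-enriched", "balanced"))
    return pd.DataFrame({
        "sample_id": ids, "cn_enhancer": e_cn, "cn_gene": g_cn,
        "log2_ratio": ratios, "t": t, "category": category,
    })
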