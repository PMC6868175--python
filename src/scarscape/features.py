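"""Per-sample genomic-scar feature vectors for clustering.

Each sample contributes per-Mbp mutation rates (SNV, InDel, MNV), the
length-weighted mean genome-wide ploidy, the total number of unique
structural variants, and the relative frequencies of seven SV categories:
translocations, inversions (both orientations merged), insertions, and
tandem duplications and deletions each split at 100 kbp.

A reduced mode drops the ploidy and MNV columns for cohorts where those
calls are unavailable (e.g. primary-tumor comparison sets).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .burden import MutationCounts, tmb
from .core import CNSegment, GenomeSpec, SampleData, SVRecord

SIZE_CUT_BP = 100_000

SV_CATEGORIES = (
    "translocation",
    "inversion",
    "insertion",
    "tandem_dup_small",
    "tandem_dup_large",
    "deletion_small",
    "deletion_large",
)

FEATURE_NAMES = (
    "tmb_snv", "tmb_indel", "tmb_mnv", "mean_ploidy", "n_sv",
    "freq_tra", "freq_inv", "freq_ins",
    "freq_dup_small", "freq_dup_large",
    "freq_del_small", "freq_del_large",
)

REDUCED_FEATURE_NAMES = tuple(
    f for f in FEATURE_NAMES if f not in ("tmb_mnv", "mean_ploidy", "freq_ins"))


def categorize_sv(sv: SVRecord, size_cut: int = SIZE_CUT_BP) -> str:
    """Assign a clustering category; DUP/DEL split at ``size_cut`` with
    ties (size == cut) going to the small class."""
    if sv.svtype == "TRA":
        return "translocation"
    if sv.svtype == "INS":
        return "insertion"
    if sv.svtype in ("INV_HH", "INV_TT"):
        return "inversion"
    small = sv.size <= size_cut
    if sv.svtype == "DUP":
        return "tandem_dup_small" if small else "tandem_dup_large"
    if sv.svtype == "DEL":
        return "deletion_small" if small else "deletion_large"
    raise ValueError(f"uncategorizable svtype {sv.svtype!r}")


def mean_ploidy(segments: Sequence[CNSegment]) -> float:
    """Length-weighted mean copy number over autosomal + X segments
    (Y excluded)."""
    segs = [s for s in segments if s.chrom not in ("Y", "chrY")]
    if not segs:
        raise ValueError("mean ploidy of an empty segment set is undefined")
    lengths = np.array([s.length for s in segs], dtype=np.float64)
    cns = np.array([s.cn for s in segs], dtype=np.float64)
    return float((cns * lengths).sum() / lengths.sum())


def sample_features(sample: SampleData, genome: GenomeSpec,
                    size_cut: int = SIZE_CUT_BP) -> dict[str, float]:
    counts = MutationCounts.from_variants(sample.variants)
    snv_only = MutationCounts(snv_g=counts.snv_g)
    indel_only = MutationCounts(indel_g=counts.indel_g)
    mnv_only = MutationCounts(mnv_g=counts.mnv_g)
    feats = {
        "tmb_snv": tmb(snv_only, genome, "genomic"),
        "tmb_indel": tmb(indel_only, genome, "genomic"),
        "tmb_mnv": tmb(mnv_only, genome, "genomic"),
        "mean_ploidy": mean_ploidy(sample.segments) if sample.segments else np.nan,
        "n_sv": float(len(sample.svs)),
    }
    cat_counts = {c: 0 for c in SV_CATEGORIES}
    for sv in sample.svs:
        cat_counts[categorize_sv(sv, size_cut)] += 1
    n_sv = len(sample.svs)
    if n_sv == 0:
        warnings.warn(f"sample {sample.sample_id} has no SVs; "
                      "frequency block set to zero")
    freq_keys = ["freq_tra", "freq_inv", "freq_ins", "freq_dup_small",
                 "freq_dup_large", "freq_del_small", "freq_del_large"]
    for key, cat in zip(freq_keys, SV_CATEGORIES):
        feats[key] = cat_counts[cat] / n_sv if n_sv else 0.0
    return feats


def build_feature_matrix(cohort: Iterable[SampleData], genome: GenomeSpec,
                         size_cut: int = SIZE_CUT_BP,
                         reduced: bool = False) -> pd.DataFrame:
    """Samples x features matrix, rows ordered by sample id.

    ``reduced=True`` drops the ploidy, MNV and insertion columns for
    cohorts lacking those calls.
    """
    rows = {}
    for sample in cohort:
        rows[sample.sample_id] = sample_features(sample, genome, size_cut)
    if len(rows) < 2:
        raise ValueError("feature matrix requires >= 2 samples")
    cols = list(REDUCED_FEATURE_NAMES if reduced else FEATURE_NAMES)
    df = pd.DataFrame.from_dict(rows, orient="index")[cols]
    df.index.name = "sample_id"
    return df.sort_index()
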