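"""Chromothripsis-like event calling from rounded copy-number segments and
structural variants.

Per chromosome (Y excluded), the candidate region is the footprint of the
intrachromosomal SVs. An event passes when all five criteria hold:

(a) >= 25 intrachromosomal SVs in the event;
(b) a run of >= 7 copy-number segments oscillating between two states, or
    >= 14 oscillating among three states;
(c) footprint span >= 20 Mbp;
(d) the four orientation classes (DEL, DUP, INV_HH, INV_TT) are
    consistent with an equal multinomial distribution (chi-square
    goodness of fit, p > 0.05; Monte-Carlo p when expected counts < 5);
(e) breakpoints are non-uniformly placed along the chromosome
    (one-sample Kolmogorov-Smirnov against uniform, p <= 0.05).

All five statistics are always computed and reported (no short-circuit),
so each criterion can be inspected in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .core import CNSegment, GenomeSpec, SampleData, SVRecord

ORIENTATION_CLASSES = ("DEL", "DUP", "INV_HH", "INV_TT")


@dataclass
class ChromothripsisCriteria:
    min_sv: int = 25
    min_osc2: int = 7
    min_osc3: int = 14
    min_size_bp: int = 20_000_000
    equal_type_p_gt: float = 0.05
    nonrandom_p_le: float = 0.05


@dataclass
class ChromothripsisEvent:
    chrom: str
    start: int
    end: int
    n_sv: int
    osc2_run: int
    osc3_run: int
    sv_type_counts: dict[str, int]
    p_equal_types: Optional[float]
    p_nonrandom: Optional[float]
    passed: bool
    criteria_met: dict[str, bool]


def oscillation_runs(segments: Sequence[CNSegment],
                     region: Optional[tuple[int, int]] = None) -> tuple[int, int]:
    """Longest oscillating runs of rounded CN states.

    ``osc2``: longest run of consecutive segments strictly alternating
    between exactly two distinct integer states. ``osc3``: longest run in
    which every adjacent pair differs and at most three distinct states
    occur. Run lengths are counted in segments.
    """
    segs = sorted(segments, key=lambda s: s.start)
    if region is not None:
        lo, hi = region
        segs = [s for s in segs if s.end >= lo and s.start <= hi]
    states = [s.cn_round for s in segs]
    n = len(states)
    if n == 0:
        return 0, 0

    osc2 = 1
    i = 0
    while i < n:
        j = i + 1
        while j < n and states[j] != states[j - 1] and (
                j < i + 2 or states[j] == states[j - 2]):
            j += 1
        osc2 = max(osc2, j - i)
        i = max(i + 1, j - 1)

    osc3 = 1
    start = 0
    for i in range(n):
        if i > 0 and states[i] == states[i - 1]:
            start = i
        while len(set(states[start:i + 1])) > 3:
            start += 1
        osc3 = max(osc3, i - start + 1)
    return osc2, osc3


def equal_type_test(sv_type_counts: dict[str, int] | Sequence[int],
                    n_mc: int = 100_000, seed: int = 0) -> float:
    """Goodness-of-fit p-value of the four orientation-class counts
    against equal proportions.

    Uses the chi-square distribution when all expected counts are >= 5,
    otherwise a seeded Monte-Carlo estimate with ``n_mc`` multinomial
    draws (add-one correction).
    """
    if isinstance(sv_type_counts, dict):
        counts = np.array([sv_type_counts.get(c, 0) for c in ORIENTATION_CLASSES],
                          dtype=np.float64)
    else:
        counts = np.asarray(sv_type_counts, dtype=np.float64)
    total = counts.sum()
    if total == 0:
        raise ValueError("equal-type test requires at least one SV")
    k = counts.size
    expected = total / k
    statistic = float(((counts - expected) ** 2 / expected).sum())
    if expected >= 5:
        return float(stats.chi2.sf(statistic, df=k - 1))
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(int(total), np.full(k, 1.0 / k), size=n_mc)
    sim = ((draws - expected) ** 2 / expected).sum(axis=1)
    return float((1 + np.sum(sim >= statistic - 1e-9)) / (1 + n_mc))


def nonrandom_breakpoint_test(breakpoints: Sequence[int],
                              chrom_length: int) -> Optional[float]:
    """One-sample KS test of breakpoint positions against the uniform
    distribution over the chromosome; small p evidences clustering.
    Returns None (criterion fails) with fewer than 5 breakpoints."""
    bp = np.asarray(breakpoints, dtype=np.float64)
    if bp.size < 5:
        return None
    res = stats.kstest(bp / chrom_length, "uniform")
    return float(res.pvalue)


def call_chromothripsis(
    sample: SampleData,
    genome: GenomeSpec,
    criteria: ChromothripsisCriteria | None = None,
    seed: int = 0,
) -> list[ChromothripsisEvent]:
    """Evaluate every chromosome carrying intrachromosomal SVs.

    Expects BAF-filtered SVs and rounded CN segments; chromosome Y is
    excluded. Insertions count toward the SV total but not the
    orientation-class test; translocations are ignored.
    """
    crit = criteria or ChromothripsisCriteria()
    by_chrom: dict[str, list[SVRecord]] = {}
    for sv in sample.svs:
        if sv.svtype == "TRA":
            continue
        if sv.chrom1 in ("Y", "chrY"):
            continue
        by_chrom.setdefault(sv.chrom1, []).append(sv)
    seg_by_chrom: dict[str, list[CNSegment]] = {}
    for seg in sample.segments:
        if seg.chrom in ("Y", "chrY"):
            continue
        seg_by_chrom.setdefault(seg.chrom, []).append(seg)

    events = []
    for chrom in sorted(by_chrom):
        svs = by_chrom[chrom]
        positions = [p for sv in svs for p in (sv.pos1, sv.pos2)]
        start, end = min(positions), max(positions)
        n_sv = len(svs)
        type_counts = {c: 0 for c in ORIENTATION_CLASSES}
        for sv in svs:
            if sv.svtype in type_counts:
                type_counts[sv.svtype] += 1
        osc2, osc3 = oscillation_runs(seg_by_chrom.get(chrom, []), (start, end))
        p_equal = (equal_type_test(type_counts, seed=seed)
                   if sum(type_counts.values()) > 0 else None)
        chrom_len = genome.chroms.get(chrom, end)
        p_nonrandom = nonrandom_breakpoint_test(positions, chrom_len)
        met = {
            "n_sv": n_sv >= crit.min_sv,
            "oscillation": osc2 >= crit.min_osc2 or osc3 >= crit.min_osc3,
            "size": (end - start) >= crit.min_size_bp,
            "equal_types": p_equal is not None and p_equal > crit.equal_type_p_gt,
            "nonrandom": p_nonrandom is not None and p_nonrandom <= crit.nonrandom_p_le,
        }
        events.append(ChromothripsisEvent(
            chrom=chrom, start=start, end=end, n_sv=n_sv,
            osc2_run=osc2, osc3_run=osc3, sv_type_counts=type_counts,
            p_equal_types=p_equal, p_nonrandom=p_nonrandom,
            passed=all(met.values()), criteria_met=met,
        ))
    return events
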