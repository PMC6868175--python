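"""Kataegis (regional hypermutation) detection.

Per chromosome, consecutive SNV positions are reduced to log10
inter-mutation distances (IMDs) and fit with a globally optimal
piecewise-constant segmentation: a dynamic program that, for a given
segment count S, minimizes the total within-segment sum of squared
deviations. The maximum S is one segment per five consecutive SNVs,
capped at 5000 per chromosome. A segment is called a kataegis focus when
its raw-scale mean IMD is <= 2000 bp and it contains at least five SNVs;
adjacent qualifying segments are merged. A sample with more than 200
events genome-wide is reset to zero events — such samples are
hypermutated throughout rather than locally.

The DP is the exact O(S m^2) layered recursion with prefix-sum segment
costs; the inner loops are JIT-compiled when numba is available. Only
hypermutated (MSI-like) samples produce chromosomes dense enough for the
quadratic term to be felt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import SampleData

MAX_SEGMENTS_PER_CHROM = 5000
SNVS_PER_SEGMENT = 5
MAX_MEAN_IMD = 2000.0
MIN_EVENT_SNVS = 5
HYPERMUTATOR_EVENT_LIMIT = 200


@dataclass
class ImdSeries:
    """Sorted SNV positions on one chromosome and their log10 IMDs.

    SNVs at identical positions are collapsed, so every distance is
    >= 1 bp (log10 of 1 bp is 0).
    """

    chrom: str
    positions: np.ndarray
    log_imd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pos = np.unique(np.asarray(self.positions, dtype=np.int64))
        self.positions = pos
        diffs = np.diff(pos).astype(np.float64)
        self.log_imd = np.log10(diffs) if diffs.size else diffs


@dataclass
class KataegisEvent:
    chrom: str
    start: int
    end: int
    n_snvs: int
    mean_imd: float


@dataclass
class KataegisResult:
    events: list[KataegisEvent]
    hypermutator_reset: bool = False
    raw_event_count: int = 0


def _dp_core(cs, css, m, S):  # pragma: no cover - exercised via wrapper
    """Exact S-segment SSE segmentation of a series with prefix sums
    cs/css (length m+1). Returns (best_cost, boundaries).

    best[s][i] = min cost of splitting the first i points into s
    segments; ties break toward the smallest split index.
    """
    INF = np.inf
    prev = np.full(m + 1, INF)
    cur = np.full(m + 1, INF)
    arg = np.zeros((S + 1, m + 1), dtype=np.int32)
    # layer 1: single segment over y[0:i]
    for i in range(1, m + 1):
        prev[i] = css[i] - css[0] - (cs[i] - cs[0]) ** 2 / i
    for s in range(2, S + 1):
        for i in range(s, m + 1):
            best_val = INF
            best_j = s - 1
            csi = cs[i]
            cssi = css[i]
            for j in range(s - 1, i):
                d = csi - cs[j]
                c = prev[j] + cssi - css[j] - d * d / (i - j)
                if c < best_val:
                    best_val = c
                    best_j = j
            cur[i] = best_val
            arg[s, i] = best_j
        for i in range(m + 1):
            prev[i] = cur[i]
            cur[i] = INF
    boundaries = np.zeros(S + 1, dtype=np.int64)
    boundaries[S] = m
    b = m
    for s in range(S, 0, -1):
        b = arg[s, b] if s > 1 else 0
        boundaries[s - 1] = b
    return prev[m], boundaries


try:  # JIT when available; the pure-Python path is identical
    from numba import njit

    _dp_core = njit(cache=True)(_dp_core)
except ImportError:  # pragma: no cover
    pass


def segment_series(series: ImdSeries, max_segments: int):
    """Optimal piecewise-constant fit of the log10 IMD series.

    Returns ``(boundaries, means, cost)`` where boundaries is an array
    b_0=0 < b_1 < ... < b_S=m delimiting the S = min(max_segments, m)
    segments over the distance indices, means are per-segment means of
    the log values, and cost is the total within-segment SSE.
    """
    if max_segments < 1:
        raise ValueError("max_segments must be >= 1")
    y = np.asarray(series.log_imd, dtype=np.float64)
    m = y.size
    if m == 0:
        return np.zeros(1, dtype=np.int64), np.zeros(0), 0.0
    S = min(max_segments, m)
    cs = np.concatenate(([0.0], np.cumsum(y)))
    css = np.concatenate(([0.0], np.cumsum(y * y)))
    cost, boundaries = _dp_core(cs, css, m, S)
    means = np.array([
        (cs[boundaries[k + 1]] - cs[boundaries[k]]) / (boundaries[k + 1] - boundaries[k])
        for k in range(S)
    ])
    return boundaries, means, float(max(cost, 0.0))


def _chromosome_events(chrom: str, positions: np.ndarray,
                       merge_adjacent: bool = True) -> list[KataegisEvent]:
    series = ImdSeries(chrom=chrom, positions=positions)
    m = series.log_imd.size
    if m == 0:
        return []
    S = min(MAX_SEGMENTS_PER_CHROM, max(1, m // SNVS_PER_SEGMENT))
    boundaries, _, _ = segment_series(series, S)
    raw = np.diff(series.positions).astype(np.float64)
    qualifying = []
    for k in range(len(boundaries) - 1):
        lo, hi = boundaries[k], boundaries[k + 1]
        n_snvs = hi - lo + 1
        if n_snvs >= MIN_EVENT_SNVS and raw[lo:hi].mean() <= MAX_MEAN_IMD:
            qualifying.append((lo, hi))
    if merge_adjacent:
        merged: list[list[int]] = []
        for lo, hi in qualifying:
            if merged and merged[-1][1] == lo:
                merged[-1][1] = hi
            else:
                merged.append([lo, hi])
        qualifying = [(lo, hi) for lo, hi in merged]
    return [
        KataegisEvent(
            chrom=chrom,
            start=int(series.positions[lo]),
            end=int(series.positions[hi]),
            n_snvs=int(hi - lo + 1),
            mean_imd=float(raw[lo:hi].mean()),
        )
        for lo, hi in qualifying
    ]


def call_kataegis(sample: SampleData, merge_adjacent: bool = True,
                  hypermutator_limit: Optional[int] = HYPERMUTATOR_EVENT_LIMIT
                  ) -> KataegisResult:
    """Detect kataegis events from the sample's SNVs (only SNVs are used).

    When the genome-wide event count exceeds ``hypermutator_limit`` the
    sample is reported with zero events and the reset flag raised.
    """
    by_chrom: dict[str, list[int]] = {}
    for v in sample.variants:
        if v.vclass == "SNV":
            by_chrom.setdefault(v.chrom, []).append(v.pos)
    events: list[KataegisEvent] = []
    for chrom in sorted(by_chrom):
        events.extend(_chromosome_events(
            chrom, np.asarray(by_chrom[chrom]), merge_adjacent=merge_adjacent))
    raw_count = len(events)
    if hypermutator_limit is not None and raw_count > hypermutator_limit:
        return KataegisResult(events=[], hypermutator_reset=True,
                              raw_event_count=raw_count)
    return KataegisResult(events=events, hypermutator_reset=False,
                          raw_event_count=raw_count)
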