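"""Mutational-signature analysis on the 96 trinucleotide substitution
classes.

A sample's SNVs are tabulated into the standard pyrimidine-normalized
96-class spectrum (substitution C>A..T>G by 5'/3' flanking base). Two
decompositions are provided:

* constrained refitting of a spectrum against a fixed signature catalog by
  non-negative least squares (active-set NNLS, deterministic);
* de novo extraction by KL-divergence multiplicative-update NMF with
  random restarts, scored per rank by cophenetic correlation of the
  consensus matrix, residual sum of squares, and mean silhouette width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import VariantRecord

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Fixed class order: alphabetical by substitution, then 5' flank, then 3'.
CLASSES_96 = [
    f"{f5}[{sub}]{f3}"
    for sub in SUBSTITUTIONS
    for f5 in BASES
    for f3 in BASES
]
_CLASS_INDEX = {c: i for i, c in enumerate(CLASSES_96)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def snv_class(trinucleotide: str, ref: str, alt: str) -> str:
    """96-class label for an SNV, reverse-complementing purine-reference
    calls onto the pyrimidine strand."""
    if len(trinucleotide) != 3:
        raise ValueError(f"trinucleotide must be a 3-mer, got {trinucleotide!r}")
    if trinucleotide[1] != ref:
        raise ValueError(
            f"trinucleotide {trinucleotide} middle base does not match ref {ref}")
    if ref in "AG":
        trinucleotide = revcomp(trinucleotide)
        ref = trinucleotide[1]
        alt = alt.translate(_COMPLEMENT)
    return f"{trinucleotide[0]}[{ref}>{alt}]{trinucleotide[2]}"


@dataclass
class Spectrum96:
    """Counts over the 96 substitution classes for one sample."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros(96))
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have exactly 96 entries")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class SignatureCatalog:
    """96 x K matrix of signature probability columns."""

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape[0] != 96:
            raise ValueError("catalog must have 96 rows")
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("one name per signature column required")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each catalog column must sum to 1 (+-1e-6)")

    @classmethod
    def from_tsv(cls, path) -> "SignatureCatalog":
        """Read a catalog TSV: first column holds 'A[C>A]A'-style labels,
        remaining columns one signature each. Rows are reordered into the
        canonical class order."""
        df = pd.read_csv(path, sep="\t")
        label_col = df.columns[0]
        df = df.set_index(label_col).loc[CLASSES_96]
        return cls(matrix=df.to_numpy(), names=list(df.columns))


@dataclass
class SignatureFit:
    weights: np.ndarray
    relative_contributions: Optional[np.ndarray]
    residual_norm: float
    names: list[str]


def build_spectrum(snvs: Iterable[VariantRecord],
                   reference: Optional[dict] = None) -> Spectrum96:
    """Tabulate SNVs into a 96-class spectrum.

    Contexts come from each record's trinucleotide field, or are fetched
    from ``reference`` (a mapping chrom -> sequence, e.g. a pyfaidx.Fasta)
    when absent. SNVs with no obtainable context are excluded and counted
    in ``n_excluded``.
    """
    counts = np.zeros(96)
    excluded = 0
    for v in snvs:
        if v.vclass != "SNV":
            continue
        tnc = v.trinucleotide
        if tnc is None and reference is not None and v.chrom in reference:
            seq = reference[v.chrom]
            if 2 <= v.pos <= len(seq) - 1:
                tnc = str(seq[v.pos - 2:v.pos + 1]).upper()
        if tnc is None:
            excluded += 1
            continue
        try:
            counts[_CLASS_INDEX[snv_class(tnc, v.ref, v.alt)]] += 1
        except (ValueError, KeyError):
            excluded += 1
    return Spectrum96(counts=counts, n_excluded=excluded)


def fit_signatures(spectrum: Spectrum96, catalog: SignatureCatalog) -> SignatureFit:
    """Refit a spectrum as a non-negative linear combination of catalog
    signatures (active-set NNLS; deterministic)."""
    m = spectrum.counts
    if m.sum() == 0:
        return SignatureFit(weights=np.zeros(catalog.matrix.shape[1]),
                            relative_contributions=None,
                            residual_norm=0.0, names=list(catalog.names))
    weights, residual = optimize.nnls(catalog.matrix, m)
    total = weights.sum()
    rel = weights / total if total > 0 else None
    return SignatureFit(weights=weights, relative_contributions=rel,
                        residual_norm=float(residual), names=list(catalog.names))


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# de novo NMF
# ---------------------------------------------------------------------------

_EPS = 1e-12


def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized Kullback-Leibler divergence D(V || WH)."""
    mask = V > 0
    d = float(np.sum(V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS))))
    return d - float(V.sum()) + float(WH.sum())

def nmf_kl(V: np.ndarray, rank: int, rng: np.random.Generator,
           max_iter: int = 200, tol: float = 1e-6):
    """One KL-NMF run with multiplicative updates.

    Returns (W, H, objectives) where objectives records the divergence
    after every update sweep (non-increasing by construction).
    """
    n_feat, n_samp = V.shape
    scale = np.sqrt(V.mean() / rank)
    W = rng.uniform(0.1, 1.0, size=(n_feat, rank)) * scale
    H = rng.uniform(0.1, 1.0, size=(rank, n_samp)) * scale
    objectives = [kl_divergence(V, W @ H)]
    for _ in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        W *= (V / WH) @ H.T / np.maximum(H.sum(axis=1), _EPS)
        WH = np.maximum(W @ H, _EPS)
        H *= W.T @ (V / WH) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        obj = kl_divergence(V, W @ H)
        objectives.append(obj)
        if abs(objectives[-2] - obj) <= tol * max(abs(objectives[-2]), 1.0):
            break
    return W, H, objectives


def _consensus_metrics(connectivity_sum: np.ndarray, n_runs: int, rank: int):
    from sklearn.metrics import silhouette_score

    consensus = connectivity_sum / n_runs
    n = consensus.shape[0]
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.average(condensed)
    if condensed.max() <= _EPS:
        warnings.warn(f"degenerate consensus at rank {rank}: all runs agree "
                      "on a single cluster")
        return np.nan, np.nan, consensus
    coph_corr, _ = hierarchy.cophenet(Z, condensed)
    labels = hierarchy.fcluster(Z, rank, criterion="maxclust")
    if len(set(labels)) < 2 or len(set(labels)) >= n:
        sil = np.nan
    else:
        sil = float(silhouette_score(dist, labels, metric="precomputed"))
    return float(coph_corr), sil, consensus


def denovo_nmf(spectra: np.ndarray, rank_range=(2, 15), n_runs: int = 50,
               seed: int = 0, chosen_rank: int = 5, max_iter: int = 200):
    """Rank survey + factorization for a cohort spectrum matrix.

    ``spectra`` is 96 x n_samples. For each rank in ``rank_range`` the NMF
    is restarted ``n_runs`` times from seeded random initializations; the
    run-wise sample assignments (dominant exposure) define a consensus
    matrix whose cophenetic correlation and silhouette measure rank
    stability, and the best run supplies the residual sum of squares.

    Returns ``(metrics, W, H)``: a per-rank DataFrame and the best-run
    factorization at ``chosen_rank``.
    """
    V = np.asarray(spectra, dtype=np.float64)
    if V.ndim != 2 or V.shape[1] < 2:
        raise ValueError("need a 96 x n matrix with >= 2 samples")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    lo, hi = rank_range
    ranks = [r for r in range(lo, hi + 1) if r < min(V.shape)]
    if not ranks:
        raise ValueError("no admissible rank below min(matrix dims)")
    if chosen_rank not in ranks:
        raise ValueError(f"chosen_rank {chosen_rank} outside admissible ranks")
    master = np.random.SeedSequence(seed)
    rows = []
    chosen = None
    for rank, ss in zip(ranks, master.spawn(len(ranks))):
        best_obj = np.inf
        best_WH = None
        conn_sum = np.zeros((V.shape[1], V.shape[1]))
        for run_ss in ss.spawn(n_runs):
            rng = np.random.default_rng(run_ss)
            W, H, objs = nmf_kl(V, rank, rng, max_iter=max_iter)
            labels = H.argmax(axis=0)
            conn_sum += labels[:, None] == labels[None, :]
            if objs[-1] < best_obj:
                best_obj = objs[-1]
                best_WH = (W, H)
        coph, sil, _ = _consensus_metrics(conn_sum, n_runs, rank)
        W, H = best_WH
        rss = float(np.sum((V - W @ H) ** 2))
        rows.append({"rank": rank, "cophenetic": coph, "rss": rss,
                     "silhouette": sil})
        if rank == chosen_rank:
            chosen = best_WH
    metrics = pd.DataFrame(rows)
    W, H = chosen
    return metrics, W, H


def contributions_by_etiology(fit: SignatureFit, etiology: dict[str, str]) -> dict[str, float]:
    """Sum relative contributions over a signature -> etiology grouping."""
    if fit.relative_contributions is None:
        return {}
    out: dict[str, float] = {}
    for name, c in zip(fit.names, fit.relative_contributions):
        group = etiology.get(name, "unknown")
        out[group] = out.get(group, 0.0) + float(c)
    return out
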