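"""Unsupervised genotype discovery and cluster-level statistics.

The clustering recipe: per-feature root-mean-square scaling without
centering, sample-by-sample dissimilarity d = 1 - r (Pearson correlation
between feature rows), Ward linkage applied directly to those
dissimilarities without squaring (the classic R ``ward.D`` contract, as
opposed to ``ward.D2``), optimal leaf ordering, an automated elbow on the
within-cluster sum-of-squares curve, and feature-resampling bootstrap
support per dendrogram node. Cluster-by-trait enrichment uses two-sided
Fisher exact tests with Benjamini-Hochberg correction applied jointly
across all tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


@dataclass
class ClusterResult:
    linkage: np.ndarray              # scipy-format (n-1) x 4 merge table
    leaf_order: list[str]            # sample ids after optimal leaf ordering
    k: int
    labels: pd.Series                # cluster label per sample id
    bootstrap_support: Optional[pd.DataFrame]
    wss: pd.DataFrame                # k vs within-cluster sum of squares


def scale_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each column by its root mean square, sqrt(sum(x^2)/(n-1)),
    without centering (the R ``scale(x, center=FALSE)`` convention)."""
    X = matrix.to_numpy(dtype=np.float64)
    rms = np.sqrt((X ** 2).sum(axis=0) / (X.shape[0] - 1))
    zero = np.flatnonzero(rms == 0)
    if zero.size:
        names = [matrix.columns[i] for i in zero]
        raise ValueError(f"all-zero feature column(s): {names}")
    return pd.DataFrame(X / rms, index=matrix.index, columns=matrix.columns)


def pearson_dissimilarity(scaled: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample dissimilarity d = 1 - Pearson r between rows."""
    X = scaled.to_numpy(dtype=np.float64)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 features per sample")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = [scaled.index[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant feature row(s), Pearson undefined: {bad}")
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.maximum((d + d.T) / 2.0, 0.0)
    return pd.DataFrame(d, index=scaled.index, columns=scaled.index)


def ward_linkage(dissimilarity: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Agglomerative Ward merging by Lance-Williams updates applied to the
    given dissimilarities without squaring (``ward.D``).

    Returns a scipy-format linkage matrix; the recorded merge height is
    the criterion value at the merge. Ties are broken toward the lowest
    (i, j) pair in current index order, so the result is deterministic.
    """
    D = np.asarray(dissimilarity, dtype=np.float64)
    if np.isnan(D).any():
        raise ValueError("dissimilarity matrix contains NaN")
    n = D.shape[0]
    d = D.copy()
    np.fill_diagonal(d, np.inf)
    sizes = np.ones(n)
    cluster_id = np.arange(n)
    active = np.ones(n, dtype=bool)
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], d, np.inf)
        iu = np.triu_indices(n, k=1)
        flat = masked[iu]
        best = int(np.argmin(flat))  # first occurrence = lexicographic min
        i, j = int(iu[0][best]), int(iu[1][best])
        height = d[i, j]
        si, sj = sizes[i], sizes[j]
        # Lance-Williams ward coefficients on the raw dissimilarities
        for k in np.flatnonzero(active):
            if k == i or k == j:
                continue
            sk = sizes[k]
            new = ((si + sk) * d[i, k] + (sj + sk) * d[j, k] - sk * height) / (
                si + sj + sk)
            d[i, k] = d[k, i] = new
        Z[step] = [min(cluster_id[i], cluster_id[j]),
                   max(cluster_id[i], cluster_id[j]), height, si + sj]
        sizes[i] = si + sj
        active[j] = False
        cluster_id[i] = n + step
    return Z


def optimal_leaf_order(Z: np.ndarray, dissimilarity: pd.DataFrame | np.ndarray
                       ) -> np.ndarray:
    """Leaf permutation minimizing the sum of adjacent-leaf
    dissimilarities among the 2^(n-1) orderings consistent with the tree.

    Bar-Joseph dynamic program: per node, the table M[a, b] holds the
    best cost of laying out the node's subtree with leftmost leaf a and
    rightmost leaf b; children combine through a min-plus product over
    the junction pair. Exact, verified against exhaustive enumeration at
    small n.
    """
    D = np.asarray(dissimilarity, dtype=np.float64)
    n = D.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)

    leaves: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    M: dict[int, np.ndarray] = {i: np.zeros((1, 1)) for i in range(n)}
    # junction argmins per internal node: (k index within left child,
    # m index within right child) for every (a, b)
    args: dict[int, tuple] = {}
    children: dict[int, tuple[int, int]] = {}

    for step, (a, b, _, _) in enumerate(Z):
        l, r = int(a), int(b)
        node = n + step
        children[node] = (l, r)
        Ll, Lr = leaves[l], leaves[r]
        Dlr = D[np.ix_(Ll, Lr)]
        # T[a, k-choice, m] = Ml[a, k] + D[k, m]; minimize over k
        stack = M[l][:, :, None] + Dlr[None, :, :]
        k_arg = stack.argmin(axis=1)
        T = np.take_along_axis(stack, k_arg[:, None, :], axis=1)[:, 0, :]
        # add right-side table; minimize over m
        stack2 = T[:, :, None] + M[r][None, :, :]
        m_arg = stack2.argmin(axis=1)
        cross = np.take_along_axis(stack2, m_arg[:, None, :], axis=1)[:, 0, :]
        nl, nr = len(Ll), len(Lr)
        full = np.full((nl + nr, nl + nr), np.inf)
        full[:nl, nl:] = cross
        full[nl:, :nl] = cross.T  # reversal symmetry
        M[node] = full
        args[node] = (k_arg, m_arg)
        leaves[node] = np.concatenate([Ll, Lr])

    root = 2 * n - 2

    def _reconstruct(node: int, a: int, b: int) -> list[int]:
        """Resolve (node, leftmost position a, rightmost position b) to
        the ordered list of leaf ids; positions index the node's leaf
        array, a leaf node resolves to its own id."""
        if node < n:
            return [node]
        l, r = children[node]
        nl = len(leaves[l])
        if a >= nl:  # reversed orientation
            return _reconstruct(node, b, a)[::-1]
        k_arg, m_arg = args[node]
        bj = b - nl
        m = int(m_arg[a, bj])
        k = int(k_arg[a, m])
        return _reconstruct(l, a, k) + _reconstruct(r, m, bj)

    flat = np.argmin(M[root])
    a, b = np.unravel_index(flat, M[root].shape)
    return np.array(_reconstruct(root, int(a), int(b)))


def _wss_for_labels(D: np.ndarray, labels: np.ndarray) -> float:
    """Ward-style within-cluster cost in dissimilarity space:
    sum over clusters of sum_{i<j in C} d_ij / |C|."""
    total = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        sub = D[np.ix_(idx, idx)]
        total += float(sub[np.triu_indices(len(idx), 1)].sum()) / len(idx)
    return total


def choose_k_elbow(scaled: pd.DataFrame, Z: np.ndarray, k_max: int = 15,
                   weak_threshold: float = 0.2) -> tuple[int, pd.DataFrame]:
    """Elbow selection of the cluster count.

    For tree cuts at k = 1..k_max the within-cluster cost is evaluated in
    the same dissimilarity space the tree was built in (the ward
    criterion, sum of within-cluster dissimilarities over cluster size).
    The elbow is the k with maximum perpendicular distance to the chord
    joining the curve endpoints, computed on the log of the cost — the
    curve typically spans orders of magnitude, and the log-scale chord
    tracks where the curve flattens permanently, which is what visual
    inspection responds to. A warning is raised when the curvature is
    weak (max relative chord distance below ``weak_threshold``).
    """
    n = len(scaled)
    if k_max >= n:
        raise ValueError("k_max must be < number of samples")
    D = pearson_dissimilarity(scaled).to_numpy()
    ks = np.arange(1, k_max + 1)
    wss = np.array([
        _wss_for_labels(D, hierarchy.fcluster(Z, t=k, criterion="maxclust"))
        for k in ks
    ])
    logw = np.log(np.maximum(wss, 1e-12))
    p1 = np.array([ks[0], logw[0]], dtype=float)
    p2 = np.array([ks[-1], logw[-1]], dtype=float)
    span = p2 - p1
    norm = np.linalg.norm(span)
    if norm == 0:
        dist = np.zeros_like(logw)
    else:
        dist = np.abs(span[0] * (p1[1] - logw) - (p1[0] - ks) * span[1]) / norm
    k_opt = int(ks[np.argmax(dist)])
    rel = dist.max() / max(logw[0] - logw[-1], 1e-12)
    if rel < weak_threshold:
        warnings.warn("elbow curvature is weak; cluster count is unreliable")
    table = pd.DataFrame({"k": ks, "wss": wss, "chord_distance": dist})
    return k_opt, table


def _clades(Z: np.ndarray, ids: Sequence) -> list[frozenset]:
    n = len(ids)
    members: dict[int, frozenset] = {i: frozenset([ids[i]]) for i in range(n)}
    out = []
    for step, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        out.append(merged)
    return out


def bootstrap_support(matrix: pd.DataFrame, Z: np.ndarray,
                      n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Ordinary bootstrap probability per internal node.

    Features (columns) are resampled with replacement, the full pipeline
    (scale, 1-r dissimilarity, ward.D) is re-run, and each original node
    is scored by the fraction of replicate trees containing an identical
    leaf set.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    ids = list(matrix.index)
    original = _clades(Z, ids)
    hits = np.zeros(len(original))
    rng = np.random.default_rng(seed)
    p = matrix.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, p, size=p)
        boot = matrix.iloc[:, cols]
        boot.columns = range(p)
        try:
            rep = ward_linkage(pearson_dissimilarity(scale_features(boot)))
        except ValueError:
            continue  # degenerate resample (e.g. all-zero column)
        rep_clades = set(_clades(rep, ids))
        for idx, clade in enumerate(original):
            if clade in rep_clades:
                hits[idx] += 1
    return pd.DataFrame({
        "node": np.arange(len(original)),
        "size": [len(c) for c in original],
        "support": hits / n_boot,
    })


def cluster(matrix: pd.DataFrame, k: Optional[int] = None, k_max: int = 15,
            n_boot: int = 0, seed: int = 0) -> ClusterResult:
    """Run the full unsupervised recipe on a feature matrix."""
    scaled = scale_features(matrix)
    D = pearson_dissimilarity(scaled)
    Z = ward_linkage(D)
    order = optimal_leaf_order(Z, D)
    k_auto, wss = choose_k_elbow(scaled, Z, k_max=min(k_max, len(matrix) - 1))
    k = k or k_auto
    labels = pd.Series(hierarchy.fcluster(Z, t=k, criterion="maxclust"),
                       index=matrix.index, name="cluster")
    support = (bootstrap_support(matrix, Z, n_boot=n_boot, seed=seed)
               if n_boot >= 2 else None)
    return ClusterResult(
        linkage=Z, leaf_order=[matrix.index[i] for i in order], k=k,
        labels=labels, bootstrap_support=support, wss=wss)


# ---------------------------------------------------------------------------
# enrichment and cohort comparisons
# ---------------------------------------------------------------------------

def cluster_enrichment(labels: pd.Series, traits: pd.DataFrame,
                       q_flag: float = 0.05) -> pd.DataFrame:
    """Two-sided Fisher exact enrichment of binary traits per cluster.

    BH correction is applied jointly across all (cluster, trait) tests.
    """
    traits = traits.loc[labels.index].astype(bool)
    rows = []
    for clust in sorted(pd.unique(labels)):
        in_mask = (labels == clust).to_numpy()
        for trait in traits.columns:
            yes = traits[trait].to_numpy()
            a = int((in_mask & yes).sum())
            b = int((in_mask & ~yes).sum())
            c = int((~in_mask & yes).sum())
            d = int((~in_mask & ~yes).sum())
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append({
                "cluster": clust, "trait": trait,
                "freq_in": a / max(a + b, 1), "freq_out": c / max(c + d, 1),
                "odds_ratio": odds, "p": p,
            })
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["q"] <= q_flag
    return df


TCGA_CLASS_ORDER = ("ERG", "ETV1", "ETV4", "FLI1", "SPOP", "FOXA1", "IDH1")


def classify_tcga(flags: pd.DataFrame) -> tuple[pd.Series, float]:
    """Supervised mutually-exclusive classification.

    ``flags`` columns: ERG/ETV1/ETV4/FLI1 (gene-break flags) and
    SPOP/FOXA1/IDH1 (coding mutation or CN aberration flags), boolean.
    Each sample gets the first matching class in precedence order, else
    'unclassified'. Returns (classes, classified fraction).
    """
    classes = []
    for _, row in flags.iterrows():
        for cls in TCGA_CLASS_ORDER:
            if cls in flags.columns and bool(row[cls]):
                classes.append(cls)
                break
        else:
            classes.append("unclassified")
    out = pd.Series(classes, index=flags.index, name="tcga_class")
    frac = float((out != "unclassified").mean())
    return out, frac


def compare_cohorts(aberrations_a: pd.DataFrame, aberrations_b: pd.DataFrame,
                    tmb_a: Optional[Sequence[float]] = None,
                    tmb_b: Optional[Sequence[float]] = None) -> dict:
    """Per-gene mutational-frequency comparison between two cohorts.

    Inputs are samples x genes boolean tables (multiple aberrations per
    gene per sample already collapsed to one event). Returns a per-gene
    table (frequency difference, odds ratio, Fisher p, BH q) and, when
    TMB vectors are supplied, a two-sided Wilcoxon rank-sum comparison.
    """
    if not len(aberrations_a) or not len(aberrations_b):
        raise ValueError("both cohorts must be non-empty")
    genes = list(aberrations_a.columns)
    if set(genes) != set(aberrations_b.columns):
        raise ValueError("cohorts must share the same gene universe")
    na, nb = len(aberrations_a), len(aberrations_b)
    rows = []
    for gene in genes:
        a = int(aberrations_a[gene].astype(bool).sum())
        b = int(aberrations_b[gene].astype(bool).sum())
        odds, p = stats.fisher_exact([[a, na - a], [b, nb - b]])
        rows.append({"gene": gene, "freq_a": a / na, "freq_b": b / nb,
                     "freq_diff": a / na - b / nb, "odds_ratio": odds, "p": p})
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    result = {"genes": table}
    if tmb_a is not None and tmb_b is not None:
        stat, p = stats.ranksums(tmb_a, tmb_b)
        result["tmb_wilcoxon"] = {"statistic": float(stat), "p": float(p)}
    return result


def pca_cos2(matrix: pd.DataFrame, center: bool = True,
             scale: bool = True) -> dict:
    """SVD-based PCA with per-feature cos2 (squared quality of
    representation) per component.

    With all components retained, each feature's cos2 values sum to 1, so
    cos2 ranks which components carry each feature.
    """
    X = matrix.to_numpy(dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("PCA requires >= 2 samples")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("constant feature column; cannot scale")
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # variable coordinates: loading * component standard deviation
    coord = Vt.T * (s / np.sqrt(max(X.shape[0] - 1, 1)))
    denom = (coord ** 2).sum(axis=1, keepdims=True)
    cos2 = (coord ** 2) / np.where(denom == 0, 1.0, denom)
    comp_names = [f"PC{i+1}" for i in range(len(s))]
    return {
        "components": pd.DataFrame(Vt.T, index=matrix.columns, columns=comp_names),
        "explained_variance": pd.Series(s ** 2 / max(X.shape[0] - 1, 1),
                                        index=comp_names),
        "cos2": pd.DataFrame(cos2, index=matrix.columns, columns=comp_names),
    }
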