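"""The multivariate nectar-syndrome stage: PCA, UPGMA clustering, the
hand-built pollination-syndrome distance, the Mantel permutation test, and
the λ signal of syndrome on the nectar dendrogram.

Nectar-composition variables are z-scored before Euclidean distances are
taken; UPGMA (average linkage) turns the distance matrix into an
ultrametric dendrogram.  The association between nectar composition and
pollination syndrome is tested two ways: a Mantel test of the nectar
distance matrix against a syndrome distance matrix (same syndrome 0,
different 1, except 0.5 between the bee or butterfly classes and the mixed
bee-and-butterfly class), and a likelihood-ratio test of Pagel's λ for the
discrete syndrome on the dendrogram against a star-phylogeny (white noise)
null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .phylo import Phylogeny
from .traits import SyndromeMap

__all__ = [
    "standardize", "pca", "PCAResult", "upgma",
    "syndrome_distance_matrix", "mantel_test", "dendrogram_lambda_signal",
    "euclidean_distance_matrix",
]


def standardize(df: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column (mean 0, s.d. 1; population normalisation)."""
    sd = df.std(ddof=0)
    zero = sd.index[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance columns: {list(zero)}")
    return (df - df.mean()) / sd


def euclidean_distance_matrix(df: pd.DataFrame,
                              standardized: bool = True) -> pd.DataFrame:
    """Pairwise Euclidean distances between rows (z-scoring columns first)."""
    if df.isna().any().any():
        raise ValueError("distance matrix input has missing cells")
    X = standardize(df) if standardized else df
    D = squareform(pdist(X.to_numpy()))
    return pd.DataFrame(D, index=df.index, columns=df.index)


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame            # species × axis
    loadings: pd.DataFrame          # variable × axis (eigenvectors)
    correlations: pd.DataFrame      # variable–axis correlations
    variance_explained: pd.Series   # fraction per axis
    eigenvalues: pd.Series


def pca(df: pd.DataFrame, scale: bool = True) -> PCAResult:
    """Principal component analysis of a species × variable matrix.

    ``scale=True`` analyses the correlation matrix (each column z-scored),
    otherwise the covariance matrix.  Axis signs follow a deterministic
    convention: the largest-magnitude loading on each axis is positive.
    """
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    if df.isna().any().any():
        raise ValueError("PCA input has missing cells")
    X = df.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = list(df.columns[sd == 0])
            raise ValueError(f"zero-variance columns with scale=True: {bad}")
        X = X / sd
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / n
    V = Vt.T
    # deterministic sign: largest |loading| per axis positive
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
            U[:, j] = -U[:, j]
    scores = U * s
    axes = [f"PC{j + 1}" for j in range(V.shape[1])]
    scores_df = pd.DataFrame(scores, index=df.index, columns=axes)
    loadings_df = pd.DataFrame(V, index=df.columns, columns=axes)
    with np.errstate(invalid="ignore"):
        corr = np.array([
            [np.corrcoef(df[c], scores[:, j])[0, 1] for j in range(len(axes))]
            for c in df.columns
        ])
    ve = eig / eig.sum()
    return PCAResult(
        scores=scores_df,
        loadings=loadings_df,
        correlations=pd.DataFrame(corr, index=df.columns, columns=axes),
        variance_explained=pd.Series(ve, index=axes),
        eigenvalues=pd.Series(eig, index=axes),
    )


# ----------------------------------------------------------------------
# UPGMA
# ----------------------------------------------------------------------
def _check_distance(D: pd.DataFrame) -> np.ndarray:
    A = D.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(A < 0):
        raise ValueError("distances must be nonnegative")
    if not np.allclose(np.diag(A), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal must be zero")
    return A


def upgma(D: pd.DataFrame) -> Phylogeny:
    """Average-linkage (UPGMA) dendrogram as an ultrametric Phylogeny.

    Node heights are half the merge distances, so tip-to-tip path length in
    the dendrogram equals the cluster distance at which they join.  Ties
    merge in leftmost-pair order (deterministic).
    """
    A = _check_distance(D)
    labels = list(D.index)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 items")
    Z = linkage(squareform(A, checks=False), method="average")
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    height = np.zeros(n_nodes)  # distance from the node up to the tips
    for j in range(n - 1):
        a, b, dist, _ = Z[j]
        v = n + j
        parent[int(a)] = v
        parent[int(b)] = v
        height[v] = dist / 2.0
    root_h = height[-1]
    depth = root_h - height  # tips at depth root_h
    edge = np.zeros(n_nodes)
    for v in range(n_nodes - 1):
        edge[v] = max(depth[v] - depth[parent[v]], 0.0)
    return Phylogeny(parent, edge, labels)


# ----------------------------------------------------------------------
# syndrome distance + Mantel
# ----------------------------------------------------------------------
def syndrome_distance_matrix(syndromes: SyndromeMap) -> pd.DataFrame:
    """0 within a syndrome, 0.5 between bee or butterfly and the mixed
    bee-and-butterfly class, 1 between any other pair of syndromes."""
    sp = syndromes.species
    labels = [syndromes[s] for s in sp]
    half = {frozenset({"bee", "bee_and_butterfly"}),
            frozenset({"butterfly", "bee_and_butterfly"})}
    n = len(sp)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j]:
                d = 0.0
            elif frozenset({labels[i], labels[j]}) in half:
                d = 0.5
            else:
                d = 1.0
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=sp, columns=sp)


def mantel_test(D1: pd.DataFrame, D2: pd.DataFrame, n_perm: int = 9999,
                seed: int = 0) -> tuple[float, float]:
    """One-sided (positive association) Mantel test.

    r is the Pearson correlation of the lower-triangle entries; the p-value
    is (1 + #{permuted r ≥ observed}) / (1 + n_perm), permuting the
    rows/columns of the second matrix jointly.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if list(D1.index) != list(D1.columns) or list(D2.index) != list(D2.columns):
        raise ValueError("distance matrices must have matching row/column labels")
    if set(D1.index) != set(D2.index):
        raise ValueError("label sets differ between the two matrices")
    D2 = D2.loc[D1.index, D1.index]
    A = _check_distance(D1)
    B = _check_distance(D2)
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    a = A[iu]
    a = (a - a.mean())
    sa = np.sqrt((a**2).sum())
    if sa == 0:
        raise ValueError("first distance matrix is constant")

    def corr_with(Bm):
        b = Bm[iu]
        b = b - b.mean()
        sb = np.sqrt((b**2).sum())
        if sb == 0:
            return 0.0
        return float((a * b).sum() / (sa * sb))

    r_obs = corr_with(B)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(B[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return r_obs, p


# ----------------------------------------------------------------------
# λ signal of the discrete syndrome on the dendrogram
# ----------------------------------------------------------------------
def dendrogram_lambda_signal(dendrogram: Phylogeny, syndromes: SyndromeMap,
                             ) -> tuple[float, float, float]:
    """ML Pagel-λ signal of pollination syndrome on a nectar dendrogram.

    The syndrome is dummy-coded into membership indicators and a single λ,
    shared across indicators, scales the dendrogram's off-diagonal (shared
    path) covariance; per-indicator means and variances are profiled by GLS
    and λ is maximized over [0, 1].  λ = 0 is exactly the star-phylogeny
    (white noise) model, so the likelihood-ratio test against it uses a
    1-d.f. χ² reference.  (A discrete Mk likelihood with a free transition
    rate cannot identify λ here: as the rate grows, any tree fits
    independent tip states equally well.)  Returns (λ̂, LRT statistic, p).
    """
    from .models import _gls_profile, _lambda_cov, _optimize_scalar

    sub = syndromes.subset(dendrogram.tip_labels)
    states = sub.states_present()
    if len(states) < 2:
        raise ValueError("syndromes are monomorphic on the dendrogram")
    labels = [sub[s] for s in dendrogram.tip_labels]
    C = dendrogram.shared_depth_matrix()
    ones = np.ones((dendrogram.n_tips, 1))
    # one indicator per non-reference state
    Ys = [np.array([1.0 if l == st else 0.0 for l in labels])
          for st in states[1:]]

    def ll(lam: float) -> float:
        V = _lambda_cov(C, lam)
        return float(sum(_gls_profile(y, ones, V)[2] for y in Ys))

    lam_hat, negf = _optimize_scalar(lambda l: -ll(l), 0.0, 1.0,
                                     n_grid=11, window=0.25)
    lrt = max(0.0, 2.0 * (-negf - ll(0.0)))
    p = float(stats.chi2.sf(lrt, df=1))
    return float(lam_hat), lrt, p
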