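"""Population-structure summaries: pairwise F_ST, DAPC, and spatial PCA.

* Pairwise F_ST uses the Weir–Cockerham (1984) variance-components estimator,
  multi-locus ratio of sums, diploid, with per-locus removal of missing
  genotypes.
* DAPC (discriminant analysis of principal components) reduces genotypes to
  leading PCs and applies canonical discriminant analysis; the PC count is
  chosen by stratified cross-validation on the mean successful assignment
  rate (MSAR), with root-mean-squared error (RMSE) of 1 - accuracy reported
  alongside.
* sPCA couples genetic variance to a neighbour network: eigenvectors of the
  lag-covariance form (1/n) X^T ((L + L^T)/2) X; positive eigenvalues mark
  global structure (neighbours alike), negative eigenvalues local structure
  (neighbours unlike).  Significance by row-permutation tests on the extreme
  eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import MISSING, GenotypeMatrix
from .mvstats import canonical_discriminant

__all__ = [
    "pairwise_fst", "wc_fst", "dapc_crossval", "dapc_fit",
    "NeighbourNetwork", "SpcaResult", "spca", "spca_tests",
]


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def wc_fst(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """Weir–Cockerham theta for two diploid samples (ratio of sums).

    ``codes_*`` are (individuals, loci) 0/1/2 matrices with -1 missing;
    loci with fewer than two called genotypes in either sample, or
    monomorphic across both, contribute nothing.
    """
    r = 2.0
    comp = []
    for codes in (codes_a, codes_b):
        called = codes != MISSING
        n_i = called.sum(axis=0).astype(float)            # diploids called
        alt = np.where(called, codes, 0).sum(axis=0)
        het = ((codes == 1) & called).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(n_i > 0, alt / (2 * n_i), np.nan)
            h_i = np.where(n_i > 0, het / n_i, np.nan)
        comp.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comp
    ok = (n1 >= 2) & (n2 >= 2) & np.isfinite(p1) & np.isfinite(p2)
    n1, p1, h1, n2, p2, h2 = (v[ok] for v in (n1, p1, h1, n2, p2, h2))
    nbar = (n1 + n2) / r
    poly = (p1 != p2) | ((p1 > 0) & (p1 < 1))
    n1, p1, h1, n2, p2, h2, nbar = (v[poly] for v in
                                    (n1, p1, h1, n2, p2, h2, nbar))
    if nbar.size == 0:
        raise ValueError("no co-typed polymorphic loci for this pair")
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                             - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    denom = (a + b + c).sum()
    if denom == 0:
        return 0.0
    return float(a.sum() / denom)


def pairwise_fst(matrix: GenotypeMatrix, site_labels=None) -> pd.DataFrame:
    """Site-by-site Weir–Cockerham F_ST matrix (diagonal 0 by convention)."""
    labels = matrix.site_labels() if site_labels is None else \
        np.asarray(site_labels)
    sites = sorted(set(labels.tolist()))
    if len(sites) < 2:
        raise ValueError("need at least two sites")
    out = pd.DataFrame(0.0, index=sites, columns=sites)
    for i, si in enumerate(sites):
        for sj in sites[i + 1:]:
            f = wc_fst(matrix.codes[labels == si], matrix.codes[labels == sj])
            out.loc[si, sj] = out.loc[sj, si] = f
    return out


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------

def _impute_center(codes: np.ndarray):
    G = codes.astype(float)
    G[G == MISSING] = np.nan
    mean = np.nanmean(G, axis=0)
    inds = np.where(np.isnan(G))
    G[inds] = np.take(mean, inds[1])
    return G - mean


def dapc_crossval(matrix: GenotypeMatrix, groups, pc_grid, *,
                  n_train_sets: int = 100, holdout: float = 0.1,
                  seed: int = 0) -> pd.DataFrame:
    """Choose the PC count by stratified cross-validated assignment.

    For each candidate PC count: ``n_train_sets`` stratified random
    (1-holdout)/holdout splits; PCA on the training individuals; a linear
    discriminant classifier on the training PC scores; MSAR = mean holdout
    accuracy, RMSE = root mean squared (1 - accuracy).  Returns the table
    with an ``chosen`` flag on the MSAR-maximizing count (ties -> fewer PCs).
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    groups = np.asarray(groups)
    X = _impute_center(matrix.codes)
    n = len(groups)
    rng = np.random.default_rng(seed)
    levels, ginx = np.unique(groups, return_inverse=True)
    if min(np.bincount(ginx)) < 2:
        raise ValueError("every group needs at least two individuals")
    rows = []
    for npc in pc_grid:
        accs = []
        skipped = False
        for t in range(n_train_sets):
            test_idx = []
            for g in range(len(levels)):
                members = np.flatnonzero(ginx == g)
                k = max(1, int(round(holdout * len(members))))
                test_idx.extend(rng.choice(members, size=k, replace=False))
            test_idx = np.array(sorted(test_idx))
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            if npc >= len(train_idx):
                skipped = True
                break
            Xtr = X[train_idx]
            mu = Xtr.mean(axis=0)
            U, s, Vt = np.linalg.svd(Xtr - mu, full_matrices=False)
            comps = Vt[:npc]
            Str = (Xtr - mu) @ comps.T
            Ste = (X[test_idx] - mu) @ comps.T
            lda = LinearDiscriminantAnalysis()
            lda.fit(Str, ginx[train_idx])
            accs.append(float((lda.predict(Ste) == ginx[test_idx]).mean()))
        if skipped:
            import warnings
            warnings.warn(f"{npc} PCs >= training individuals; skipped")
            continue
        accs = np.array(accs)
        rows.append((npc, 100.0 * accs.mean(),
                     float(np.sqrt(((1.0 - accs) ** 2).mean()))))
    tab = pd.DataFrame(rows, columns=["n_pcs", "MSAR", "RMSE"])
    if tab.empty:
        raise ValueError("no usable PC count in pc_grid")
    best = tab.sort_values(["MSAR", "n_pcs"],
                           ascending=[False, True]).iloc[0]["n_pcs"]
    tab["chosen"] = tab["n_pcs"] == best
    return tab


def dapc_fit(matrix: GenotypeMatrix, groups, n_pcs: int):
    """PCA then canonical discriminant analysis on the PC scores.

    Returns (scores DataFrame with group column, per-DF variance %, group
    centroid DataFrame)."""
    groups = np.asarray(groups)
    X = _impute_center(matrix.codes)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    pcs = U[:, :n_pcs] * s[:n_pcs]
    res = canonical_discriminant(pcs, groups)
    ndf = res.scores.shape[1]
    sc = pd.DataFrame(res.scores, columns=[f"DF{i+1}" for i in range(ndf)])
    sc.insert(0, "group", groups)
    cent = sc.groupby("group").mean()
    return sc, res.variance_pct, cent


# ---------------------------------------------------------------------------
# sPCA
# ---------------------------------------------------------------------------

@dataclass
class NeighbourNetwork:
    """Binary neighbour graph over individuals with row-normalized weights."""

    adjacency: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.adjacency, float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(A).any():
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = A

    @property
    def n(self):
        return self.adjacency.shape[0]

    @property
    def weights(self):
        """Row-normalized weight matrix L (isolated rows stay zero)."""
        rs = self.adjacency.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            L = np.where(rs > 0, self.adjacency / rs, 0.0)
        return L

    @classmethod
    def within_locality(cls, localities):
        """Neighbours = all pairs from the same locality (any habitat)."""
        loc = np.asarray(localities)
        A = (loc[:, None] == loc[None, :]).astype(float)
        np.fill_diagonal(A, 0.0)
        return cls(A)


@dataclass
class SpcaResult:
    eigenvalues: np.ndarray     # signed, descending
    axes: np.ndarray            # loadings, columns match eigenvalues
    lag_scores: np.ndarray      # L X projected on axes
    global_stat: float          # max positive eigenvalue (0 if none)
    local_stat: float           # |min negative eigenvalue| (0 if none)


def spca(X: np.ndarray, network: NeighbourNetwork) -> SpcaResult:
    """Spatially explicit PCA of centered scores X against a network.

    Eigen-decomposition of C = (1/n) X^T ((L + L^T)/2) X: positive
    eigenvalues capture positive spatial autocorrelation (global structure),
    negative ones negative autocorrelation (local structure).
    """
    X = np.asarray(X, float)
    if network.n != X.shape[0]:
        raise ValueError("network nodes must equal score rows")
    if network.adjacency.sum() == 0:
        raise ValueError("empty neighbour network")
    Xc = X - X.mean(axis=0)
    L = network.weights
    W = 0.5 * (L + L.T)
    C = Xc.T @ W @ Xc / X.shape[0]
    C = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    lag = (W @ Xc) @ V
    pos = w[w > 0]
    neg = w[w < 0]
    return SpcaResult(w, V, lag,
                      float(pos.max()) if pos.size else 0.0,
                      float(-neg.min()) if neg.size else 0.0)


def spca_tests(X: np.ndarray, network: NeighbourNetwork, *,
               n_rand: int = 9999, seed: int = 0):
    """Permutation tests of global/local structure.

    Individual rows of X are permuted against the fixed network; the test
    statistics are the largest positive and |most negative| eigenvalues;
    p = (1 + #{perm >= obs}) / (n_rand + 1).  Returns a dict with observed
    statistics and p-values.
    """
    if n_rand < 99:
        raise ValueError("n_rand must be >= 99")
    obs = spca(X, network)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    ge_g = 0
    ge_l = 0
    for _ in range(n_rand):
        perm = rng.permutation(n)
        r = spca(X[perm], network)
        if r.global_stat >= obs.global_stat:
            ge_g += 1
        if r.local_stat >= obs.local_stat:
            ge_l += 1
    return {
        "global_stat": obs.global_stat,
        "global_p": (1 + ge_g) / (n_rand + 1),
        "local_stat": obs.local_stat,
        "local_p": (1 + ge_l) / (n_rand + 1),
        "n_randomizations": n_rand,
    }
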