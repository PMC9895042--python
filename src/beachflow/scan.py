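"""Selection outlier scan and environmental-association Bayes factors.

Two-step screen for habitat-driven divergent selection:

1. a PCA-regression outlier scan — genotypes are regressed on the leading K
   principal components of individual structure; each SNP's vector of
   regression z-scores yields a Mahalanobis D² that, after genomic-inflation
   rescaling, follows chi-square(K) under neutrality.  Outliers are SNPs with
   MAF > 5% and Bonferroni-adjusted p < 0.1.
2. environmental association — per-site standardized allele frequencies are
   modelled as multivariate normal with covariance Ω (the drift structure of
   the sites, estimated by a moment estimator on a thinned SNP set); the
   Bayes factor compares a linear habitat effect against the null by uniform
   -prior quadrature over the effect size.  Run-to-run stochasticity of the
   reference MCMC tool is recreated by bootstrap-resampling the SNP set used
   to estimate Ω across replicate runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import MISSING, GenotypeMatrix

__all__ = [
    "OutlierScanResult", "pcadapt_scan", "bonferroni_outliers",
    "pop_covariance", "bayes_factor_env", "replicate_consistency",
    "site_allele_frequencies",
]


@dataclass
class OutlierScanResult:
    table: pd.DataFrame   # snp_id, z_1..z_K, d2, p, p_adj, maf, outlier
    K: int
    inflation: float      # genomic inflation factor lambda

    @property
    def outliers(self):
        return self.table.loc[self.table["outlier"], "snp_id"].tolist()


def _impute_scale(matrix: GenotypeMatrix):
    """Mean-imputed genotypes scaled by sqrt(p(1-p)); constant SNPs flagged."""
    G = matrix.codes.astype(float)
    G[G == MISSING] = np.nan
    p = np.nanmean(G, axis=0) / 2.0
    col_mean = 2.0 * p
    inds = np.where(np.isnan(G))
    G[inds] = np.take(col_mean, inds[1])
    sd = np.sqrt(p * (1 - p))
    ok = sd > 0
    Gs = np.zeros_like(G)
    Gs[:, ok] = (G[:, ok] - col_mean[ok]) / sd[ok]
    maf = np.minimum(p, 1 - p)
    return Gs, maf, ok


def pcadapt_scan(matrix: GenotypeMatrix, K: int = 4, alpha: float = 0.1,
                 maf_min: float = 0.05) -> OutlierScanResult:
    """PCA-regression Mahalanobis outlier scan over all SNPs.

    Genotypes are centered, scaled by sqrt(p(1-p)) with mean imputation of
    missing calls; individuals' leading K principal components are the
    regressors; per-SNP z-scores feed a Mahalanobis D² against the
    (uncentered) empirical z second moment, rescaled by a median-based
    genomic inflation factor.  Because the K z-components of a SNP share
    one residual variance estimate with n - K - 1 degrees of freedom, the
    exact null reference is Hotelling-type: D²/K ~ F(K, n-K-1); the large-n
    chi-square(K) limit is anti-conservative in the far tail at GBS-scale
    sample sizes, so the F reference is used throughout.
    """
    if not (1 <= K < matrix.n_individuals):
        raise ValueError("need 1 <= K < number of individuals")
    Gs, maf, ok = _impute_scale(matrix)
    n = matrix.n_individuals
    # individual-space PCA of the scaled genotype matrix
    U, s, Vt = np.linalg.svd(Gs - Gs.mean(axis=0), full_matrices=False)
    scores = U[:, :K]                      # orthonormal component scores
    # per-SNP multiple regression on orthonormal scores: beta = scores^T g
    B = scores.T @ Gs                      # (K, m)
    resid_ss = (Gs ** 2).sum(axis=0) - (B ** 2).sum(axis=0)
    dof = max(n - K - 1, 1)
    sigma = np.sqrt(np.maximum(resid_ss, 0.0) / dof)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sigma > 0, B / sigma, 0.0).T   # (m, K)
    valid = ok & (sigma > 0)
    if valid.sum() <= K:
        raise ValueError("too few usable SNPs for the scan")
    # uncentered second moment: E[z] = 0 under the null, and the statistic
    # stays invariant to reference/alternate allele flips (z -> -z per SNP)
    Zv = Z[valid]
    cov = Zv.T @ Zv / len(Zv) + 1e-12 * np.eye(K)
    d2 = np.einsum("ij,jk,ik->i", Z, np.linalg.inv(cov), Z)
    nu = dof
    f_median = stats.f.ppf(0.5, K, nu)
    lam = float(np.median(d2[valid]) / (K * f_median))
    lam = max(lam, 1e-12)
    p = stats.f.sf(d2 / (lam * K), K, nu)
    p[~valid] = 1.0
    m_tested = int(valid.sum())
    p_adj = np.minimum(1.0, p * m_tested)
    flag = bonferroni_outliers(p, maf, m_tested, alpha=alpha, maf_min=maf_min)
    cols = {"snp_id": matrix.snp_ids}
    for k in range(K):
        cols[f"z{k + 1}"] = Z[:, k]
    cols.update(d2=d2, p=p, p_adj=p_adj, maf=maf, outlier=flag)
    return OutlierScanResult(pd.DataFrame(cols), K, lam)


def bonferroni_outliers(pvalues, maf, m: int, alpha: float = 0.1,
                        maf_min: float = 0.05) -> np.ndarray:
    """Outlier flags: Bonferroni-adjusted p < alpha and MAF > maf_min."""
    pvalues = np.asarray(pvalues, float)
    maf = np.asarray(maf, float)
    if m < (pvalues < 1.0).sum():
        raise ValueError("m must cover every tested SNP")
    p_adj = np.minimum(1.0, pvalues * m)
    return (p_adj < alpha) & (maf > maf_min)


def site_allele_frequencies(matrix: GenotypeMatrix, site_labels=None):
    """(sites, freq matrix (g, m), called-copy counts) per site per SNP."""
    labels = matrix.site_labels() if site_labels is None else \
        np.asarray(site_labels)
    sites = sorted(set(labels.tolist()))
    m = matrix.n_snps
    freq = np.full((len(sites), m), np.nan)
    counts = np.zeros((len(sites), m))
    for gi, site in enumerate(sites):
        sub = matrix.codes[labels == site]
        called = sub != MISSING
        tot = 2 * called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[gi] = np.where(tot > 0, alt / tot, np.nan)
        counts[gi] = tot
    return sites, freq, counts


def pop_covariance(matrix: GenotypeMatrix, site_labels=None,
                   ridge: float = 1e-6):
    """Moment estimator of the between-site drift covariance Ω.

    Per SNP the site allele-frequency vector is standardized as
    (p_g - p̄)/sqrt(p̄(1-p̄)) with p̄ the across-site mean; Ω is the average
    outer product over SNPs, symmetrized and ridge-regularized.
    Returns (site list, Ω).
    """
    sites, freq, counts = site_allele_frequencies(matrix, site_labels)
    if len(sites) < 2:
        raise ValueError("need at least two sites")
    if np.isnan(freq).any():
        dead = [sites[i] for i in range(len(sites))
                if np.isnan(freq[i]).any()]
        raise ValueError(f"sites with uncalled SNPs: {dead}")
    pbar = freq.mean(axis=0)
    use = (pbar > 0) & (pbar < 1)
    if use.sum() == 0:
        raise ValueError("no polymorphic SNPs for covariance estimation")
    X = (freq[:, use] - pbar[use]) / np.sqrt(pbar[use] * (1 - pbar[use]))
    omega = (X @ X.T) / use.sum()
    omega = 0.5 * (omega + omega.T) + ridge * np.eye(len(sites))
    return sites, omega


def bayes_factor_env(x, e, omega, prior_halfwidth: float = 10.0,
                     grid_points: int = 2001) -> float:
    """Bayes factor for a linear environment effect on standardized site
    frequencies.

    Model: x ~ MVN(beta * e*, Ω) with e* the centered binary environment
    vector; BF = [∫ L(beta) dU(beta; ±halfwidth)] / L(0), by trapezoid
    quadrature.  BF <= 1 (up to quadrature tolerance) when x is Ω-orthogonal
    to e*.
    """
    x = np.asarray(x, float)
    e = np.asarray(e, float)
    estar = e - e.mean()
    omega = np.asarray(omega, float)
    try:
        L = np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as err:
        raise ValueError("population covariance is singular even after the "
                         "ridge; inspect near-duplicate sites") from err
    from scipy.linalg import solve_triangular
    betas = np.linspace(-prior_halfwidth, prior_halfwidth, grid_points)
    # the log-likelihood is quadratic in beta; only the beta-dependent part
    # survives the ratio:  -2 log L(beta) = const - 2 b beta + a beta^2
    wx = solve_triangular(L, x, lower=True)
    we = solve_triangular(L, estar, lower=True)
    a = we @ we
    b = wx @ we
    q = a * betas ** 2 - 2.0 * b * betas
    shift = q.min()
    rel = np.exp(-0.5 * (q - shift))
    num = np.trapezoid(rel, betas) / (2.0 * prior_halfwidth)
    den = np.exp(-0.5 * (0.0 - shift))
    return float(num / den)


def replicate_consistency(matrix: GenotypeMatrix, e, snp_ids, *,
                          thinned: GenotypeMatrix, n_runs: int = 10,
                          bf_threshold: float = 10.0, seed: int = 0,
                          resample: bool = True):
    """Count, per candidate SNP, the replicate runs with BF >= threshold.

    Each run re-estimates Ω from a bootstrap resample of the thinned SNP set
    (the source of run-to-run stochasticity), then recomputes the Bayes
    factors of the candidate SNPs.  Returns a DataFrame
    (snp_id, n_significant, n_runs) plus the per-run BF matrix.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    sites_all, freq, _ = site_allele_frequencies(matrix)
    lab_site = pd.DataFrame({
        "site": sites_all,
        "e": [e[s] if isinstance(e, dict) else e[i]
              for i, s in enumerate(sites_all)]})
    evec = lab_site["e"].to_numpy(float)
    col_of = {s: j for j, s in enumerate(matrix.snp_ids)}
    rng = np.random.default_rng(seed)
    bf_runs = np.zeros((len(snp_ids), n_runs))
    for r in range(n_runs):
        if resample:
            cols = rng.integers(0, thinned.n_snps, thinned.n_snps)
            sub = GenotypeMatrix(thinned.codes[:, cols], thinned.samples,
                                 [f"bs{j}" for j in range(len(cols))])
        else:
            sub = thinned
        sites, omega = pop_covariance(sub)
        if sites != sites_all:
            raise ValueError("thinned matrix sites differ from scan matrix")
        for i, sid in enumerate(snp_ids):
            f = freq[:, col_of[sid]]
            pbar = f.mean()
            if not (0 < pbar < 1):
                bf_runs[i, r] = 0.0
                continue
            x = (f - pbar) / np.sqrt(pbar * (1 - pbar))
            bf_runs[i, r] = bayes_factor_env(x, evec, omega)
    counts = (bf_runs >= bf_threshold).sum(axis=1)
    out = pd.DataFrame({"snp_id": list(snp_ids),
                        "n_significant": counts,
                        "n_runs": n_runs})
    return out, bf_runs
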