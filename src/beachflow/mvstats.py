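"""Phenotype inference: two-way MANOVA (Pillai), two-way ANOVA, canonical DFA.

Habitat/locality effects on multivariate phenotypes (log-luminances, shape
PCs) are tested with a cross-classified linear model including the
interaction, Type III (partial) hypothesis tests under sum-to-zero contrasts,
and Pillai's trace V = tr(H (H + E)^-1) — the robust choice when residual
normality or covariance homogeneity is doubtful.  Effect sizes are partial
η² = V / s with s = min(hypothesis df, number of responses); for univariate
ANOVA, partial η² = F·df_h / (F·df_h + df_e).

Canonical discriminant functions (eigenvectors of W^{-1} B) serve both the
phenotype DFA and the genomic DAPC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

__all__ = [
    "ManovaResult", "DfaResult", "two_way_manova_pillai", "two_way_anova",
    "dfa", "canonical_discriminant", "partial_eta_sq_from_pillai",
    "partial_eta_sq_from_f", "confidence_ellipse",
]


def partial_eta_sq_from_pillai(V: float, s: int) -> float:
    """Partial η² from Pillai's trace: V / s, s = min(df_h, responses)."""
    if s < 1:
        raise ValueError("s must be >= 1")
    return V / s


def partial_eta_sq_from_f(F: float, df_h: int, df_e: int) -> float:
    """Univariate partial η² from an F statistic: F·df_h / (F·df_h + df_e)."""
    return (F * df_h) / (F * df_h + df_e)


# ---------------------------------------------------------------------------
# MANOVA / ANOVA
# ---------------------------------------------------------------------------

@dataclass
class ManovaResult:
    terms: pd.DataFrame  # term, pillai, F, df1, df2, p, s, partial_eta2

    def term(self, name):
        row = self.terms.loc[self.terms["term"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]


def _design_frame(Y, factor_a, factor_b, names=("A", "B")):
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    df = pd.DataFrame(Y, columns=[f"y{i}" for i in range(Y.shape[1])])
    df[names[0]] = pd.Categorical(np.asarray(factor_a))
    df[names[1]] = pd.Categorical(np.asarray(factor_b))
    for n in names:
        if df[n].nunique() < 2:
            raise ValueError(f"factor {n} needs >= 2 levels")
    cells = df.groupby([names[0], names[1]], observed=False).size()
    if (cells == 0).any():
        raise ValueError("empty factor cells are not supported")
    return df, Y.shape[1]


def two_way_manova_pillai(Y, factor_a, factor_b,
                          names=("A", "B")) -> ManovaResult:
    """Two-way MANOVA with interaction; Pillai's trace per term.

    Type III hypothesis matrices via sum-to-zero contrasts; Rao's F
    approximation and partial η² = V/s are reported for the two main effects
    and the interaction.  Raises if the error matrix is singular (reduce the
    responses, e.g. to leading PCs, before testing).
    """
    from statsmodels.multivariate.manova import MANOVA

    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    sd = Y.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant response column; drop it before testing")
    if Y.shape[1] == 1:
        # univariate reduction: V = SS_h/(SS_h + SS_e) = partial eta^2, s = 1
        an = two_way_anova(Y[:, 0], factor_a, factor_b, names)
        rows = [(r.term, partial_eta_sq_from_f(r.F, r.df1, r.df2), r.F,
                 r.df1, r.df2, r.p, 1,
                 partial_eta_sq_from_f(r.F, r.df1, r.df2))
                for r in an.itertuples()]
        return ManovaResult(pd.DataFrame(
            rows, columns=["term", "pillai", "F", "df1", "df2", "p", "s",
                           "partial_eta2"]))

    # Pillai's trace is invariant to per-response scaling; standardizing
    # keeps the numerics well away from absolute eigenvalue tolerances
    df, p_resp = _design_frame(Y / sd, factor_a, factor_b, names)
    ycols = " + ".join(c for c in df.columns if c.startswith("y"))
    a, b = names
    formula = (f"{ycols} ~ C({a}, Sum) * C({b}, Sum)")
    try:
        mv = MANOVA.from_formula(formula, data=df)
        # centered responses (e.g. PCA scores) have a null intercept term
        # whose test would fail; it is not of interest anyway
        res = mv.mv_test(skip_intercept_test=True)
    except Exception as err:
        raise ValueError(
            "MANOVA failed (singular error matrix?); consider reducing the "
            "responses to leading principal components") from err
    term_map = {
        a: f"C({a}, Sum)",
        b: f"C({b}, Sum)",
        f"{a}:{b}": f"C({a}, Sum):C({b}, Sum)",
    }
    la = df[a].nunique() - 1
    lb = df[b].nunique() - 1
    df_h = {a: la, b: lb, f"{a}:{b}": la * lb}
    rows = []
    for term, key in term_map.items():
        tab = res.results[key]["stat"]
        pil = tab.loc["Pillai's trace"]
        s = min(df_h[term], p_resp)
        V = float(pil["Value"])
        rows.append((term, V, float(pil["F Value"]),
                     float(pil["Num DF"]), float(pil["Den DF"]),
                     float(pil["Pr > F"]), s,
                     partial_eta_sq_from_pillai(V, s)))
    return ManovaResult(pd.DataFrame(
        rows, columns=["term", "pillai", "F", "df1", "df2", "p", "s",
                       "partial_eta2"]))


def two_way_anova(y, factor_a, factor_b, names=("A", "B")) -> pd.DataFrame:
    """Two-way ANOVA with interaction (Type III); partial η² per term."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df, _ = _design_frame(np.asarray(y, float).ravel(), factor_a, factor_b,
                          names)
    a, b = names
    model = smf.ols(f"y0 ~ C({a}, Sum) * C({b}, Sum)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=3)
    ss_err = tab.loc["Residual", "sum_sq"]
    df_err = tab.loc["Residual", "df"]
    rows = []
    for term, key in ((a, f"C({a}, Sum)"), (b, f"C({b}, Sum)"),
                      (f"{a}:{b}", f"C({a}, Sum):C({b}, Sum)")):
        r = tab.loc[key]
        F, dfh = float(r["F"]), float(r["df"])
        rows.append((term, F, dfh, float(df_err), float(r["PR(>F)"]),
                     partial_eta_sq_from_f(F, dfh, df_err)))
    return pd.DataFrame(rows, columns=["term", "F", "df1", "df2", "p",
                                       "partial_eta2"])


# ---------------------------------------------------------------------------
# canonical discriminant analysis
# ---------------------------------------------------------------------------

@dataclass
class CanonicalResult:
    eigenvalues: np.ndarray
    coef: np.ndarray          # columns are discriminant directions
    scores: np.ndarray        # centered specimen scores
    variance_pct: np.ndarray  # eigenvalue shares, sums to 100


def canonical_discriminant(Y, groups, ridge: float = 0.0) -> CanonicalResult:
    """Solve the canonical discriminant eigenproblem W^{-1} B.

    W is the pooled within-group scatter, B the between-group scatter; the
    number of discriminant functions is min(groups - 1, responses).  A ridge
    is added to W automatically (with a warning) when it is singular.
    """
    Y = np.asarray(Y, float)
    groups = np.asarray(groups)
    levels, ginx = np.unique(groups, return_inverse=True)
    g = len(levels)
    if g < 2:
        raise ValueError("need >= 2 groups")
    counts = np.bincount(ginx)
    if counts.min() < 2:
        raise ValueError("every group needs n >= 2")
    grand = Y.mean(axis=0)
    p = Y.shape[1]
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for gi in range(g):
        sub = Y[ginx == gi]
        mu = sub.mean(axis=0)
        d = sub - mu
        W += d.T @ d
        B += len(sub) * np.outer(mu - grand, mu - grand)
    if ridge > 0:
        W = W + ridge * np.eye(p)
    ndf = min(g - 1, p)
    try:
        w, V = sla.eigh(B, W)
    except (np.linalg.LinAlgError, sla.LinAlgError):
        lam = 1e-8 * np.trace(W) / p if np.trace(W) > 0 else 1e-8
        warnings.warn("singular within-group scatter; ridge added")
        w, V = sla.eigh(B, W + lam * np.eye(p))
    order = np.argsort(w)[::-1][:ndf]
    w = np.maximum(w[order], 0.0)
    V = V[:, order]
    scores = (Y - grand) @ V
    total = w.sum()
    pct = 100.0 * w / total if total > 0 else np.full(ndf, 100.0 / ndf)
    return CanonicalResult(w, V, scores, pct)


@dataclass
class DfaResult:
    coef: np.ndarray
    scores: pd.DataFrame       # group + DF columns
    variance_pct: np.ndarray
    group_means: pd.DataFrame
    ellipses: dict             # group -> (center, semi_axes, angle_rad)


def confidence_ellipse(points: np.ndarray, level: float = 0.95):
    """(center, semi-axes, angle) of the normal-theory confidence ellipse of
    2-D points, from the score covariance and the chi-square(2) quantile."""
    pts = np.asarray(points, float)[:, :2]
    center = pts.mean(axis=0)
    cov = np.cov(pts.T)
    q = stats.chi2.ppf(level, df=2)
    w, V = np.linalg.eigh(np.atleast_2d(cov))
    semi = np.sqrt(np.maximum(w, 0.0) * q)[::-1]
    angle = float(np.arctan2(V[1, -1], V[0, -1]))
    return center, semi, angle


def dfa(Y, groups, level: float = 0.95) -> DfaResult:
    """Canonical DFA with per-function variance % and confidence ellipses."""
    groups = np.asarray(groups)
    res = canonical_discriminant(np.asarray(Y, float), groups)
    ndf = res.scores.shape[1]
    sc = pd.DataFrame(res.scores, columns=[f"DF{i+1}" for i in range(ndf)])
    sc.insert(0, "group", groups)
    means = sc.groupby("group").mean()
    ellipses = {}
    if ndf >= 2:
        for gname, sub in sc.groupby("group"):
            ellipses[gname] = confidence_ellipse(
                sub[["DF1", "DF2"]].to_numpy(), level)
    return DfaResult(res.coef, sc, res.variance_pct, means, ellipses)
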