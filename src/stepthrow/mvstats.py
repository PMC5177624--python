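"""Multivariate and repeated-measures statistics.

The 2-D outcome variables of the stepping analysis (foot placement, CoM
velocity at foot lift) are compared with one-sample Hotelling's T-squared
tests on within-subject differences — the multivariate analogue of a paired
t-test.  For n subjects and p = 2 dimensions,

    T^2 = n (xbar - mu0)' S^{-1} (xbar - mu0),
    F   = (n - p) / (p (n - 1)) * T^2  ~  F(p, n - p) under H0,

with S the sample covariance.  Group means are displayed with Hotelling
confidence ellipses, normality is screened with Mardia's multivariate
skewness and kurtosis statistics (classical asymptotic forms, no
small-sample correction), univariate temporal variables go through a
one-way repeated-measures ANOVA with the Greenhouse-Geisser sphericity
correction, and families of comparisons are Bonferroni-controlled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import solve_triangular

__all__ = [
    "GroupStat", "MardiaResult", "RmAnovaResult",
    "pair_within_subject", "hotelling_one_sample", "mean_confidence_ellipse",
    "mardia_tests", "bonferroni", "rm_anova_one_way",
]


@dataclass
class GroupStat:
    """One-sample Hotelling test result with the group-mean ellipse."""

    t2: float
    f_value: float
    df: tuple[int, int]
    p_value: float
    mean: np.ndarray
    n: int
    cov: np.ndarray

    def confidence_ellipse(self, level: float = 0.95):
        """(center, shape, boundary) of the Hotelling group-mean ellipse at
        ``level``: {mu : n (xbar-mu)' S^-1 (xbar-mu) <= p(n-1)/(n-p) F_level}."""
        p, n = len(self.mean), self.n
        c = p * (n - 1) / (n - p) * stats.f.ppf(level, p, n - p)
        return self.mean, self.cov, float(c)


@dataclass
class MardiaResult:
    b1p: float          # multivariate skewness
    b2p: float          # multivariate kurtosis
    skew_stat: float    # n b1p / 6 ~ chi2(p(p+1)(p+2)/6)
    skew_df: int
    skew_p: float
    kurt_stat: float    # (b2p - p(p+2)) / sqrt(8p(p+2)/n) ~ N(0, 1)
    kurt_p: float


@dataclass
class RmAnovaResult:
    f_value: float
    df: tuple[float, float]
    p_value: float
    epsilon: float               # Greenhouse-Geisser
    df_corrected: tuple[float, float]
    p_corrected: float


def pair_within_subject(values: dict, reference: str) -> dict:
    """Subtract each subject's reference-condition mean from every condition.

    ``values`` maps condition -> (n_subjects, p) array of per-subject means,
    all in the same subject order.  Returns the same mapping of differences
    (the reference condition maps to zeros).  Adding any constant to both
    conditions of a subject leaves the differences unchanged.
    """
    if reference not in values:
        raise KeyError(f"reference condition {reference!r} missing")
    ref = np.asarray(values[reference], dtype=float)
    out = {}
    for cond, v in values.items():
        v = np.asarray(v, dtype=float)
        if v.shape != ref.shape:
            raise ValueError(f"condition {cond!r} shape {v.shape} does not match "
                             f"reference shape {ref.shape}")
        out[cond] = v - ref
    return out


def hotelling_one_sample(x: np.ndarray, mu0=None) -> GroupStat:
    """One-sample Hotelling's T-squared test of E[x] = mu0 (default zero)."""
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need n > p observations (n={n}, p={p})")
    mu0 = np.zeros(p) if mu0 is None else np.asarray(mu0, dtype=float)
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    try:
        d = np.linalg.solve(cov, mean - mu0)
    except np.linalg.LinAlgError:
        raise ValueError("singular sample covariance") from None
    t2 = float(n * (mean - mu0) @ d)
    f_value = (n - p) / (p * (n - 1)) * t2
    p_value = float(stats.f.sf(f_value, p, n - p))
    return GroupStat(t2=t2, f_value=float(f_value), df=(p, n - p),
                     p_value=p_value, mean=mean, n=n, cov=cov)


def mean_confidence_ellipse(x: np.ndarray, level: float = 0.95):
    """Hotelling confidence ellipse of the group mean.

    Returns ``(center, semi_axes, axes, boundary)``: the sample mean, the
    semi-axis lengths sqrt(c * lambda_i / n), the unit axis directions
    (eigenvectors of S, as columns), and the boundary constant c.
    """
    gs = hotelling_one_sample(np.asarray(x, dtype=float))
    center, cov, c = gs.confidence_ellipse(level)
    w, v = np.linalg.eigh(cov)
    return center, np.sqrt(c * w / gs.n), v, c


def mardia_tests(x: np.ndarray) -> MardiaResult:
    """Mardia's multivariate skewness and kurtosis tests.

    Uses the maximum-likelihood covariance (divisor n), under which the
    kurtosis of a multivariate normal converges to p(p + 2).
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need n > p observations (n={n}, p={p})")
    dev = x - x.mean(axis=0)
    s = dev.T @ dev / n
    try:
        chol = np.linalg.cholesky(s)
    except np.linalg.LinAlgError:
        raise ValueError("singular sample covariance") from None
    y = solve_triangular(chol, dev.T, lower=True).T  # whitened data
    # sum_ij (y_i . y_j)^3 = sum_abc (sum_i y_ia y_ib y_ic)^2: avoids the
    # n x n Gram matrix
    third = np.einsum("ia,ib,ic->abc", y, y, y)
    b1p = float((third ** 2).sum() / n ** 2)
    b2p = float(((y ** 2).sum(axis=1) ** 2).mean())
    skew_df = p * (p + 1) * (p + 2) // 6
    skew_stat = n * b1p / 6.0
    kurt_stat = (b2p - p * (p + 2)) / np.sqrt(8.0 * p * (p + 2) / n)
    return MardiaResult(
        b1p=b1p, b2p=b2p,
        skew_stat=float(skew_stat), skew_df=skew_df,
        skew_p=float(stats.chi2.sf(skew_stat, skew_df)),
        kurt_stat=float(kurt_stat),
        kurt_p=float(2 * stats.norm.sf(abs(kurt_stat))),
    )


def bonferroni(p_values, m: int | None = None, alpha: float = 0.05):
    """Bonferroni correction: adjusted p = min(1, m p); reject iff p < alpha/m."""
    p = np.asarray(p_values, dtype=float)
    m = len(p) if m is None else int(m)
    if m < 1:
        raise ValueError("m must be >= 1")
    adjusted = np.minimum(1.0, m * p)
    reject = p < alpha / m
    return adjusted, reject


def rm_anova_one_way(data: np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on an (n_subjects, k_conditions) table.

    Greenhouse-Geisser epsilon is estimated from the double-centered sample
    covariance of the conditions, A = C S C' with C the centering matrix:
    epsilon = tr(A)^2 / ((k-1) tr(A^2)).  For k = 2 conditions epsilon is
    exactly 1 (sphericity is trivial).
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2 or np.isnan(y).any():
        raise ValueError("need a complete (subjects x conditions) table")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 conditions (got {n} x {k})")
    grand = y.mean()
    subj = y.mean(axis=1)
    cond = y.mean(axis=0)
    ss_cond = n * ((cond - grand) ** 2).sum()
    resid = y - subj[:, None] - cond[None, :] + grand
    ss_err = (resid ** 2).sum()
    df1, df2 = k - 1, (k - 1) * (n - 1)
    if ss_err <= 0:
        f_value = np.inf if ss_cond > 0 else 0.0
    else:
        f_value = (ss_cond / df1) / (ss_err / df2)

    s = np.cov(y, rowvar=False, ddof=1)
    c = np.eye(k) - np.ones((k, k)) / k
    a = c @ s @ c
    tra, tra2 = np.trace(a), np.trace(a @ a)
    eps = 1.0 if tra2 <= 0 else float(tra ** 2 / (df1 * tra2))
    eps = float(np.clip(eps, 1.0 / df1, 1.0))

    p_value = float(stats.f.sf(f_value, df1, df2))
    dfc = (eps * df1, eps * df2)
    p_corr = float(stats.f.sf(f_value, *dfc))
    return RmAnovaResult(f_value=float(f_value), df=(df1, df2), p_value=p_value,
                         epsilon=eps, df_corrected=dfc, p_corrected=p_corr)
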