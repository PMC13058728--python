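"""Shared statistical kernels: vectorized one-way ANOVA, BH adjustment,
and limma-style empirical-Bayes variance moderation.

The ANOVA runs simultaneously over all rows of a feature x sample matrix
(one F test per feature), which is what makes proteome-scale null and
power simulations cheap. Missing values (NaN) are handled per feature;
features lacking the required replication are excluded from the tested
family rather than given a p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "oneway_anova_matrix",
    "bh_adjust",
    "moment_squeeze_variances",
]

_TINY_P = np.nextafter(0.0, 1.0)


@dataclass
class AnovaResult:
    """Row-wise one-way ANOVA over a matrix.

    Attributes
    ----------
    f, p : arrays of length n_features (NaN where untested)
    tested : bool mask of features meeting the replication requirement
    degenerate : bool mask of features with zero residual variance but
        unequal group means (p reported as the smallest positive float)
    group_means : n_features x n_groups array of group means
    n_per_group : n_features x n_groups array of non-missing counts
    df_between, df_within : per-feature degrees of freedom
    s2_within : per-feature residual (within-group) variance
    ms_between : per-feature between-group mean square
    """

    f: np.ndarray
    p: np.ndarray
    tested: np.ndarray
    degenerate: np.ndarray
    group_means: np.ndarray
    n_per_group: np.ndarray
    df_between: np.ndarray
    df_within: np.ndarray
    s2_within: np.ndarray
    ms_between: np.ndarray


def oneway_anova_matrix(values: np.ndarray,
                        groups: Sequence[np.ndarray],
                        min_per_group: int = 2) -> AnovaResult:
    """One-way fixed-effects ANOVA applied independently to every row.

    Parameters
    ----------
    values
        n_features x n_samples matrix; NaN marks missing observations.
    groups
        One integer index array per group, partitioning the sample columns.
    min_per_group
        Features with fewer non-missing replicates than this in any group
        are flagged untested (no p-value; excluded from the BH family).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    n_feat = values.shape[0]
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")

    counts = np.empty((n_feat, k))
    means = np.empty((n_feat, k))
    ssw = np.zeros(n_feat)
    for j, idx in enumerate(groups):
        block = values[:, np.asarray(idx, dtype=int)]
        n_j = np.sum(~np.isnan(block), axis=1)
        counts[:, j] = n_j
        with np.errstate(invalid="ignore", divide="ignore"):
            m_j = np.nansum(block, axis=1) / n_j
        m_j = np.where(n_j > 0, m_j, np.nan)
        means[:, j] = m_j
        dev = block - m_j[:, None]
        ssw += np.nansum(dev * dev, axis=1)

    tested = np.all(counts >= min_per_group, axis=1)
    n_tot = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        grand = np.nansum(means * counts, axis=1) / n_tot
    ssb = np.nansum(counts * (means - grand[:, None]) ** 2, axis=1)

    df_b = np.full(n_feat, float(k - 1))
    df_w = n_tot - k
    msb = ssb / df_b
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(df_w > 0, ssw / np.maximum(df_w, 1), np.nan)
        f = msb / s2

    p = np.full(n_feat, np.nan)
    ok = tested & (df_w > 0)
    zero_resid = ok & (ssw <= 0)
    # zero residual variance: equal means -> F = 0, p = 1; unequal -> p ~ 0
    degenerate = zero_resid & (ssb > 0)
    p[degenerate] = _TINY_P
    f[degenerate] = np.inf
    flat = zero_resid & (ssb <= 0)
    p[flat] = 1.0
    f[flat] = 0.0
    regular = ok & ~zero_resid
    p[regular] = sps.f.sf(f[regular], df_b[regular], df_w[regular])
    # all group means identical: guard rounding
    p[regular & (ssb <= 0)] = 1.0

    f[~ok] = np.nan
    p[~tested] = np.nan

    return AnovaResult(f=f, p=p, tested=tested, degenerate=degenerate,
                       group_means=means, n_per_group=counts.astype(int),
                       df_between=df_b, df_within=df_w.astype(float),
                       s2_within=s2, ms_between=msb)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up over the non-NaN entries of ``p``.

    NaN entries (untested features) are not part of the family and stay NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def moment_squeeze_variances(s2: np.ndarray, df: float,
                             prior_df: float | None = None
                             ) -> tuple[np.ndarray, float, float]:
    """Shrink per-feature variances toward a pooled prior (empirical Bayes).

    Models s2_g | sigma_g^2 ~ sigma_g^2 * chi2_df / df with a scaled
    inverse-chi-square prior sigma_g^2 ~ s0^2 * d0 / chi2_d0, so that
    marginally s2_g / s0^2 ~ F(df, d0). The prior parameters (d0, s0^2) are
    fitted by method of moments on the observed variances; the posterior
    variance is the precision-weighted blend (d0*s0^2 + df*s2) / (d0 + df).

    Returns (squeezed variances, d0, s0sq); d0 = inf means the observed
    spread of variances is no larger than chi-square sampling alone would
    produce, i.e. complete pooling.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2)
    vals = s2[ok]
    if vals.size < 2:
        return s2.copy(), np.inf, float(np.nanmean(vals)) if vals.size else np.nan
    m1 = float(np.mean(vals))
    var = float(np.var(vals, ddof=1))
    if m1 <= 0:
        return s2.copy(), np.inf, m1
    if prior_df is not None:
        # fixed prior df (e.g. for convergence checks); prior scale from m1
        d0 = float(prior_df)
        s0sq = m1 * (d0 - 2.0) / d0 if d0 > 2.0 else m1
        if d0 == 0.0:
            return s2.copy(), 0.0, s0sq
        squeezed = np.where(ok, (d0 * s0sq + df * s2) / (d0 + df), s2)
        return squeezed, d0, s0sq
    c = var / (m1 * m1)
    denom = c * df - 2.0
    if denom <= 0:
        d0 = np.inf
        s0sq = m1
    else:
        d0 = (2.0 * df - 4.0 + 4.0 * c * df) / denom
        if d0 <= 4.0:  # moment solution unstable; fall back to a weak prior
            d0 = 4.0 + 1e-6
        s0sq = m1 * (d0 - 2.0) / d0
    if np.isinf(d0):
        squeezed = np.where(ok, s0sq, s2)
    else:
        squeezed = np.where(ok, (d0 * s0sq + df * s2) / (d0 + df), s2)
    return squeezed, d0, s0sq
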