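"""Shared statistical primitives.

Welch's unequal-variance t test (vectorised over many sites), upper-tail
binomial and hypergeometric probabilities, and Benjamini-Hochberg /
Benjamini-Yekutieli multiple-testing adjustments. Distribution functions are
delegated to :mod:`scipy.stats`; the adjustments to
:mod:`statsmodels.stats.multitest`.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "welch_t",
    "binom_tail",
    "hypergeom_tail",
    "bh_adjust",
    "by_adjust",
]

#: smallest p value reported before taking logarithms
P_FLOOR = 1e-300


def welch_t(a, b, axis: int = -1):
    """Welch's two-sample t statistic with Welch-Satterthwaite df.

    Parameters
    ----------
    a, b : array-like
        Sample values for the two groups; the test is computed along `axis`,
        ignoring NaNs. At least two non-NaN values per group are required
        (cells failing this yield NaN t / df and p = NaN).

    Returns
    -------
    t, df, p : ndarray or float
        The statistic (mean(a) - mean(b) over the pooled standard error),
        Welch-Satterthwaite degrees of freedom, and two-sided p value.

    Notes
    -----
    Degenerate sites are resolved deterministically: zero variance in both
    groups with equal means gives t = 0, p = 1; zero variance with unequal
    means gives p = `P_FLOOR` with an infinite statistic of the correct sign.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.sum(~np.isnan(a), axis=axis)
    nb = np.sum(~np.isnan(b), axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = np.nanmean(a, axis=axis)
        mb = np.nanmean(b, axis=axis)
        va = np.nanvar(a, axis=axis, ddof=1)
        vb = np.nanvar(b, axis=axis, ddof=1)
        sa = va / na
        sb = vb / nb
        se2 = sa + sb
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
        p = 2.0 * sps.t.sf(np.abs(t), df)

    t = np.asarray(t, dtype=float)
    df = np.asarray(df, dtype=float)
    p = np.asarray(p, dtype=float)

    diff = np.asarray(ma - mb, dtype=float)
    zerovar = np.asarray(se2 == 0)
    equal = zerovar & (diff == 0)
    unequal = zerovar & (diff != 0)
    t[equal] = 0.0
    p[equal] = 1.0
    t[unequal] = np.sign(diff[unequal]) * np.inf
    p[unequal] = P_FLOOR
    df[zerovar] = np.nan

    bad = np.asarray((na < 2) | (nb < 2))
    t[bad] = np.nan
    df[bad] = np.nan
    p[bad] = np.nan
    if t.ndim == 0:
        return float(t), float(df), float(p)
    return t, df, p


def binom_tail(k, n, p):
    """Upper-tail binomial probability P(X >= k) for X ~ Binomial(n, p).

    ``k = 0`` returns 1 (the upper tail includes the whole support).
    """
    return sps.binom.sf(np.asarray(k) - 1, n, p)


def hypergeom_tail(k, n_population, n_success, n_draw):
    """Upper-tail hypergeometric probability P(X >= k).

    X counts successes among `n_draw` draws without replacement from a
    population of `n_population` containing `n_success` successes.
    """
    return sps.hypergeom.sf(np.asarray(k) - 1, n_population, n_success, n_draw)


def bh_adjust(p):
    """Benjamini-Hochberg FDR-adjusted q values (empty input passes through)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def by_adjust(p):
    """Benjamini-Yekutieli adjusted q values, valid under arbitrary dependence."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_by")[1]
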