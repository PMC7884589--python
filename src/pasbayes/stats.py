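"""Frequentist companions to the Bayes-factor analysis.

One-tailed paired t-tests (direction fixed to post > pre, the direction the
motivating hypotheses predict), Cohen's d with the pre-intervention or sham
standardiser, bias-corrected and accelerated (BCa) bootstrap confidence
intervals resampling participants, two-way mixed consistency ICC, and a thin
Shapiro-Wilk wrapper for normality screening.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps

from .exceptions import InputError, UndefinedStatisticError


def _paired(pre, post):
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.ndim != 1 or pre.shape != post.shape:
        raise InputError("pre and post must be 1-d arrays of equal length")
    if pre.size < 2:
        raise InputError("need at least 2 pairs")
    return pre, post


def paired_t_one_tailed(pre, post):
    """One-tailed paired t-test of the increase post - pre.

    Returns ``(t, df, p)`` with ``t = mean(diff) / (sd(diff)/sqrt(n))``,
    ``df = n - 1`` and p the upper-tail probability (post > pre predicted);
    a negative t therefore yields p > 0.5, never a reflected tail.
    """
    pre, post = _paired(pre, post)
    diff = post - pre
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError("zero variance of paired differences")
    t = float(diff.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(sps.t.sf(t, df))
    return t, df, p


def cohens_d_pre(pre, post):
    """Cohen's d standardised by the pre-intervention SD (n-1 denominator)."""
    pre, post = _paired(pre, post)
    sd = pre.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError("zero variance of pre-intervention values")
    return float((post - pre).mean() / sd)


def between_condition_d(delta_active, delta_sham):
    """Between-condition effect size on baseline-subtracted AURC changes.

    ``d = mean(delta_active - delta_sham) / sd(delta_sham)``: the standardiser
    is the SD of the sham-condition changes, so active-condition effects are
    expressed relative to the variability seen without an intervention.
    """
    a, s = _paired(delta_active, delta_sham)
    sd = s.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError("zero variance of sham-condition changes")
    return float((a - s).mean() / sd)


def bca_percentiles(z0: float, a: float, alpha: float = 0.05):
    """BCa-adjusted quantile levels for the bootstrap distribution.

    With ``z0 = a = 0`` this reduces exactly to the percentile interval
    (alpha/2, 1 - alpha/2).
    """
    z = sps.norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])
    adj = z0 + (z0 + z) / (1.0 - a * (z0 + z))
    return tuple(sps.norm.cdf(adj))


def bca_ci(statistic, data, n_boot: int = 10_000, seed=None, alpha: float = 0.05):
    """BCa bootstrap confidence interval for a paired statistic.

    Parameters
    ----------
    statistic : callable
        ``statistic(*arrays) -> float``; evaluated on participant-resampled
        copies of ``data`` (pairing preserved: one index draw per resample).
    data : tuple of 1-d arrays
        Aligned per-participant arrays (e.g. ``(pre, post)``).
    n_boot : int
        Number of bootstrap resamples (default 10,000).
    seed : int, numpy Generator, or None
        Source of randomness; fix for reproducibility.

    Notes
    -----
    Bias correction z0 comes from the fraction of the bootstrap distribution
    below the point estimate; acceleration a from jackknife skewness.  If the
    bootstrap distribution is degenerate the interval collapses to the point
    estimate with a warning.
    """
    arrays = [np.asarray(x, dtype=float) for x in data]
    n = arrays[0].size
    if any(x.shape != (n,) for x in arrays):
        raise InputError("all data arrays must be 1-d of equal length")
    rng = np.random.default_rng(seed)
    theta = float(statistic(*arrays))

    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        try:
            boot[b] = statistic(*(x[idx[b]] for x in arrays))
        except UndefinedStatisticError:
            # e.g. a resample that drew a single participant n times
            boot[b] = np.nan
    boot = boot[np.isfinite(boot)]
    if boot.size < 2 or np.allclose(boot, boot[0]):
        warnings.warn("degenerate bootstrap distribution; interval collapses "
                      "to the point estimate")
        return theta, theta

    # bias correction
    n_eff = boot.size
    prop = np.mean(boot < theta)
    prop = min(max(prop, 1.0 / (2 * n_eff)), 1.0 - 1.0 / (2 * n_eff))
    z0 = float(sps.norm.ppf(prop))

    # acceleration from the jackknife
    jack = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        jack[i] = statistic(*(x[mask] for x in arrays))
        mask[i] = True
    dev = jack.mean() - jack
    denom = (dev ** 2).sum() ** 1.5
    a = float((dev ** 3).sum() / (6.0 * denom)) if denom > 0 else 0.0

    lo_q, hi_q = bca_percentiles(z0, a, alpha)
    lo, hi = np.quantile(boot, [lo_q, hi_q])
    return float(lo), float(hi)


def icc3(matrix):
    """ICC(3,1): two-way mixed, consistency, single-measure reliability.

    Parameters
    ----------
    matrix : array-like, shape (participants, sessions)
        Complete matrix of pre-intervention AURC values, one column per
        session.  Requires >= 3 participants and >= 2 sessions with no
        missing entries (case-complete).

    Returns
    -------
    float
        ``(BMS - EMS) / (BMS + (k - 1) * EMS)`` from the two-way ANOVA mean
        squares (BMS between participants, EMS residual).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise InputError("need a 2-d matrix with >= 3 participants, >= 2 sessions")
    if not np.all(np.isfinite(x)):
        raise InputError("matrix must be complete (case-complete requirement)")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    bms = k * ((row_means - grand) ** 2).sum() / (n - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ems = (resid ** 2).sum() / ((n - 1) * (k - 1))
    return float((bms - ems) / (bms + (k - 1) * ems))


def normality_check(values):
    """Shapiro-Wilk normality test; advisory only (no gating downstream).

    Returns ``(W, p)``; requires 3 <= n <= 5000.
    """
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise InputError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    w, p = sps.shapiro(x)
    return float(w), float(p)
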