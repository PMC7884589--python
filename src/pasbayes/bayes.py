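"""Interval-prior Bayes factors for the paired / one-sample t design.

The model places a zero-centred scaled Cauchy prior (scale ``r``, the JZS
prior) on the standardised effect size delta and restricts it to an interval
[a, b] defining the experimental hypothesis.  Given a paired t-statistic the
marginal likelihood of each hypothesis is the noncentral-t density of the
observed t averaged over the (renormalised) prior on that region, with
noncentrality delta * sqrt(n).

Three comparisons are supported:

``interval-vs-null``
    Marginal likelihood of the interval-restricted prior against the point
    null delta = 0.  This is the parameterisation selected by the calibration
    harness (see :mod:`pasbayes.calibration`) and therefore the default.
``complement-vs-null``
    The complement of the interval (both tails) against the point null.
``interval-vs-complement``
    The ratio of the two, i.e. the interval hypothesis against the hypothesis
    that the effect lies outside it.

Because the marginal likelihoods depend on the data only through (t, n), the
engine accepts either raw paired values or a bare t-statistic, which is what
makes published tables reproducible from print.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .exceptions import InputError, NumericalError
from .priors import PriorSpec

#: Default Cauchy prior scale on the standardised effect size (JZS default).
DEFAULT_R = math.sqrt(2.0) / 2.0

#: Comparison selected by calibration against published worked examples.
DEFAULT_COMPARISON = "interval-vs-null"

_COMPARISONS = ("interval-vs-null", "complement-vs-null", "interval-vs-complement")


@dataclass(frozen=True)
class BFModel:
    """Prior family and comparison for an interval Bayes-factor t-test.

    Parameters
    ----------
    r : float
        Scale of the zero-centred Cauchy prior on delta (default sqrt(2)/2).
    comparison : str
        One of ``interval-vs-null``, ``complement-vs-null``,
        ``interval-vs-complement``.
    epsabs : float
        Absolute quadrature tolerance for the marginal likelihoods.
    """

    r: float = DEFAULT_R
    comparison: str = DEFAULT_COMPARISON
    epsabs: float = 1e-10

    def __post_init__(self):
        if not self.r > 0:
            raise InputError(f"prior scale r must be positive, got {self.r}")
        if self.comparison not in _COMPARISONS:
            raise InputError(
                f"unknown comparison {self.comparison!r}; expected one of {_COMPARISONS}"
            )


@dataclass(frozen=True)
class TStatInput:
    """A paired-design t-statistic with its sample size (df = n - 1)."""

    t: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise InputError(f"paired sample size must be >= 2, got {self.n}")
        if not np.isfinite(self.t):
            raise InputError(f"t must be finite, got {self.t}")

    @property
    def df(self) -> int:
        return self.n - 1


def likelihood_t(t: float, df: int, delta: float, n: int) -> float:
    """Noncentral-t density of an observed t for true effect size ``delta``.

    The noncentrality parameter is ``delta * sqrt(n)`` for the one-sample /
    paired design.  ``delta = 0`` reduces to the central t density.
    """
    if df < 1:
        raise InputError(f"df must be >= 1, got {df}")
    return float(stats.nct.pdf(t, df, delta * math.sqrt(n)))


def prior_mass(model: BFModel, interval: tuple[float, float]) -> float:
    """Prior probability assigned to ``interval`` by the Cauchy(0, r) prior.

    F(b) - F(a) with F(x) = 1/2 + arctan(x/r)/pi; either bound may be
    infinite.
    """
    a, b = interval
    if not a < b:
        raise InputError(f"interval requires a < b, got [{a}, {b}]")
    return float(stats.cauchy.cdf(b, 0.0, model.r) - stats.cauchy.cdf(a, 0.0, model.r))


def _marginal(data: TStatInput, model: BFModel, a: float, b: float) -> float:
    """Unnormalised marginal likelihood integral of the prior over [a, b].

    The integrand (noncentral-t density times Cauchy density) is smooth and
    unimodal per segment; segments are split at 0 and scipy's adaptive
    quadrature maps infinite tails internally.
    """
    sqrt_n = math.sqrt(data.n)
    df, t, r = data.df, data.t, model.r

    def integrand(delta):
        return stats.nct.pdf(t, df, delta * sqrt_n) * stats.cauchy.pdf(delta, 0.0, r)

    # split at zero where the prior density peaks
    cuts = [a]
    if a < 0.0 < b:
        cuts.append(0.0)
    cuts.append(b)
    total = 0.0
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        val, err = integrate.quad(integrand, lo, hi, epsabs=model.epsabs, limit=200)
        if not np.isfinite(val):
            raise NumericalError(
                "marginal-likelihood quadrature failed",
                diagnostics={"t": t, "df": df, "segment": (lo, hi), "estimate": val},
            )
        total += val
    return total


def marginal_likelihoods(data: TStatInput, prior: PriorSpec, model: BFModel) -> dict:
    """Marginal likelihoods of the interval, complement and point-null models.

    Interval and complement marginals are renormalised by their prior mass so
    each is a proper (conditional-prior) marginal likelihood.
    """
    a, b = prior.interval
    p_int = prior_mass(model, (a, b))
    if not 0.0 < p_int < 1.0:
        raise InputError(
            f"prior mass of interval [{a}, {b}] must be in (0, 1), got {p_int}"
        )
    m_interval = _marginal(data, model, a, b) / p_int
    m_tails = _marginal(data, model, -np.inf, a) + _marginal(data, model, b, np.inf)
    m_complement = m_tails / (1.0 - p_int)
    m_null = float(stats.t.pdf(data.t, data.df))
    return {
        "interval": m_interval,
        "complement": m_complement,
        "null": m_null,
        "prior_mass_interval": p_int,
    }


def interval_bf(
    data: TStatInput,
    prior: PriorSpec,
    model: BFModel | None = None,
) -> float:
    """Bayes factor for the configured comparison (see :class:`BFModel`).

    Positive and finite for finite t; the comparison defaults to the
    calibrated ``interval-vs-null``.
    """
    model = model or BFModel()
    m = marginal_likelihoods(data, prior, model)
    if model.comparison == "interval-vs-null":
        return m["interval"] / m["null"]
    if model.comparison == "complement-vs-null":
        return m["complement"] / m["null"]
    return m["interval"] / m["complement"]


class IntervalBayesTTest:
    """Interval-prior Bayes-factor t-test for a paired design.

    Construct either from raw paired data (``pre``, ``post``) or from a bare
    t-statistic with its sample size.  ``fit()`` returns an
    :class:`IntervalBayesTTestResults` with the Bayes factor and, when raw
    data are available, the frequentist companions (one-tailed p, Cohen's d
    with the pre-intervention standardiser, BCa bootstrap CI).

    Examples
    --------
    >>> from pasbayes import IntervalBayesTTest, PriorSpec
    >>> prior = PriorSpec("Pre vs Post30", 0.849, 0.634, 1.063)
    >>> res = IntervalBayesTTest(prior, t=2.82, n=14).fit()
    >>> round(res.bf, 1)
    22.5
    """

    def __init__(self, prior: PriorSpec, t=None, n=None, pre=None, post=None,
                 model: BFModel | None = None):
        self.prior = prior
        self.model = model or BFModel()
        if pre is not None or post is not None:
            if pre is None or post is None:
                raise InputError("both pre and post must be given for raw data")
            self.pre = np.asarray(pre, dtype=float)
            self.post = np.asarray(post, dtype=float)
            if self.pre.shape != self.post.shape or self.pre.ndim != 1:
                raise InputError("pre and post must be 1-d arrays of equal length")
            self.data = None  # filled during fit
        elif t is not None and n is not None:
            self.pre = self.post = None
            self.data = TStatInput(float(t), int(n))
        else:
            raise InputError("provide either (pre, post) arrays or (t, n)")

    def fit(self, n_boot: int = 10_000, seed: int | None = None):
        from . import stats as _stats  # local import avoids a cycle

        if self.pre is not None:
            t, df, p = _stats.paired_t_one_tailed(self.pre, self.post)
            d = _stats.cohens_d_pre(self.pre, self.post)
            ci = _stats.bca_ci(
                _stats.cohens_d_pre, (self.pre, self.post), n_boot=n_boot, seed=seed
            )
            data = TStatInput(t, self.pre.size)
        else:
            data = self.data
            t, df = data.t, data.df
            p = float(stats.t.sf(t, df))
            d = ci = None
        m = marginal_likelihoods(data, self.prior, self.model)
        bf = interval_bf(data, self.prior, self.model)
        return IntervalBayesTTestResults(
            model=self, data=data, bf=bf, t=t, df=df, p_one_tailed=p,
            d=d, d_ci=ci, marginals=m,
        )


@dataclass
class IntervalBayesTTestResults:
    """Results of :meth:`IntervalBayesTTest.fit`."""

    model: IntervalBayesTTest
    data: TStatInput
    bf: float
    t: float
    df: int
    p_one_tailed: float
    d: float | None
    d_ci: tuple[float, float] | None
    marginals: dict = field(repr=False, default_factory=dict)

    def summary(self) -> str:
        p = self.model.prior
        lines = [
            "Interval-prior Bayes-factor t-test",
            "-" * 42,
            f"contrast        {p.contrast}",
            f"interval (d)    [{p.lower_d:.3f}, {p.upper_d:.3f}]",
            f"prior           Cauchy(0, {self.model.model.r:.4f}) truncated",
            f"comparison      {self.model.model.comparison}",
            f"BF              {self.bf:.3f}",
            f"t({self.df})           {self.t:.3f}",
            f"p (one-tailed)  {self.p_one_tailed:.4f}",
        ]
        if self.d is not None:
            lines.append(f"Cohen's d       {self.d:.3f}")
        if self.d_ci is not None:
            lines.append(f"95% BCa CI      [{self.d_ci[0]:.3f}, {self.d_ci[1]:.3f}]")
        return "\n".join(lines)
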