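"""Informed effect-size priors for the post-intervention contrasts.

Each experimental hypothesis is an interval of standardised effect sizes
(Cohen's d).  The default table pairs point estimates taken from an earlier
paired-stimulation study (linearly interpolated in time between the 0 min and
30 min contrasts) with interval bounds derived from published 95% confidence
intervals.  Priors are data, not code: the defaults ship as a table and can be
overridden from a delimited file for new studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import ConfigurationError, InputError

#: Post-intervention measurement times, minutes after the intervention ends.
POST_TIMES_MIN = {"Post0": 0.0, "Post10": 10.0, "Post20": 20.0, "Post30": 30.0}

#: Default point estimates at the interpolation endpoints (Cohen's d).
DEFAULT_D_POST0 = 0.601
DEFAULT_D_POST30 = 0.849

#: Default interval bounds per contrast (from published 95% CIs).
DEFAULT_BOUNDS = {
    "Post0": (0.403, 0.799),
    "Post10": (0.474, 0.893),
    "Post20": (0.556, 0.976),
    "Post30": (0.634, 1.063),
}


@dataclass(frozen=True)
class PriorSpec:
    """Effect-size prior for one Pre-vs-Post contrast.

    Attributes
    ----------
    contrast : str
        Label of the contrast, e.g. ``"Pre vs Post30"``.
    point_d : float
        Point estimate of the expected effect size (Cohen's d).
    lower_d, upper_d : float
        Bounds of the experimental-hypothesis interval on d.
    """

    contrast: str
    point_d: float
    lower_d: float
    upper_d: float

    def __post_init__(self):
        for name in ("point_d", "lower_d", "upper_d"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ConfigurationError(f"PriorSpec.{name} must be finite, got {v!r}")
        if not (self.lower_d < self.point_d < self.upper_d):
            raise ConfigurationError(
                "PriorSpec requires lower_d < point_d < upper_d, got "
                f"({self.lower_d}, {self.point_d}, {self.upper_d}) for {self.contrast!r}"
            )

    @property
    def interval(self) -> tuple[float, float]:
        return (self.lower_d, self.upper_d)

    @property
    def half_width(self) -> float:
        return 0.5 * (self.upper_d - self.lower_d)


def interpolate_point_estimates(
    d_post0: float,
    d_post30: float,
    times: Sequence[float],
) -> list[float]:
    """Linearly interpolate effect-size point estimates between 0 and 30 min.

    Parameters
    ----------
    d_post0, d_post30 : float
        Point estimates at the endpoints (0 and 30 minutes post-intervention).
    times : sequence of float
        Times in minutes; must lie inside [0, 30] (extrapolation is refused).
    """
    out = []
    for t in times:
        if not 0.0 <= t <= 30.0:
            raise InputError(f"time {t} min outside the interpolation range [0, 30]")
        out.append(d_post0 + (d_post30 - d_post0) * t / 30.0)
    return out


def build_prior_table(
    d_post0: float = DEFAULT_D_POST0,
    d_post30: float = DEFAULT_D_POST30,
    bounds: dict[str, tuple[float, float]] | None = None,
    timepoints: Iterable[str] = ("Post0", "Post10", "Post20", "Post30"),
) -> list[PriorSpec]:
    """Build the per-contrast prior table (one PriorSpec per post timepoint).

    Point estimates are interpolated linearly in minutes between the Post0 and
    Post30 endpoints; interval bounds default to the packaged table.
    """
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    tps = list(timepoints)
    times = [POST_TIMES_MIN[tp] for tp in tps]
    points = interpolate_point_estimates(d_post0, d_post30, times)
    specs = []
    for tp, d in zip(tps, points):
        lo, hi = bounds[tp]
        specs.append(PriorSpec(contrast=f"Pre vs {tp}", point_d=float(round(d, 3)),
                               lower_d=lo, upper_d=hi))
    return specs


def adjust_interval(observed_d: float, old: PriorSpec, ndigits: int = 2) -> PriorSpec:
    """Re-centre a prior interval on an observed effect size, preserving width.

    This is the hypothesis-updating rule for a replication: the interval keeps
    its half-width (i.e. "the same confidence intervals") but is re-centred on
    the effect size actually observed.  Bounds are rounded to ``ndigits``
    decimals for reporting (the pre-rounding width is preserved exactly).
    """
    w = old.half_width
    lo, hi = observed_d - w, observed_d + w
    return PriorSpec(
        contrast=old.contrast,
        point_d=float(observed_d),
        lower_d=round(lo, ndigits),
        upper_d=round(hi, ndigits),
    )


def priors_to_frame(priors: Iterable[PriorSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.contrast, p.point_d, p.lower_d, p.upper_d) for p in priors],
        columns=["contrast", "point_d", "lower_d", "upper_d"],
    )


def read_prior_table(path: str | Path) -> list[PriorSpec]:
    """Read a prior table from delimited text (contrast, point, lower, upper)."""
    df = pd.read_csv(path)
    required = {"contrast", "point_d", "lower_d", "upper_d"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"prior table missing columns: {sorted(missing)}")
    return [
        PriorSpec(r.contrast, float(r.point_d), float(r.lower_d), float(r.upper_d))
        for r in df.itertuples()
    ]


def write_prior_table(priors: Iterable[PriorSpec], path: str | Path) -> None:
    priors_to_frame(priors).to_csv(path, index=False)
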