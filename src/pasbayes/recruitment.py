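"""Recruitment curves and the area-under-recruitment-curve (AURC) summary.

For each (participant, condition, timepoint) cell the MEP amplitudes at the
eight stimulation intensities (90-160% rMT in 10% steps) are summarised by
the mean of the natural-log-transformed amplitudes, inverse-transformed back
to mV (i.e. the geometric mean).  The AURC - the trapezoidal-rule area of the
curve over intensity - is the excitability index carried forward to the
statistical analysis.  A curve with any invalid intensity cell yields a
missing AURC (no partial trapezoids); missing AURCs are filled later by kNN
imputation.

X-axis units are %rMT, so AURC has units mV*%rMT.  All downstream inference
uses within-subject contrasts, which are invariant to a fixed x-rescaling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InputError
from .preprocess import CELL_KEYS, QC_RETAINED

#: The eight stimulation intensities, % of resting motor threshold.
INTENSITIES = tuple(range(90, 161, 10))

CURVE_KEYS = ["participant", "condition", "timepoint"]


def log_mean_amplitude(amplitudes) -> float:
    """Geometric mean of MEP amplitudes: exp(mean(ln a)), in mV."""
    a = np.asarray(amplitudes, dtype=float)
    if a.size == 0:
        raise InputError("empty amplitude list")
    if np.any(a <= 0):
        raise InputError("amplitudes must be strictly positive (log undefined)")
    return float(np.exp(np.mean(np.log(a))))


def build_curves(trials: pd.DataFrame, cell_mask: pd.DataFrame | None = None,
                 amplitude_col: str = "mep_fcr_mv",
                 pool_extra_120: bool = True) -> pd.DataFrame:
    """Summarise QC'd trials into recruitment-curve points.

    Returns a long table with one row per (participant, condition, timepoint,
    intensity): geometric-mean amplitude (mV), retained trial count and a
    validity flag.  Every combination of the curve keys present in ``trials``
    is expanded to all eight intensities, so wholly empty cells appear as
    invalid points.  By default all retained trials at 120% rMT are pooled
    (the curve sequence plus the extra stimuli delivered at that intensity);
    ``pool_extra_120=False`` restricts every intensity to the first six trials.
    """
    retained = trials[trials["qc_status"] == QC_RETAINED].copy()
    if not pool_extra_120:
        retained = retained[retained["trial"] <= 6]

    grouped = (
        retained.groupby(CELL_KEYS)[amplitude_col]
        .agg([("amplitude_mv", log_mean_amplitude), ("n_trials", "size")])
        .reset_index()
    )

    curves = (
        trials[CURVE_KEYS].drop_duplicates()
        .merge(pd.DataFrame({"intensity_pct_rmt": INTENSITIES}), how="cross")
        .merge(grouped, on=CELL_KEYS, how="left")
    )
    curves["n_trials"] = curves["n_trials"].fillna(0).astype(int)
    curves["valid"] = curves["amplitude_mv"].notna()

    if cell_mask is not None:
        mask = cell_mask.set_index(CELL_KEYS)["valid"]
        keys = pd.MultiIndex.from_frame(curves[CELL_KEYS])
        cell_ok = mask.reindex(keys, fill_value=False).to_numpy()
        curves["valid"] &= cell_ok
        curves.loc[~curves["valid"], "amplitude_mv"] = np.nan
    return curves.sort_values(CURVE_KEYS + ["intensity_pct_rmt"]).reset_index(drop=True)


def threshold_sanity(curves: pd.DataFrame) -> pd.DataFrame:
    """Advisory check that the motor threshold was determined correctly.

    Flags, per curve, whether the mean amplitude at 90% rMT is below 0.05 mV
    and the amplitude at 100% rMT lies in the closed band [0.05, 0.1] mV.
    During acquisition a failure triggered re-thresholding; here the flags are
    purely advisory.
    """
    wide = curves.pivot_table(index=CURVE_KEYS, columns="intensity_pct_rmt",
                              values="amplitude_mv", observed=True)
    out = wide.reset_index()[CURVE_KEYS].copy()
    a90 = wide.get(90)
    a100 = wide.get(100)
    if a90 is None or a100 is None:
        raise InputError("curves must include 90% and 100% rMT points")
    out["pass_90"] = (a90 < 0.05).to_numpy()
    out["pass_100"] = ((a100 >= 0.05) & (a100 <= 0.1)).to_numpy()
    return out


def trapezoid_area(intensities, amplitudes) -> float:
    """Trapezoidal-rule area under a recruitment curve (mV * %rMT)."""
    x = np.asarray(intensities, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if x.size < 2:
        raise InputError("need at least 2 points for a trapezoid area")
    if np.any(np.diff(x) <= 0):
        raise InputError("intensities must be strictly increasing")
    return float(np.trapezoid(y, x))


def aurc_table(curves: pd.DataFrame) -> pd.DataFrame:
    """Compute the AURC for every curve; incomplete curves yield missing values.

    Returns one row per (participant, condition, timepoint) with columns
    ``aurc`` (mV*%rMT, NaN when missing), ``missing`` and ``imputed``
    (False here; set by the imputation stage).
    """
    rows = []
    for keys, grp in curves.groupby(CURVE_KEYS, sort=True):
        complete = bool(grp["valid"].all()) and len(grp) == len(INTENSITIES)
        if complete:
            g = grp.sort_values("intensity_pct_rmt")
            val = trapezoid_area(g["intensity_pct_rmt"], g["amplitude_mv"])
        else:
            val = np.nan
        rows.append((*keys, val, not complete, False))
    return pd.DataFrame(rows, columns=CURVE_KEYS + ["aurc", "missing", "imputed"])
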