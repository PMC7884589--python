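"""Trial-level quality control for MEP recordings.

Three rules, applied in a fixed order and tracked through a ``qc_status``
column:

1. absolute rule - a trial is rejected when the background RMS EMG in the
   93-3 ms pre-stimulus window exceeds 2.5 uV in EITHER muscle (strictly
   greater); elevated background indicates raised spinal motoneuron
   excitability that contaminates the MEP amplitude;
2. whisker rule - among the surviving trials, per participant and per muscle,
   a trial whose RMS exceeds Q3 + 1.5 * IQR of that participant's pooled
   retained RMS values is rejected;
3. minimum cell count - an analysis cell (participant x condition x timepoint
   x intensity) must keep at least five trials, otherwise the whole cell is
   invalid and its AURC becomes missing downstream.

Re-running the full sequence is idempotent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InputError

QC_RETAINED = "retained"
QC_REJECTED_ABSOLUTE = "rejected_absolute"
QC_REJECTED_WHISKER = "rejected_whisker"
QC_IN_INVALID_CELL = "in_invalid_cell"

MUSCLES = ("fcr", "ecr")
RMS_COLUMNS = {"fcr": "rms_fcr_uv", "ecr": "rms_ecr_uv"}

#: Absolute background-RMS rejection threshold, uV.
DEFAULT_ABS_THRESHOLD_UV = 2.5
#: Whisker multiplier on the IQR.
DEFAULT_WHISKER_MULTIPLIER = 1.5
#: Minimum retained trials per analysis cell.
DEFAULT_MIN_CELL_COUNT = 5

CELL_KEYS = ["participant", "condition", "timepoint", "intensity_pct_rmt"]


def background_rms(trace, sampling_rate, window=(-93.0, -3.0), onset_index=None):
    """Root-mean-square of a background EMG segment, in the trace's units.

    Parameters
    ----------
    trace : array-like
        Sampled EMG (uV).
    sampling_rate : float
        Samples per second (the study recorded at 4 kHz).
    window : (float, float)
        Half-open window [start, end) in ms relative to TMS onset; the
        default is the 93 ms to 3 ms pre-stimulus window.
    onset_index : int, optional
        Sample index of TMS onset.  Defaults to the last sample, i.e. a trace
        that ends at stimulus onset.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise InputError("trace must be 1-d")
    start_ms, end_ms = window
    if not start_ms < end_ms:
        raise InputError(f"window start must precede end, got {window}")
    onset = x.size if onset_index is None else int(onset_index)
    i0 = onset + int(round(start_ms * sampling_rate / 1000.0))
    i1 = onset + int(round(end_ms * sampling_rate / 1000.0))
    if i0 < 0 or i1 > x.size or i0 >= i1:
        raise InputError(
            f"window {window} ms outside trace extent (samples [{i0}, {i1}) "
            f"of {x.size})"
        )
    seg = x[i0:i1]
    return float(np.sqrt(np.mean(seg ** 2)))


def _require_qc_column(trials: pd.DataFrame) -> pd.DataFrame:
    out = trials.copy()
    if "qc_status" not in out.columns:
        out["qc_status"] = QC_RETAINED
        out["rejection_muscle"] = ""
    return out


def apply_absolute_rule(trials: pd.DataFrame,
                        threshold: float = DEFAULT_ABS_THRESHOLD_UV) -> pd.DataFrame:
    """Reject trials whose background RMS exceeds ``threshold`` in either muscle.

    The inequality is strict: a trial at exactly the threshold is retained.
    The whole trial (both muscles' MEPs) is disregarded.
    """
    out = _require_qc_column(trials)
    eligible = out["qc_status"].isin([QC_RETAINED, QC_IN_INVALID_CELL])
    fcr_bad = out[RMS_COLUMNS["fcr"]] > threshold
    ecr_bad = out[RMS_COLUMNS["ecr"]] > threshold
    bad = eligible & (fcr_bad | ecr_bad)
    out.loc[bad, "qc_status"] = QC_REJECTED_ABSOLUTE
    out.loc[bad, "rejection_muscle"] = np.where(fcr_bad[bad], "fcr", "ecr")
    out.loc[eligible & ~bad, "qc_status"] = QC_RETAINED
    return out


def apply_whisker_rule(trials: pd.DataFrame,
                       multiplier: float = DEFAULT_WHISKER_MULTIPLIER,
                       quantile_method: str = "linear",
                       per_cell: bool = False) -> pd.DataFrame:
    """Reject trials above the per-participant upper whisker of background RMS.

    Quartiles are computed per participant, separately per muscle, over all of
    that participant's retained RMS values (pooled across conditions and
    timepoints; set ``per_cell=True`` to pool within condition x timepoint
    instead).  A trial is rejected when its RMS in the offending muscle is
    strictly above Q3 + ``multiplier`` * IQR.  The quantile convention
    defaults to linear interpolation between order statistics (numpy
    ``method='linear'``, the common "type 7"); participants with fewer than 4
    retained values still get quartiles under the same convention.
    """
    out = _require_qc_column(trials)
    retained = out["qc_status"] == QC_RETAINED
    group_keys = ["participant"] + (["condition", "timepoint"] if per_cell else [])

    for muscle in MUSCLES:
        col = RMS_COLUMNS[muscle]
        # whiskers from currently retained trials only
        still = out["qc_status"] == QC_RETAINED
        whisker = (
            out.loc[still]
            .groupby(group_keys)[col]
            .apply(lambda v: _upper_whisker(v.to_numpy(), multiplier, quantile_method))
        )
        limits = out[group_keys].apply(tuple, axis=1) if len(group_keys) > 1 \
            else out["participant"]
        lim = limits.map(whisker)
        bad = (out["qc_status"] == QC_RETAINED) & (out[col] > lim)
        out.loc[bad, "qc_status"] = QC_REJECTED_WHISKER
        out.loc[bad, "rejection_muscle"] = muscle
    return out


def _upper_whisker(values: np.ndarray, multiplier: float, method: str) -> float:
    q1, q3 = np.quantile(values, [0.25, 0.75], method=method)
    return q3 + multiplier * (q3 - q1)


def enforce_min_cell_count(trials: pd.DataFrame,
                           min_count: int = DEFAULT_MIN_CELL_COUNT):
    """Invalidate analysis cells with fewer than ``min_count`` retained trials.

    Returns ``(trials, cell_mask)``: trials with retained rows of invalid
    cells re-flagged ``in_invalid_cell``, and a cell-validity mask indexed by
    (participant, condition, timepoint, intensity) covering every cell present
    in the input, empty cells included implicitly (a cell absent from the mask
    has no trials at all and is invalid).
    """
    out = _require_qc_column(trials)
    # idempotence: rows previously parked in invalid cells compete again
    out.loc[out["qc_status"] == QC_IN_INVALID_CELL, "qc_status"] = QC_RETAINED
    retained = out["qc_status"] == QC_RETAINED
    counts = out.loc[retained].groupby(CELL_KEYS).size()
    all_cells = out.groupby(CELL_KEYS).size()
    n_retained = counts.reindex(all_cells.index, fill_value=0)
    mask = (n_retained >= min_count).rename("valid").reset_index()

    invalid = set(map(tuple, mask.loc[~mask["valid"], CELL_KEYS].to_numpy()))
    keys = list(map(tuple, out[CELL_KEYS].to_numpy()))
    in_bad = np.fromiter((k in invalid for k in keys), bool, len(keys))
    out.loc[in_bad & retained.to_numpy(), "qc_status"] = QC_IN_INVALID_CELL
    return out, mask


def run_qc(trials: pd.DataFrame,
           threshold: float = DEFAULT_ABS_THRESHOLD_UV,
           multiplier: float = DEFAULT_WHISKER_MULTIPLIER,
           min_count: int = DEFAULT_MIN_CELL_COUNT,
           quantile_method: str = "linear",
           per_cell: bool = False):
    """Apply the full QC sequence (absolute -> whisker -> min cell count)."""
    out = apply_absolute_rule(trials, threshold)
    out = apply_whisker_rule(out, multiplier, quantile_method, per_cell)
    return enforce_min_cell_count(out, min_count)


def qc_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Counts per QC status per participant and timepoint (for the QC report)."""
    tab = (
        trials.groupby(["participant", "timepoint", "qc_status"])
        .size()
        .unstack(fill_value=0)
        .reset_index()
    )
    for col in (QC_RETAINED, QC_REJECTED_ABSOLUTE, QC_REJECTED_WHISKER,
                QC_IN_INVALID_CELL):
        if col not in tab.columns:
            tab[col] = 0
    return tab


def retention_rate(trials: pd.DataFrame) -> float:
    """Fraction of trials surviving the absolute and whisker rules."""
    ok = trials["qc_status"].isin([QC_RETAINED, QC_IN_INVALID_CELL])
    return float(ok.mean())
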