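"""Reading, writing and schema validation of the delimited trial table.

The trial table is long-format delimited text with a header and fixed column
names: participant, condition, timepoint, intensity_pct_rmt, trial,
mep_fcr_mv, mep_ecr_mv, rms_fcr_uv, rms_ecr_uv.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import SchemaError
from .recruitment import INTENSITIES
from .simulate import TIMEPOINTS

TRIAL_COLUMNS = [
    "participant", "condition", "timepoint", "intensity_pct_rmt", "trial",
    "mep_fcr_mv", "mep_ecr_mv", "rms_fcr_uv", "rms_ecr_uv",
]

KEY_COLUMNS = ["participant", "condition", "timepoint", "intensity_pct_rmt", "trial"]

POSITIVE_COLUMNS = ["mep_fcr_mv", "mep_ecr_mv", "rms_fcr_uv", "rms_ecr_uv"]


def validate_trial_table(df: pd.DataFrame,
                         conditions=None,
                         timepoints=TIMEPOINTS,
                         intensities=INTENSITIES) -> pd.DataFrame:
    """Validate a trial table against the pipeline schema.

    Raises :class:`SchemaError` listing offending rows for: missing columns,
    non-positive amplitudes or RMS values, unknown condition / timepoint /
    intensity labels, and duplicate (participant, condition, timepoint,
    intensity, trial) keys.  ``conditions=None`` accepts any condition label.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")

    problems = []
    for col in POSITIVE_COLUMNS:
        bad = df.index[~(df[col] > 0)]
        if len(bad):
            problems.append((f"non-positive {col}", bad))
    if conditions is not None:
        bad = df.index[~df["condition"].isin(conditions)]
        if len(bad):
            problems.append(("unknown condition label", bad))
    bad = df.index[~df["timepoint"].isin(timepoints)]
    if len(bad):
        problems.append(("unknown timepoint label", bad))
    bad = df.index[~df["intensity_pct_rmt"].isin(intensities)]
    if len(bad):
        problems.append(("unknown intensity level", bad))
    dup = df.index[df.duplicated(KEY_COLUMNS, keep=False)]
    if len(dup):
        problems.append(("duplicate trial key", dup))

    if problems:
        rows = sorted({int(i) for _, idx in problems for i in idx[:20]})
        msg = "; ".join(f"{what} (rows {list(idx[:5])}{'...' if len(idx) > 5 else ''})"
                        for what, idx in problems)
        raise SchemaError(f"trial table schema violations: {msg}", rows=rows)
    return df


def read_trial_table(path: str | Path, validate: bool = True,
                     conditions=None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if validate:
        validate_trial_table(df, conditions=conditions)
    return df


def write_trial_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
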