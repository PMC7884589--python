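"""Sequential k-nearest-neighbour imputation of missing AURC cells.

A missing (participant, condition, timepoint) cell is matched to the k
closest observed cells in a mixed feature space - the condition (categorical,
simple matching), the timepoint (ordered categorical, normalised rank
distance) and the participant's observed AURC profile at the other timepoints
(numeric, range-normalised) - under a Gower-type distance, and filled with
the median of the neighbours' values.  Cells are filled sequentially, rows
with the least missingness first, so later fills may draw on earlier ones;
observed values are never altered.

This is a deterministic re-specification of the sequential kNN scheme the
field commonly applies (ties among equidistant donors broken
lexicographically); it is documented as an approximation, not an emulation of
any particular package's internals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ImputationError, InputError
from .recruitment import CURVE_KEYS

log = logging.getLogger(__name__)

DEFAULT_TIMEPOINT_ORDER = ("Pre", "Post0", "Post10", "Post20", "Post30")


@dataclass
class ImputationSpec:
    """Configuration of the sequential kNN imputation.

    Attributes
    ----------
    k : int
        Neighbour count (default 10); reduced with a warning when fewer
        donors exist.
    timepoint_order : tuple of str
        Ordering of the timepoint labels used for the rank distance.
    """

    k: int = 10
    timepoint_order: tuple = DEFAULT_TIMEPOINT_ORDER

    def __post_init__(self):
        if self.k < 1:
            raise InputError(f"k must be >= 1, got {self.k}")


@dataclass
class ImputationLogEntry:
    """One filled cell: its donors and their distances (for the audit log)."""

    cell: tuple
    value: float
    donors: list = field(default_factory=list)
    distances: list = field(default_factory=list)


def _gower_distance(rec_row, don_row, rec_tp, don_tp, tp_rank, profiles,
                    ranges, timepoints):
    """Gower-type dissimilarity between a recipient and a donor cell."""
    parts = []
    # condition: simple matching
    parts.append(0.0 if rec_row[1] == don_row[1] else 1.0)
    # timepoint: normalised rank distance
    span = max(len(tp_rank) - 1, 1)
    parts.append(abs(tp_rank[rec_tp] - tp_rank[don_tp]) / span)
    # numeric profile over timepoints other than the recipient's target
    rec_prof = profiles[rec_row]
    don_prof = profiles[don_row]
    for tp in timepoints:
        if tp == rec_tp:
            continue
        a, b = rec_prof.get(tp), don_prof.get(tp)
        if a is None or b is None:
            continue
        rng = ranges[tp]
        parts.append(abs(a - b) / rng if rng > 0 else 0.0)
    return sum(parts) / len(parts)


def knn_impute(aurc: pd.DataFrame, spec: ImputationSpec | None = None):
    """Fill every missing AURC cell; returns ``(table, log_entries)``.

    The input is the long AURC table (participant, condition, timepoint,
    aurc, missing, imputed).  The returned table is complete, with
    ``imputed`` set on filled cells; the log lists each fill with its donors
    and distances.
    """
    spec = spec or ImputationSpec()
    out = aurc.copy().reset_index(drop=True)
    if not out["missing"].any():
        return out, []
    if not (~out["missing"]).any():
        raise ImputationError("no complete donor cells available")

    tp_rank = {tp: i for i, tp in enumerate(spec.timepoint_order)}
    unknown = set(out["timepoint"]) - set(tp_rank)
    if unknown:
        raise InputError(f"timepoints not in ordering: {sorted(unknown)}")

    # fill order: rows (participant x condition) with least missingness first,
    # then fixed table order
    miss = out[out["missing"]].copy()
    row_missing = out.groupby(["participant", "condition"])["missing"].sum()
    miss["row_miss"] = list(map(
        lambda pc: row_missing[pc],
        zip(miss["participant"], miss["condition"]),
    ))
    miss = miss.sort_values(
        ["row_miss", "participant", "condition", "timepoint"],
        key=lambda s: s.map(tp_rank) if s.name == "timepoint" else s,
    )

    entries = []
    for idx in miss.index:
        rec = out.loc[idx]
        rec_key = (rec["participant"], rec["condition"])
        rec_tp = rec["timepoint"]

        observed = out[~out["aurc"].isna()]
        if observed.empty:
            raise ImputationError("no complete donor cells available")
        ranges = {
            tp: float(g["aurc"].max() - g["aurc"].min())
            for tp, g in observed.groupby("timepoint")
        }
        profiles = {
            key: dict(zip(g["timepoint"], g["aurc"]))
            for key, g in observed.groupby(["participant", "condition"])
        }
        profiles.setdefault(rec_key, {})

        cands = []
        for j in observed.index:
            if j == idx:
                continue
            don = out.loc[j]
            d = _gower_distance(
                rec_key, (don["participant"], don["condition"]),
                rec_tp, don["timepoint"], tp_rank, profiles, ranges,
                list(spec.timepoint_order),
            )
            cands.append((d, don["participant"], don["condition"],
                          tp_rank[don["timepoint"]], don["timepoint"],
                          float(don["aurc"])))
        cands.sort(key=lambda c: c[:4])  # lexicographic tie-break
        k = min(spec.k, len(cands))
        if k < spec.k:
            warnings.warn(
                f"only {k} donors available for cell "
                f"{(rec['participant'], rec['condition'], rec_tp)}; using all"
            )
        chosen = cands[:k]
        value = float(np.median([c[5] for c in chosen]))
        out.loc[idx, "aurc"] = value
        out.loc[idx, "missing"] = False
        out.loc[idx, "imputed"] = True
        entry = ImputationLogEntry(
            cell=(rec["participant"], rec["condition"], rec_tp),
            value=value,
            donors=[(c[1], c[2], c[4]) for c in chosen],
            distances=[c[0] for c in chosen],
        )
        entries.append(entry)
        log.debug("imputed %s = %.4f from %d donors", entry.cell, value, k)
    return out, entries
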