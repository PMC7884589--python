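"""The experiment-level model: trial table in, Bayes-factor report out.

:class:`PASExperiment` is the statsmodels-style entry point: construct it
from a trial-level DataFrame (or CSV), call :meth:`PASExperiment.fit`, and
receive a :class:`PASResults` carrying the QC'd trials, recruitment curves,
AURC tables (pre- and post-imputation), the main per-condition contrast
report (Bayes factor, t, one-tailed p, Cohen's d, BCa interval), the
between-condition supplementary report, the pre-intervention session
reliability (ICC(3)) and normality screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import preprocess, recruitment, stats
from .bayes import BFModel, TStatInput, interval_bf
from .exceptions import InputError, PipelineError
from .impute import ImputationSpec, knn_impute
from .io import validate_trial_table
from .priors import PriorSpec, build_prior_table

POST_TIMEPOINTS = ("Post0", "Post10", "Post20", "Post30")


def _aurc_wide(aurc: pd.DataFrame, condition: str) -> pd.DataFrame:
    sub = aurc[aurc["condition"] == condition]
    wide = sub.pivot(index="participant", columns="timepoint", values="aurc")
    return wide.sort_index()


def bf_report(aurc: pd.DataFrame,
              priors: Sequence[PriorSpec] | None = None,
              model: BFModel | None = None,
              n_boot: int = 10_000,
              seed=None,
              conditions: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-condition Pre-vs-Post contrast report from a complete AURC table.

    One row per (condition, post timepoint): Bayes factor under the informed
    interval prior, paired t, df, one-tailed p, Cohen's d standardised by the
    pre-intervention SD and its 95% BCa bootstrap interval.
    """
    if aurc["aurc"].isna().any():
        raise PipelineError("AURC table contains missing cells; impute first")
    priors = list(priors) if priors is not None else build_prior_table()
    model = model or BFModel()
    by_tp = {p.contrast.split()[-1]: p for p in priors}
    if conditions is None:
        conditions = list(dict.fromkeys(aurc["condition"]))

    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rows = []
    for cond in conditions:
        wide = _aurc_wide(aurc, cond)
        pre = wide["Pre"].to_numpy()
        for tp in POST_TIMEPOINTS:
            if tp not in wide.columns:
                continue
            post = wide[tp].to_numpy()
            prior = by_tp[tp]
            t, df, p = stats.paired_t_one_tailed(pre, post)
            d = stats.cohens_d_pre(pre, post)
            sub_seed = np.random.default_rng(ss.spawn(1)[0])
            lo, hi = stats.bca_ci(stats.cohens_d_pre, (pre, post),
                                  n_boot=n_boot, seed=sub_seed)
            bf = interval_bf(TStatInput(t, pre.size), prior, model)
            rows.append((cond, prior.contrast, bf, t, df, p, d, lo, hi))
    return pd.DataFrame(rows, columns=[
        "condition", "contrast", "bf", "t", "df", "p_one_tailed",
        "d", "d_lower", "d_upper",
    ])


def supplementary_report(aurc: pd.DataFrame,
                         sham: str = "Sham",
                         n_boot: int = 10_000,
                         seed=None) -> pd.DataFrame:
    """Between-condition effect sizes on baseline-subtracted AURC changes.

    For each active condition and post timepoint, the change from baseline
    (post - pre, per participant) is contrasted with the sham-condition
    change; the standardiser is the SD of the sham changes.  Baseline
    subtraction mitigates the impact of the modest between-session
    reliability of the pre-intervention measurement.
    """
    conditions = [c for c in dict.fromkeys(aurc["condition"]) if c != sham]
    if sham not in set(aurc["condition"]):
        raise InputError(f"sham condition {sham!r} not present")
    wide_sham = _aurc_wide(aurc, sham)
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rows = []
    for cond in conditions:
        wide = _aurc_wide(aurc, cond)
        if not wide.index.equals(wide_sham.index):
            raise PipelineError("participants differ between conditions")
        for tp in POST_TIMEPOINTS:
            if tp not in wide.columns:
                continue
            delta_a = (wide[tp] - wide["Pre"]).to_numpy()
            delta_s = (wide_sham[tp] - wide_sham["Pre"]).to_numpy()
            d = stats.between_condition_d(delta_a, delta_s)
            sub_seed = np.random.default_rng(ss.spawn(1)[0])
            lo, hi = stats.bca_ci(stats.between_condition_d, (delta_a, delta_s),
                                  n_boot=n_boot, seed=sub_seed)
            rows.append((cond, tp, d, lo, hi))
    return pd.DataFrame(rows, columns=["condition", "timepoint",
                                       "d", "d_lower", "d_upper"])


class PASExperiment:
    """Full PAS analysis of a trial-level dataset.

    Parameters
    ----------
    trials : DataFrame
        Long-format trial table (see :mod:`pasbayes.io` for the schema).
    priors : list of PriorSpec, optional
        Informed effect-size priors per contrast; defaults to the packaged
        table.  The same priors apply to every condition.
    bf_model : BFModel, optional
        Prior scale and comparison; defaults to the calibrated
        parameterisation.
    abs_threshold, whisker_multiplier, min_cell_count, quantile_method :
        QC rule settings; defaults are the published values (2.5 uV, 1.5,
        5 trials, linear/type-7 quantiles).
    imputation : ImputationSpec, optional
        Sequential kNN settings (default k = 10).

    Examples
    --------
    >>> from pasbayes import PASExperiment, SimConfig, generate_dataset
    >>> trials = generate_dataset(SimConfig(seed=7))
    >>> res = PASExperiment.from_dataframe(trials).fit(n_boot=2000, seed=1)
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(self, trials: pd.DataFrame, *,
                 priors: Sequence[PriorSpec] | None = None,
                 bf_model: BFModel | None = None,
                 abs_threshold: float = preprocess.DEFAULT_ABS_THRESHOLD_UV,
                 whisker_multiplier: float = preprocess.DEFAULT_WHISKER_MULTIPLIER,
                 min_cell_count: int = preprocess.DEFAULT_MIN_CELL_COUNT,
                 quantile_method: str = "linear",
                 imputation: ImputationSpec | None = None,
                 sham_condition: str = "Sham",
                 validate: bool = True):
        if validate:
            validate_trial_table(trials)
        self.trials = trials
        self.priors = list(priors) if priors is not None else build_prior_table()
        self.bf_model = bf_model or BFModel()
        self.abs_threshold = abs_threshold
        self.whisker_multiplier = whisker_multiplier
        self.min_cell_count = min_cell_count
        self.quantile_method = quantile_method
        self.imputation = imputation or ImputationSpec()
        self.sham_condition = sham_condition

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame, **kwargs) -> "PASExperiment":
        return cls(trials, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "PASExperiment":
        from .io import read_trial_table
        return cls(read_trial_table(path, validate=False), **kwargs)

    def fit(self, n_boot: int = 10_000, seed=None,
            supplementary: bool = True) -> "PASResults":
        """Run QC, curve building, AURC, imputation and both reports."""
        qcd, mask = preprocess.run_qc(
            self.trials, self.abs_threshold, self.whisker_multiplier,
            self.min_cell_count, self.quantile_method,
        )
        curves = recruitment.build_curves(qcd, mask)
        aurc_pre = recruitment.aurc_table(curves)
        aurc, imp_log = knn_impute(aurc_pre, self.imputation)

        ss = np.random.SeedSequence(seed)
        seed_main, seed_supp = ss.spawn(2)
        contrasts = bf_report(aurc, self.priors, self.bf_model,
                              n_boot=n_boot, seed=seed_main)
        supp = None
        if supplementary and self.sham_condition in set(aurc["condition"]):
            supp = supplementary_report(aurc, self.sham_condition,
                                        n_boot=n_boot, seed=seed_supp)

        icc = self._icc(aurc_pre)
        shapiro = self._normality(aurc)
        return PASResults(
            model=self, seed=seed, trials=qcd, cell_mask=mask, curves=curves,
            aurc_pre_imputation=aurc_pre, aurc=aurc, imputation_log=imp_log,
            contrasts=contrasts, supplementary=supp, icc=icc,
            normality=shapiro,
            retention=preprocess.retention_rate(qcd),
            threshold_flags=recruitment.threshold_sanity(curves),
        )

    def _icc(self, aurc_pre: pd.DataFrame) -> float | None:
        """ICC(3) of case-complete, non-imputed pre-intervention AURCs."""
        pre = aurc_pre[(aurc_pre["timepoint"] == "Pre") & ~aurc_pre["missing"]]
        mat = pre.pivot(index="participant", columns="condition", values="aurc")
        mat = mat.dropna()
        if mat.shape[0] < 3 or mat.shape[1] < 2:
            return None
        return stats.icc3(mat.to_numpy())

    def _normality(self, aurc: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for (cond, tp), grp in aurc.groupby(["condition", "timepoint"]):
            if len(grp) < 3:
                continue
            w, p = stats.normality_check(grp["aurc"].to_numpy())
            rows.append((cond, tp, w, p))
        return pd.DataFrame(rows, columns=["condition", "timepoint", "W", "p"])


@dataclass
class PASResults:
    """Results of :meth:`PASExperiment.fit` (the machine twin of the report)."""

    model: PASExperiment
    seed: object
    trials: pd.DataFrame = field(repr=False)
    cell_mask: pd.DataFrame = field(repr=False)
    curves: pd.DataFrame = field(repr=False)
    aurc_pre_imputation: pd.DataFrame = field(repr=False)
    aurc: pd.DataFrame = field(repr=False)
    imputation_log: list = field(repr=False)
    contrasts: pd.DataFrame = field(repr=False)
    supplementary: pd.DataFrame | None = field(repr=False)
    icc: float | None
    normality: pd.DataFrame = field(repr=False)
    retention: float
    threshold_flags: pd.DataFrame = field(repr=False)

    def summary(self) -> str:
        lines = [
            "PAS Bayes-factor analysis",
            "=" * 64,
            f"trials retained after QC: {self.retention:.1%}"
            f"   imputed AURC cells: {int(self.aurc['imputed'].sum())}"
            f" of {len(self.aurc)}",
        ]
        if self.icc is not None:
            lines.append(f"pre-intervention session reliability ICC(3): "
                         f"{self.icc:.2f}")
        lines += ["", "Main contrasts (interval-prior Bayes factors)",
                  "-" * 64,
                  f"{'condition':<10} {'contrast':<14} {'BF':>7} {'t':>6} "
                  f"{'p':>6} {'d':>6} {'95% BCa CI':>14}"]
        for r in self.contrasts.itertuples():
            lines.append(
                f"{r.condition:<10} {r.contrast:<14} {r.bf:>7.1f} {r.t:>6.2f} "
                f"{r.p_one_tailed:>6.3f} {r.d:>6.2f} "
                f"[{r.d_lower:>5.2f}, {r.d_upper:>5.2f}]"
            )
        if self.supplementary is not None:
            lines += ["", "Supplementary: active vs sham "
                          "(baseline-subtracted, sham standardiser)",
                      "-" * 64]
            for r in self.supplementary.itertuples():
                lines.append(
                    f"{r.condition:<10} {r.timepoint:<14} {r.d:>6.2f} "
                    f"[{r.d_lower:>5.2f}, {r.d_upper:>5.2f}]"
                )
        return "\n".join(lines)

    def plot_deltas(self, ax=None):
        """Violin plot of per-participant AURC changes, per condition."""
        from .plotting import plot_aurc_changes
        return plot_aurc_changes(self.aurc, ax=ax)
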