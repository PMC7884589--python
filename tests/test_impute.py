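"""Sequential kNN imputation of missing AURC cells."""

import numpy as np
import pandas as pd
import pytest

from pasbayes.exceptions import ImputationError
from pasbayes.impute import ImputationSpec, knn_impute


def aurc_frame(values: dict, timepoints=("Pre", "Post0", "Post10", "Post20")):
    """Build a long AURC table from {(participant, condition): [v per tp]}."""
    rows = []
    for (p, c), vals in values.items():
        for tp, v in zip(timepoints, vals):
            rows.append((p, c, tp, v, v is None, False))
    df = pd.DataFrame(rows, columns=["participant", "condition", "timepoint",
                                     "aurc", "missing", "imputed"])
    df["aurc"] = df["aurc"].astype(float)
    return df


class TestBasics:
    def test_no_missing_identity(self, toy_aurc):
        full = toy_aurc[~toy_aurc["missing"]].reset_index(drop=True)
        out, log = knn_impute(full)
        pd.testing.assert_frame_equal(out, full)
        assert log == []

    def test_constant_neighbourhood(self):
        vals = {("P1", "A"): [30.0, None, 30.0, 30.0]}
        vals.update({(f"P{i}", "A"): [30.0, 30.0, 30.0, 30.0]
                     for i in range(2, 6)})
        out, log = knn_impute(aurc_frame(vals), ImputationSpec(k=4))
        filled = out[out["imputed"]]
        assert len(filled) == 1
        assert filled["aurc"].iloc[0] == pytest.approx(30.0)

    def test_no_donors_raises(self):
        vals = {("P1", "A"): [None, None, None, None]}
        with pytest.raises(ImputationError):
            knn_impute(aurc_frame(vals))

    def test_k_reduced_with_warning(self):
        vals = {("P1", "A"): [20.0, None, 22.0, 21.0],
                ("P2", "A"): [25.0, 24.0, 26.0, 25.0]}
        with pytest.warns(UserWarning, match="donors"):
            out, log = knn_impute(aurc_frame(vals), ImputationSpec(k=50))
        assert not out["missing"].any()


def brute_force_impute(df, k, timepoints):
    """Independent exhaustive-search re-implementation for small tables."""
    df = df.copy().reset_index(drop=True)
    rank = {tp: i for i, tp in enumerate(timepoints)}
    missing_rows = df[df["missing"]]
    per_row = df.groupby(["participant", "condition"])["missing"].sum()
    order = sorted(
        missing_rows.index,
        key=lambda i: (per_row[(df.loc[i, "participant"], df.loc[i, "condition"])],
                       df.loc[i, "participant"], df.loc[i, "condition"],
                       rank[df.loc[i, "timepoint"]]),
    )
    for i in order:
        p, c, tp = df.loc[i, ["participant", "condition", "timepoint"]]
        obs = df[df["aurc"].notna()]
        ranges = {u: g["aurc"].max() - g["aurc"].min()
                  for u, g in obs.groupby("timepoint")}
        prof = {key: dict(zip(g["timepoint"], g["aurc"]))
                for key, g in obs.groupby(["participant", "condition"])}
        cands = []
        for j in obs.index:
            q, e, u = df.loc[j, ["participant", "condition", "timepoint"]]
            parts = [0.0 if c == e else 1.0,
                     abs(rank[tp] - rank[u]) / (len(timepoints) - 1)]
            for w in timepoints:
                if w == tp:
                    continue
                a = prof.get((p, c), {}).get(w)
                b = prof.get((q, e), {}).get(w)
                if a is None or b is None:
                    continue
                parts.append(abs(a - b) / ranges[w] if ranges[w] > 0 else 0.0)
            cands.append((sum(parts) / len(parts), q, e, rank[u],
                          df.loc[j, "aurc"]))
        cands.sort(key=lambda t: t[:4])
        df.loc[i, "aurc"] = float(np.median([t[4] for t in cands[:k]]))
        df.loc[i, "missing"] = False
        df.loc[i, "imputed"] = True
    return df


class TestExhaustiveOracle:
    def test_toy_table_matches_brute_force(self):
        """6-row x 4-timepoint toy table with two holes: exact agreement."""
        rng = np.random.default_rng(9)
        tps = ("Pre", "Post0", "Post10", "Post20")
        vals = {}
        for p in ("P1", "P2", "P3"):
            for c in ("A", "B"):
                vals[(p, c)] = list(rng.uniform(20, 60, 4).round(2))
        vals[("P1", "A")][2] = None
        vals[("P3", "B")][0] = None
        df = aurc_frame(vals, tps)
        spec = ImputationSpec(k=3, timepoint_order=tps)
        got, _ = knn_impute(df, spec)
        expected = brute_force_impute(df, 3, tps)
        pd.testing.assert_series_equal(got["aurc"], expected["aurc"])

    def test_donor_row_permutation_invariance(self):
        rng = np.random.default_rng(13)
        tps = ("Pre", "Post0", "Post10", "Post20")
        vals = {(f"P{i}", c): list(rng.uniform(10, 50, 4).round(2))
                for i in range(1, 5) for c in ("A", "B")}
        vals[("P2", "B")][3] = None
        df = aurc_frame(vals, tps)
        spec = ImputationSpec(k=5, timepoint_order=tps)
        out1, _ = knn_impute(df, spec)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        out2, _ = knn_impute(shuffled, spec)
        key = ["participant", "condition", "timepoint"]
        v1 = out1.set_index(key)["aurc"].sort_index()
        v2 = out2.set_index(key)["aurc"].sort_index()
        pd.testing.assert_series_equal(v1, v2)


class TestProperties:
    def test_imputed_within_donor_range(self, toy_aurc):
        out, log = knn_impute(toy_aurc, ImputationSpec(k=5))
        for entry in log:
            donors = [out.set_index(["participant", "condition",
                                     "timepoint"]).loc[d, "aurc"]
                      for d in entry.donors]
            assert min(donors) <= entry.value <= max(donors)

    def test_observed_values_never_altered(self, toy_aurc):
        out, _ = knn_impute(toy_aurc)
        obs = ~toy_aurc["missing"]
        assert np.allclose(out.loc[obs, "aurc"], toy_aurc.loc[obs, "aurc"])

    def test_error_shrinks_with_session_noise(self):
        """MCAR deletions recover better when between-session noise is small."""
        from pasbayes import preprocess as pp
        from pasbayes.recruitment import aurc_table, build_curves
        from pasbayes.simulate import SimConfig, generate_dataset

        def mean_abs_err(tau_s, seeds):
            errs = []
            for seed in seeds:
                cfg = SimConfig(seed=seed, n_participants=8,
                                conditions=("Sham",), contamination_rate=0.0,
                                tau_session=tau_s, tau_timepoint=0.05,
                                sigma_log=0.3)
                qcd, mask = pp.run_qc(generate_dataset(cfg))
                truth = aurc_table(build_curves(qcd, mask))
                rng = np.random.default_rng(seed)
                holes = rng.choice(len(truth), 3, replace=False)
                holed = truth.copy()
                holed.loc[holes, "aurc"] = np.nan
                holed.loc[holes, "missing"] = True
                filled, _ = knn_impute(holed)
                errs.append(np.abs(filled.loc[holes, "aurc"]
                                   - truth.loc[holes, "aurc"]).mean())
            return np.mean(errs)

        seeds = range(6)
        assert mean_abs_err(0.02, seeds) < mean_abs_err(0.8, seeds)
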