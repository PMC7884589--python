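import matplotlib
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

matplotlib.use("Agg")

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_trials():
    """A small synthetic trial table: 6 participants, 2 conditions."""
    from pasbayes.simulate import SimConfig, generate_dataset

    cfg = SimConfig(seed=11, n_participants=6, conditions=("TMS-TMS", "Sham"))
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_priors():
    from pasbayes.priors import build_prior_table

    return build_prior_table()


@pytest.fixture()
def toy_aurc():
    """A 6-row x 4-timepoint AURC table with one missing cell."""
    rows = []
    rng = np.random.default_rng(5)
    tps = ("Pre", "Post0", "Post10", "Post20")
    for p in ("P1", "P2", "P3"):
        for c in ("A", "B"):
            base = rng.uniform(20, 60)
            for tp in tps:
                rows.append((p, c, tp, base + rng.normal(0, 3), False, False))
    df = pd.DataFrame(rows, columns=["participant", "condition", "timepoint",
                                     "aurc", "missing", "imputed"])
    df.loc[5, ["aurc", "missing"]] = [np.nan, True]
    return df
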