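"""Basic visualisation of AURC changes (violin + bootstrap CI)."""

from __future__ import annotations

import numpy as np

from . import stats


def plot_aurc_changes(aurc, ax=None, n_boot: int = 10_000, seed=0):
    """Violin plot of per-participant AURC changes (post - pre) per condition.

    One violin per (condition, post timepoint), with individual participant
    points, the mean, and a 95% bootstrap CI of the mean.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    conditions = list(dict.fromkeys(aurc["condition"]))
    post_tps = [tp for tp in ("Post0", "Post10", "Post20", "Post30")
                if tp in set(aurc["timepoint"])]
    if ax is None:
        _, ax = plt.subplots(figsize=(2.5 * len(conditions) + 2, 4))

    rng = np.random.default_rng(seed)
    positions, labels, data = [], [], []
    pos = 0
    for cond in conditions:
        wide = (aurc[aurc["condition"] == cond]
                .pivot(index="participant", columns="timepoint", values="aurc"))
        for tp in post_tps:
            delta = (wide[tp] - wide["Pre"]).to_numpy()
            data.append(delta)
            positions.append(pos)
            labels.append(f"{cond}\n{tp}")
            pos += 1
        pos += 1

    ax.violinplot(data, positions=positions, showextrema=False)
    for x, delta in zip(positions, data):
        jitter = (np.linspace(-0.08, 0.08, delta.size))
        ax.plot(x + jitter, delta, "o", ms=3, alpha=0.6)
        boot = np.array([
            delta[rng.integers(0, delta.size, delta.size)].mean()
            for _ in range(n_boot)
        ])
        lo, hi = np.quantile(boot, [0.025, 0.975])
        ax.errorbar(x, delta.mean(), yerr=[[delta.mean() - lo], [hi - delta.mean()]],
                    fmt="ko", capsize=4, ms=5)
    ax.axhline(0.0, ls="--", c="grey", lw=1)
    ax.set_xticks(positions)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylabel("change in AURC (mV·%rMT)")
    return ax
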