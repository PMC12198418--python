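#!/usr/bin/env python
"""State-derived behavioural statistics on synthetic ground truth.

Plants the relationships the statistics are built to detect — a quadratic
switch-performance law with its optimum at nine switches, a negative linear
load dependence of encoding-state dwell time, and a distractor effect on
state-1 dwell — then recovers them with the package's regression and
contrast machinery. Writes results/behaviour_fits.json.
"""

import json
from pathlib import Path

import numpy as np

from oscroute.states import (
    StateSequence,
    distractor_contrast,
    load_regression,
    pc1_performance,
    switch_performance_regression,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    out = {}

    # switch-performance: planted optimum at 9 switches
    switches = rng.integers(2, 17, size=120).astype(float)
    rt = 400.0 + 4.0 * (switches - 9.0) ** 2 + 20.0 * rng.standard_normal(120)
    fit = switch_performance_regression(switches, rt)
    out["switch_optimum"] = fit["optimal_switches"]
    out["switch_quadratic_beta_sd"] = fit["report"].beta("switches_sq")
    print(f"switch-performance optimum: {fit['optimal_switches']:.2f} "
          f"(planted 9)")

    # PC1 of a correlated 3-test battery
    factor = rng.standard_normal(120)
    battery = np.column_stack([factor + 0.4 * rng.standard_normal(120)
                               for _ in range(3)])
    pc = pc1_performance(battery)
    out["pc1_explained_variance"] = pc["explained_variance_ratio"]
    print(f"PC1 explains {100 * pc['explained_variance_ratio']:.0f}% of the "
          "battery variance")

    # load regression: dwell time in the encoding state falls with load
    load = np.tile(np.arange(6), 12).astype(float)
    zload = (load - load.mean()) / load.std()
    dwell = 0.25 - 0.05 * zload + 0.01 * rng.standard_normal(load.size)
    rep = load_regression(dwell, load, form="linear")["report"]
    out["load_slope_beta_sd"] = rep.beta("load")
    row = rep.table.loc["load"]
    print(f"load slope beta_sd = {row['beta_sd']:.2f} "
          f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}], p = {row['p']:.2g}")

    # distractor contrast: planted 100 ms effect in the expected directions
    windows = [(1.5, 2.0), (2.5, 3.0), (3.5, 4.0)]
    directions = [-1, -1, +1]
    rate, T, n_subj = 100.0, 450, 13
    dist = np.full((n_subj, T), 2)
    ctrl = np.full((n_subj, T), 2)
    for s in range(n_subj):
        for (a, b), sign in zip(windows, directions):
            i0 = int(a * rate)
            n_ctrl = 25
            delta = sign * (0.100 + 0.050 * rng.standard_normal())
            n_dist = int(round(n_ctrl + delta * rate))
            ctrl[s, i0:i0 + n_ctrl] = 1
            dist[s, i0:i0 + max(n_dist, 0)] = 1
    rep, per = distractor_contrast(
        StateSequence(labels=dist, sampling_rate=rate),
        StateSequence(labels=ctrl, sampling_rate=rate),
        windows, directions)
    out["distractor_mean_difference_ms"] = 1000 * rep.mean_difference
    out["distractor_cohens_d"] = rep.d
    out["distractor_p"] = rep.p
    print(f"distractor contrast: {1000 * rep.mean_difference:.0f} ms "
          f"(d = {rep.d:.2f}, one-sided p = {rep.p:.3g})")

    (RESULTS / "behaviour_fits.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
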