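#!/usr/bin/env python
"""Generate the synthetic study inputs: an envelope cohort with planted
networks/states and a structural connectome with posterior/dorsal modules.

Writes small summaries to results/ and the full arrays to scratch/ (the
downstream analysis scripts regenerate inputs from the same seeds, so
scratch/ is a convenience, not a dependency).
"""

from pathlib import Path

import numpy as np

from oscroute.connectome import write_graph
from oscroute.syndata import (
    ConnectomeSpec,
    EnvelopeSpec,
    generate_cohort,
    generate_connectome,
    write_envelopes,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"

COHORT = dict(n_subjects=4, n_trials=10, n_parcels=60, trial_duration=3.0,
              seed=1)
CONNECTOME = dict(n_cortical=40, seed=0)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)

    spec = EnvelopeSpec(**COHORT)
    env, seq = generate_cohort(spec)
    write_envelopes(env, SCRATCH / "cohort")
    print(f"cohort: {env.n_subjects} subjects x {env.n_trials} trials x "
          f"{env.n_parcels} parcels x {env.n_times} samples at "
          f"{env.sampling_rate:.0f} Hz")
    occ = np.bincount(seq.labels.ravel(), minlength=spec.K + 1)[1:]
    print("hidden state occupancy:", np.round(occ / occ.sum(), 3))

    g = generate_connectome(ConnectomeSpec(**CONNECTOME))
    write_graph(g, SCRATCH / "connectome_raw")
    print(f"raw connectome: {g.n_nodes} nodes "
          f"({g.cortical.size} cortical + {g.subcortical.size} subcortical), "
          f"masks: { {k: len(v) for k, v in g.masks.items()} }")

    (RESULTS / "cohort_conditions.json").write_text(
        __import__("json").dumps({"cohort": COHORT, "connectome": CONNECTOME},
                                 indent=2))


if __name__ == "__main__":
    main()
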