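"""Shared fixtures: a synthetic envelope cohort with planted networks and a
small collapsed connectome. Session-scoped because generation plus ICA is
the expensive part of the suite."""

from __future__ import annotations

import numpy as np
import pytest

from oscroute.connectome import collapse_subcortex
from oscroute.networks import extract_components, match_components
from oscroute.spectral import EnvelopeArray, normalize_envelopes
from oscroute.syndata import ConnectomeSpec, EnvelopeSpec, generate_cohort, generate_connectome

COHORT_SPEC = dict(n_subjects=4, n_trials=10, n_parcels=60,
                   trial_duration=3.0, seed=1)


@pytest.fixture(scope="session")
def cohort():
    """(envelopes, true state sequence, spec) with 4 planted networks."""
    spec = EnvelopeSpec(**COHORT_SPEC)
    env, seq = generate_cohort(spec)
    return env, seq, spec


@pytest.fixture(scope="session")
def cohort_components(cohort):
    """Per-subject ICA components matched to the planted networks."""
    env, seq, spec = cohort
    envn = normalize_envelopes(env)
    W = env.metadata["planted_weights"]
    templates = {f"net{j}": W[j] for j in range(W.shape[0])}
    per_subject = []
    for s in range(env.n_subjects):
        sub = EnvelopeArray(values=envn.values[s:s + 1],
                            center_frequency=envn.center_frequency,
                            sampling_rate=envn.sampling_rate, normalized=True)
        comps = extract_components(sub, W.shape[0], seed=0)
        per_subject.append(match_components(comps, templates))
    return per_subject


@pytest.fixture(scope="session")
def small_graph():
    """Collapsed 42-node synthetic connectome used by the model tests."""
    return collapse_subcortex(generate_connectome(ConnectomeSpec(n_cortical=40)))


@pytest.fixture(scope="session")
def raw_graph():
    return generate_connectome(ConnectomeSpec(n_cortical=40))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
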