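"""Synthetic inputs with the statistical structure the analyses assume.

Two generators:

* envelope cohorts — band-limited amplitude envelopes with planted spatial
  networks whose activations are modulated by a hidden Markov state
  sequence, so ICA recovery, state clustering and the behavioural
  regressions can all be tested against known ground truth;
* connectomes — weighted connectivity and distance matrices over two
  hemispheric shells of cortical nodes plus seven subcortical regions per
  hemisphere, with distance-decaying weights and subcortical hubs, feeding
  the collapsing rules and the dual-layer simulator.

Ground truth is carried in metadata sidecars and never consumed by pipeline
stages. All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .connectome import SUBCORTICAL_REGIONS, StructuralGraph
from .spectral import EnvelopeArray
from .states import StateSequence

__all__ = [
    "EnvelopeSpec",
    "ConnectomeSpec",
    "default_planted_networks",
    "generate_state_sequence",
    "generate_envelopes",
    "generate_cohort",
    "generate_connectome",
    "write_envelopes",
    "read_envelopes",
]


def default_planted_networks(n_parcels: int = 200, K: int = 4,
                             seed: int = 0) -> list[np.ndarray]:
    """K unit-norm nonnegative spatial networks on disjoint parcel blocks.

    Weights within each block are smooth random profiles, loosely emulating
    posterior/dorsal theta/alpha topographies without claiming anatomy.
    """
    rng = np.random.default_rng(seed)
    edges = np.linspace(0, n_parcels, K + 1).astype(int)
    nets = []
    for k in range(K):
        w = np.zeros(n_parcels)
        block = slice(edges[k], edges[k + 1])
        profile = gaussian_filter1d(rng.random(edges[k + 1] - edges[k]) + 0.3, 2.0)
        w[block] = profile
        nets.append(w / np.linalg.norm(w))
    return nets


@dataclass
class EnvelopeSpec:
    """Conditions for a synthetic envelope cohort.

    sampling_rate defaults to five samples per carrier cycle, matching the
    post-filtering rate of the real pipeline. state_gain multiplies the
    activation of the state's dominant network, so larger gains give better
    separated states.
    """

    n_subjects: int = 8
    n_trials: int = 20
    n_parcels: int = 200
    center_frequency: float = 10.0
    sampling_rate: float | None = None
    trial_duration: float = 2.5
    planted_networks: list[np.ndarray] | None = None
    state_transition_matrix: np.ndarray | None = None
    state_gain: float = 3.0
    noise_sd: float = 0.1
    activation_smoothness: float = 3.0   # samples, low-pass scale of activations
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate is None:
            self.sampling_rate = 5 * self.center_frequency
        if self.planted_networks is None:
            self.planted_networks = default_planted_networks(
                self.n_parcels, 4, seed=self.seed)
        self.planted_networks = [np.asarray(w, dtype=float)
                                 for w in self.planted_networks]
        for w in self.planted_networks:
            if w.shape != (self.n_parcels,):
                raise ValueError("planted network length must equal n_parcels")
            if abs(np.linalg.norm(w) - 1) > 1e-8:
                raise ValueError("planted networks must have unit Euclidean norm")
        K = len(self.planted_networks)
        if self.state_transition_matrix is None:
            # sticky chain: stay with p=0.9, switch uniformly otherwise
            T = np.full((K, K), 0.1 / max(K - 1, 1))
            np.fill_diagonal(T, 0.9 if K > 1 else 1.0)
            self.state_transition_matrix = T
        self.state_transition_matrix = np.asarray(
            self.state_transition_matrix, dtype=float)
        T = self.state_transition_matrix
        if T.shape != (K, K):
            raise ValueError("transition matrix must be K x K with K = number "
                             "of planted networks")
        if np.any(T < 0) or np.any(np.abs(T.sum(axis=1) - 1) > 1e-12):
            raise ValueError("transition matrix rows must be nonnegative and "
                             "sum to 1")
        if self.state_gain <= 0:
            raise ValueError("state_gain must be positive")

    @property
    def K(self) -> int:
        return len(self.planted_networks)

    @property
    def n_timepoints(self) -> int:
        return int(round(self.trial_duration * self.sampling_rate))


def generate_state_sequence(spec: EnvelopeSpec, n_timepoints: int,
                            rng: np.random.Generator | None = None,
                            start: int | None = None) -> StateSequence:
    """Sample one Markov state sequence of labels in 1..K."""
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    T = spec.state_transition_matrix
    K = spec.K
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    labels = np.empty(n_timepoints, dtype=int)
    state = int(rng.integers(K)) if start is None else start - 1
    if not 0 <= state < K:
        raise ValueError("start state out of range")
    labels[0] = state + 1
    for t in range(1, n_timepoints):
        state = int(rng.choice(K, p=T[state]))
        labels[t] = state + 1
    return StateSequence(labels=labels[None, :], sampling_rate=spec.sampling_rate,
                         K=K)


def _activations(spec: EnvelopeSpec, labels: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Smooth positive activations, the dominant network boosted by state_gain.

    The baseline is lognormal (exponentiated smooth Gaussian noise):
    amplitude envelopes are positively skewed, and the heavy tail is what
    lets a spatial ICA separate the sources.
    """
    K, T = spec.K, labels.size
    base = gaussian_filter1d(rng.standard_normal((K, T)),
                             spec.activation_smoothness, axis=1)
    base = np.exp(0.8 * base / max(base.std(), 1e-12))
    boost = np.where(labels[None, :] == np.arange(1, K + 1)[:, None],
                     spec.state_gain, 1.0)
    return base * boost


def generate_envelopes(spec: EnvelopeSpec,
                       states: StateSequence) -> EnvelopeArray:
    """Envelopes from planted networks driven by a given state sequence.

    envelope(t, parcel) = sum_j activation_j(t) * weight_j(parcel) + noise,
    truncated at zero (amplitude envelopes are nonnegative). The state
    sequence may carry one row (shared by all subjects) or one per subject.
    Ground-truth weights, labels and activations go to ``metadata``.
    """
    if states.K != spec.K:
        raise ValueError("state sequence K does not match planted network count")
    T = states.n_times
    rng = np.random.default_rng(spec.seed)
    W = np.stack(spec.planted_networks)            # (K, parcels)
    vals = np.empty((spec.n_subjects, spec.n_trials, spec.n_parcels, T))
    acts = np.empty((spec.n_subjects, spec.n_trials, spec.K, T))
    for s in range(spec.n_subjects):
        lab = states.labels[s % states.n_subjects]
        for r in range(spec.n_trials):
            A = _activations(spec, lab, rng)       # (K, T)
            clean = A.T @ W                        # (T, parcels)
            noisy = clean + spec.noise_sd * rng.standard_normal(clean.shape)
            vals[s, r] = np.clip(noisy, 0, None).T
            acts[s, r] = A
    return EnvelopeArray(
        values=vals, center_frequency=spec.center_frequency,
        sampling_rate=spec.sampling_rate, edge_trimmed=True,
        metadata={"planted_weights": W, "state_labels": states.labels,
                  "activations": acts})


def generate_cohort(spec: EnvelopeSpec) -> tuple[EnvelopeArray, StateSequence]:
    """One state sequence per subject plus the matching envelope cohort."""
    rng = np.random.default_rng(spec.seed)
    T = spec.n_timepoints
    labels = np.stack([
        generate_state_sequence(spec, T, rng=rng).labels[0]
        for _ in range(spec.n_subjects)
    ])
    seq = StateSequence(labels=labels, sampling_rate=spec.sampling_rate, K=spec.K)
    env = generate_envelopes(spec, seq)
    return env, seq


@dataclass
class ConnectomeSpec:
    """Conditions for a synthetic structural connectome.

    Cortical nodes sit on two hemispheric spherical shells (radius in mm);
    connection strength decays as exp(-distance_decay * D) with lognormal
    jitter, and subcortical hubs fan out with ``hub_strength`` times the
    cortical weight scale. Posterior and dorsal masks are carved from the
    node coordinates (most posterior / most superior cortical nodes).
    """

    n_cortical: int = 200
    n_subcortical_per_hemisphere: int = 7
    shell_radius: float = 75.0          # mm
    hemisphere_gap: float = 6.0          # mm between the two shells
    distance_decay: float = 0.04         # 1/mm; streamline counts are short-range dominated
    hub_strength: float = 3.0
    module_strength: float = 3.0         # within-mask structural boost
    weight_jitter: float = 0.5           # sd of lognormal jitter
    mask_fraction: float = 0.2           # fraction of cortical nodes per mask
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cortical < 8 or self.n_cortical % 2:
            raise ValueError("n_cortical must be even and >= 8")
        if self.n_subcortical_per_hemisphere != len(SUBCORTICAL_REGIONS):
            raise ValueError(
                f"expected {len(SUBCORTICAL_REGIONS)} subcortical regions per "
                "hemisphere")
        if self.distance_decay < 0 or self.hub_strength <= 0:
            raise ValueError("invalid decay or hub strength")


def _shell_points(n: int, radius: float, x_sign: int,
                  gap: float, rng: np.random.Generator) -> np.ndarray:
    """Random points on one hemispheric shell (x_sign picks the hemisphere)."""
    pts = rng.standard_normal((n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts[:, 0] = x_sign * np.abs(pts[:, 0])
    pts *= radius
    pts[:, 0] += x_sign * gap / 2
    return pts


def generate_connectome(spec: ConnectomeSpec) -> StructuralGraph:
    """Raw (uncollapsed) synthetic structural graph with 2 x 7 subcortical nodes."""
    rng = np.random.default_rng(spec.seed)
    half = spec.n_cortical // 2
    coords = []
    names, hemis, roles = [], [], []
    for sign, hemi in ((-1, "lh"), (1, "rh")):
        pts = _shell_points(half, spec.shell_radius, sign,
                            spec.hemisphere_gap, rng)
        coords.append(pts)
        names += [f"ctx_{hemi}_{i:03d}" for i in range(half)]
        hemis += [hemi] * half
        roles += ["cortical"] * half
    for sign, hemi in ((-1, "lh"), (1, "rh")):
        # subcortical cluster near the midline, slightly below center
        base = np.array([sign * (spec.hemisphere_gap / 2 + 12.0), 0.0, -15.0])
        pts = base + 6.0 * rng.standard_normal(
            (spec.n_subcortical_per_hemisphere, 3))
        coords.append(pts)
        names += [f"{r}_{hemi}" for r in SUBCORTICAL_REGIONS]
        hemis += [hemi] * spec.n_subcortical_per_hemisphere
        roles += ["subcortical"] * spec.n_subcortical_per_hemisphere
    xyz = np.vstack(coords)
    n = xyz.shape[0]

    D = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
    off = ~np.eye(n, dtype=bool)
    D[off] = np.maximum(D[off], 1.0)   # floor: distinct regions are > 0 mm apart

    jitter = np.exp(spec.weight_jitter * rng.standard_normal((n, n)))
    jitter = np.sqrt(jitter * jitter.T)               # symmetric jitter
    C = np.exp(-spec.distance_decay * D) * jitter
    hub = np.ones(n)
    sub = np.array([r != "cortical" for r in roles])
    hub[sub] = spec.hub_strength
    C *= np.sqrt(np.outer(hub, hub))                  # symmetric hub fan-out
    np.fill_diagonal(C, 0.0)
    np.fill_diagonal(D, 0.0)

    cort_xyz = xyz[:spec.n_cortical]
    n_mask = max(2, int(spec.mask_fraction * spec.n_cortical))
    posterior = np.sort(np.argsort(cort_xyz[:, 1])[:n_mask])     # most posterior (low y)
    rest = np.setdiff1d(np.arange(spec.n_cortical), posterior)
    dorsal = np.sort(rest[np.argsort(cort_xyz[rest, 2])[::-1][:n_mask]])  # most superior

    # functional networks ride on structural modules: boost within-mask edges
    for idx in (posterior, dorsal):
        C[np.ix_(idx, idx)] *= spec.module_strength
    np.fill_diagonal(C, 0.0)

    nodes = pd.DataFrame({"name": names, "hemisphere": hemis, "role": roles,
                          "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2]})
    return StructuralGraph(C=C, D=D, nodes=nodes,
                           masks={"posterior": posterior, "dorsal": dorsal})


def write_envelopes(env: EnvelopeArray, prefix: str | Path) -> None:
    """Binary array container (.npy) plus a JSON sidecar with dims and truth."""
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), env.values)
    sidecar = {
        "shape": list(env.values.shape),
        "center_frequency": env.center_frequency,
        "sampling_rate": env.sampling_rate,
        "edge_trimmed": env.edge_trimmed,
        "normalized": env.normalized,
        "metadata": {k: np.asarray(v).tolist() for k, v in env.metadata.items()},
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def read_envelopes(prefix: str | Path) -> EnvelopeArray:
    prefix = Path(prefix)
    values = np.load(prefix.with_suffix(".npy"))
    side = json.loads(prefix.with_suffix(".json").read_text())
    return EnvelopeArray(
        values=values, center_frequency=side["center_frequency"],
        sampling_rate=side["sampling_rate"], edge_trimmed=side["edge_trimmed"],
        normalized=side["normalized"],
        metadata={k: np.asarray(v) for k, v in side["metadata"].items()})
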