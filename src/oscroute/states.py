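"""Brain states: k-means over network activations and the derived statistics.

Each timepoint carries one activation value per network component; k-means
(Euclidean, default K=4) classifies every timepoint into a state, and states
are relabelled so that state j is the one whose centroid is maximal in
component j (state 1 = posterior theta, 2 = posterior alpha, 3 = dorsal
alpha, 4 = dorsal theta in the canonical ordering). On top of the labelled
sequences this module computes occupancy curves, switch counts, time-in-state,
the load and switch-performance regressions, the PC1 performance composite,
and the distractor contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .stats import EffectReport, OLSReport, paired_t, standardized_ols

__all__ = [
    "StateModel",
    "StateSequence",
    "cluster_states",
    "state_occupancy",
    "count_state_switches",
    "time_in_state",
    "load_regression",
    "switch_performance_regression",
    "pc1_performance",
    "distractor_contrast",
]


@dataclass
class StateModel:
    """K-means centroids over component activations, relabelled by dominance."""

    centroids: np.ndarray  # (K, n_components), row j dominates component j
    K: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.K < 1 or self.centroids.shape[0] != self.K:
            raise ValueError("centroid count must equal K >= 1")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")


@dataclass
class StateSequence:
    """State labels in 1..K per (subject, timepoint)."""

    labels: np.ndarray
    sampling_rate: float
    K: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.atleast_2d(np.asarray(self.labels, dtype=int))
        if self.labels.ndim != 2:
            raise ValueError("labels must be (subjects, time)")
        if self.labels.min(initial=1) < 1:
            raise ValueError("state labels start at 1")
        if self.K is None:
            self.K = int(self.labels.max())

    @property
    def n_subjects(self) -> int:
        return self.labels.shape[0]

    @property
    def n_times(self) -> int:
        return self.labels.shape[1]

    def window_slice(self, window: tuple[float, float] | None) -> slice:
        if window is None:
            return slice(0, self.n_times)
        t0, t1 = window
        i0 = int(round(t0 * self.sampling_rate))
        i1 = int(round(t1 * self.sampling_rate))
        if not (0 <= i0 < i1 <= self.n_times):
            raise ValueError(f"window {window} outside the sequence")
        return slice(i0, i1)


def _dominance_relabel(centroids: np.ndarray) -> np.ndarray:
    """Permutation old-state -> new-state so that new state j peaks at component j.

    Greedy on centroid values; falls back gracefully (with a warning) when
    argmax assignments collide.
    """
    K, n_comp = centroids.shape
    order = np.argsort(centroids, axis=None)[::-1]
    state_of_comp = {}
    used_states: set[int] = set()
    for flat in order:
        k, j = divmod(int(flat), n_comp)
        if j in state_of_comp or k in used_states or j >= K:
            continue
        state_of_comp[j] = k
        used_states.add(k)
    if len(state_of_comp) < K:
        warnings.warn("could not assign a unique dominant component to every "
                      "state; remaining states labelled arbitrarily", stacklevel=3)
        leftover_k = [k for k in range(K) if k not in used_states]
        leftover_j = [j for j in range(K) if j not in state_of_comp]
        for j, k in zip(leftover_j, leftover_k):
            state_of_comp[j] = k
    perm = np.empty(K, dtype=int)
    for j, k in state_of_comp.items():
        perm[k] = j  # old cluster k becomes state j+1
    return perm


def cluster_states(timecourses: np.ndarray, K: int = 4, seed: int | None = 0,
                   n_init: int = 50) -> tuple[StateModel, StateSequence]:
    """K-means clustering of component activations into brain states.

    timecourses: (n_subjects, n_times, n_components) or (n_times,
    n_components); all subjects are pooled for fitting, every timepoint is
    labelled. sampling_rate on the returned sequence defaults to 1 and
    should be overwritten by the caller if windows in seconds are needed.
    """
    tc = np.asarray(timecourses, dtype=float)
    if tc.ndim == 2:
        tc = tc[None]
    n_subj, n_times, n_comp = tc.shape
    flat = tc.reshape(-1, n_comp)
    if K > np.unique(flat, axis=0).shape[0]:
        raise ValueError("K exceeds the number of distinct points")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
    raw = km.fit_predict(flat)
    perm = _dominance_relabel(km.cluster_centers_)
    labels = perm[raw] + 1
    centroids = km.cluster_centers_[np.argsort(perm)]
    model = StateModel(centroids=centroids, K=K, seed=seed)
    seq = StateSequence(labels=labels.reshape(n_subj, n_times),
                        sampling_rate=1.0, K=K)
    return model, seq


def state_occupancy(seq: StateSequence) -> np.ndarray:
    """Fraction of subjects in each state at each timepoint, shape (K, T)."""
    K = seq.K
    occ = np.stack([(seq.labels == k + 1).mean(axis=0) for k in range(K)])
    return occ


def count_state_switches(seq: StateSequence,
                         window: tuple[float, float] | None = None) -> np.ndarray:
    """Number of consecutive-timepoint label changes per subject."""
    sl = seq.window_slice(window)
    if sl.stop - sl.start < 1:
        raise ValueError("empty window")
    lab = seq.labels[:, sl]
    return (np.diff(lab, axis=1) != 0).sum(axis=1)


def time_in_state(seq: StateSequence, state: int,
                  window: tuple[float, float] | None = None,
                  fraction: bool = False) -> np.ndarray:
    """Total time (s) each subject spends in ``state`` within the window."""
    if not 1 <= state <= seq.K:
        raise ValueError(f"unknown state id {state} (K={seq.K})")
    sl = seq.window_slice(window)
    lab = seq.labels[:, sl]
    counts = (lab == state).sum(axis=1)
    if fraction:
        return counts / lab.shape[1]
    return counts / seq.sampling_rate


def load_regression(times: np.ndarray, load: np.ndarray,
                    form: str = "linear") -> dict:
    """Regress mean time-in-state on working-memory load.

    Returns standardized coefficients (OLS on z-scored variables) plus, for
    the quadratic form, the fitted vertex in raw load units.
    """
    times = np.asarray(times, dtype=float).ravel()
    load = np.asarray(load, dtype=float).ravel()
    if form not in {"linear", "quadratic"}:
        raise ValueError("form must be 'linear' or 'quadratic'")
    if form == "quadratic" and np.unique(load).size < 3:
        raise ValueError("quadratic form needs >= 3 distinct load levels")
    if form == "linear":
        rep = standardized_ols(times, load[:, None], names=["load"])
        return {"report": rep, "form": form}
    X = np.column_stack([load, load ** 2])
    rep = standardized_ols(times, X, names=["load", "load_sq"])
    b2, b1, _ = np.polyfit(load, times, 2)
    vertex = -b1 / (2 * b2) if b2 != 0 else np.nan
    return {"report": rep, "form": form, "vertex": float(vertex)}


def switch_performance_regression(switches: np.ndarray,
                                  outcome: np.ndarray) -> dict:
    """Quadratic OLS of a performance outcome on switch counts.

    The optimum switch count is the vertex of the raw-unit parabola,
    ``-b1 / (2 b2)``.
    """
    x = np.asarray(switches, dtype=float).ravel()
    y = np.asarray(outcome, dtype=float).ravel()
    if x.size < 3 or np.unique(x).size < 3:
        raise ValueError("need >= 3 subjects with >= 3 distinct switch counts")
    X = np.column_stack([x, x ** 2])
    rep = standardized_ols(y, X, names=["switches", "switches_sq"])
    b2, b1, _ = np.polyfit(x, y, 2)
    vertex = -b1 / (2 * b2) if b2 != 0 else np.nan
    return {"report": rep, "optimal_switches": float(vertex)}


def pc1_performance(scores: np.ndarray) -> dict:
    """First principal component of a subjects x tests score table.

    Scores are z-scored per test; PC1's sign is fixed so it correlates
    positively with the mean test score, making higher PC1 = better overall
    performance when the tests are scored in the same direction.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[1] < 2 or S.shape[0] < 3:
        raise ValueError("need >= 3 subjects and >= 2 tests")
    sd = S.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("a test column is constant")
    Z = (S - S.mean(axis=0)) / sd
    pca = PCA(n_components=min(Z.shape))
    comp_scores = pca.fit_transform(Z)
    pc1 = comp_scores[:, 0]
    loadings = pca.components_[0]
    mean_score = Z.mean(axis=1)
    if np.corrcoef(pc1, mean_score)[0, 1] < 0:
        pc1, loadings = -pc1, -loadings
    return {"pc1": pc1, "loadings": loadings,
            "explained_variance_ratio": float(pca.explained_variance_ratio_[0])}


def distractor_contrast(seq_distractor: StateSequence,
                        seq_control: StateSequence,
                        windows: list[tuple[float, float]],
                        expected_direction: list[int],
                        state: int = 1) -> tuple[EffectReport, np.ndarray]:
    """Signed time-in-state difference between distractor and control trials.

    For each subject and stimulus window, the difference
    (distractor - control) in time spent in ``state`` is multiplied by the
    expected direction (+1 where the effect should raise time-in-state under
    distractors, -1 where it should lower it), so that effects in the
    predicted direction are positive. Subject scores are the mean over
    windows; a one-sided paired t-test asks whether the mean exceeds zero.
    Returns the effect report and the per-subject signed differences in
    seconds.
    """
    if seq_distractor.n_subjects != seq_control.n_subjects:
        raise ValueError("conditions must cover the same subjects")
    if len(windows) != len(expected_direction):
        raise ValueError("one expected direction per window")
    if any(s not in (-1, 1) for s in expected_direction):
        raise ValueError("expected_direction entries must be +1 or -1")
    diffs = []
    for win, sign in zip(windows, expected_direction):
        td = time_in_state(seq_distractor, state, win)
        tc = time_in_state(seq_control, state, win)
        diffs.append(sign * (td - tc))
    per_subject = np.mean(diffs, axis=0)
    report = paired_t(per_subject, sidedness="one")
    return report, per_subject
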