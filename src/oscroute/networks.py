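"""Spatial network extraction by ICA and network-similarity reliability.

Within each subject and frequency band, ICA on normalized envelope data
separates 2-5 independent spatial components. A component is a weight vector
over the 200 parcels (rows of the linear ICA operator; larger weight = the
parcel contributes more to the signal) plus its activation time course.
Components are compared by cosine similarity, matched to canonical
templates (posterior/dorsal networks), and reliability is quantified as the
similarity of the same network type across sessions, tasks or subjects
while holding the other two factors fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import FastICA

from .spectral import EnvelopeArray
from .stats import paired_t

__all__ = [
    "NetworkComponent",
    "extract_components",
    "average_timecourses",
    "cosine_similarity",
    "match_components",
    "reliability_analysis",
]


@dataclass
class NetworkComponent:
    weights: np.ndarray           # (n_parcels,), sign-fixed positive-dominant
    timecourse: np.ndarray        # (n_trials, n_times) activation
    frequency_band: str = ""
    label: str = "other"          # posterior / dorsal / other
    sign_convention: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.any(self.weights):
            raise ValueError("weight vector must be non-zero")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (|u||v|): 1 for aligned, 0 for orthogonal, -1 opposed."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


def extract_components(env: EnvelopeArray, n_components: int,
                       seed: int | None = 0, n_restarts: int = 20,
                       max_iter: int = 2000) -> list[NetworkComponent]:
    """FastICA decomposition of envelopes into spatial network components.

    Samples are (trial, time) points, features are parcels; the unmixing
    rows are the spatial weight vectors. Each component is sign-flipped to
    positive-dominant (weight sum >= 0) and the list is ordered by
    descending back-projected variance. Of ``n_restarts`` seeded runs the
    one with the highest negentropy objective is kept.
    """
    if not 2 <= n_components <= 5:
        raise ValueError("n_components must be between 2 and 5")
    if n_components > env.n_parcels:
        raise ValueError("more components than parcels")
    if not env.normalized:
        raise ValueError("envelopes must be normalized before ICA")
    if env.n_subjects != 1:
        raise ValueError("extract_components works per subject; pass one subject")
    X = env.values[0].transpose(0, 2, 1).reshape(-1, env.n_parcels)

    rng = np.random.default_rng(seed)
    best: FastICA | None = None
    best_obj = -np.inf
    last_err: Exception | None = None
    for _ in range(n_restarts):
        ica = FastICA(n_components=n_components, max_iter=max_iter,
                      random_state=int(rng.integers(2**31 - 1)), whiten="unit-variance")
        try:
            S = ica.fit_transform(X)
        except Exception as err:  # pragma: no cover - convergence pathologies
            last_err = err
            continue
        if ica.n_iter_ >= max_iter:
            continue
        # negentropy surrogate: mean (E[logcosh(s)] - gaussian baseline)^2
        obj = float(np.sum((np.mean(np.log(np.cosh(S)), axis=0) - 0.374567) ** 2))
        if obj > best_obj:
            best_obj, best = obj, ica
    if best is None:
        raise RuntimeError(
            f"FastICA failed to converge in {n_restarts} restarts "
            f"(max_iter={max_iter}); last error: {last_err}")

    S = best.transform(X)                       # (samples, comps)
    W = best.components_                        # (comps, parcels) unmixing
    mixing = best.mixing_                       # (parcels, comps)
    comps = []
    for j in range(n_components):
        w = W[j].copy()
        s = S[:, j].copy()
        if w.sum() < 0:
            w, s = -w, -s
        ev = float(np.var(s) * np.sum(mixing[:, j] ** 2))
        tc = s.reshape(env.n_trials, -1)
        comps.append(NetworkComponent(weights=w, timecourse=tc,
                                      meta={"explained_variance": ev}))
    comps.sort(key=lambda c: c.meta["explained_variance"], reverse=True)
    return comps


def average_timecourses(comp: NetworkComponent,
                        trial_groups: np.ndarray | None = None) -> np.ndarray:
    """Trial-mean activation time course, one row per group.

    ``trial_groups`` labels each trial (e.g. by session/task); None averages
    all trials together.
    """
    tc = comp.timecourse
    if trial_groups is None:
        return tc.mean(axis=0, keepdims=True)
    trial_groups = np.asarray(trial_groups)
    if trial_groups.shape[0] != tc.shape[0]:
        raise ValueError("one group label per trial required")
    out = []
    for g in np.unique(trial_groups):
        rows = tc[trial_groups == g]
        if rows.size == 0:
            raise ValueError(f"empty trial group {g!r}")
        out.append(rows.mean(axis=0))
    return np.stack(out)


def match_components(comps: list[NetworkComponent],
                     templates: dict[str, np.ndarray],
                     threshold: float = 0.3) -> dict[str, NetworkComponent | None]:
    """Greedy one-to-one assignment of components to template networks.

    Pairs are ranked by |cosine| to the templates; assignments below
    ``threshold`` are declared unidentifiable (None), mirroring that not
    every network is identifiable in every data partition.
    """
    pairs = []
    for name, tmpl in templates.items():
        for i, c in enumerate(comps):
            pairs.append((abs(cosine_similarity(c.weights, tmpl)), name, i))
    pairs.sort(reverse=True)
    assigned: dict[str, NetworkComponent | None] = {n: None for n in templates}
    used: set[int] = set()
    for score, name, i in pairs:
        if assigned[name] is not None or i in used or score < threshold:
            continue
        comp = comps[i]
        comp.label = name
        assigned[name] = comp
        used.add(i)
    return assigned


def reliability_analysis(components: pd.DataFrame, axis: str) -> dict:
    """Network similarity along one factor, holding the other two fixed.

    ``components`` is a tidy table with columns subject, session, task,
    network and a ``weights`` column holding the weight vectors. For
    ``axis='session'`` all pairs of rows sharing (subject, task, network)
    but differing in session contribute a cosine similarity, and so on. A
    one-sided one-sample t-test asks whether the mean similarity exceeds
    zero.
    """
    factors = {"session", "task", "subject"}
    if axis not in factors:
        raise ValueError(f"axis must be one of {sorted(factors)}")
    held = sorted(factors - {axis}) + ["network"]
    sims = []
    rows = []
    for key, grp in components.groupby(held):
        ws = list(grp["weights"])
        for a, b in combinations(range(len(ws)), 2):
            s = cosine_similarity(ws[a], ws[b])
            sims.append(s)
            rows.append({"network": key[-1], "axis": axis, "similarity": s})
    if len(sims) < 2:
        raise ValueError(f"fewer than 2 comparable pairs along axis {axis!r}")
    sims = np.asarray(sims)
    if sims.std(ddof=1) == 0:
        # perfectly reproducible components: the one-sample t degenerates
        t_val = np.inf if sims.mean() > 0 else (-np.inf if sims.mean() < 0 else 0.0)
        report = type("Degenerate", (), {"t": t_val, "df": sims.size - 1,
                                         "p": 0.0 if sims.mean() > 0 else 1.0})
    else:
        report = paired_t(sims, sidedness="one")
    return {
        "axis": axis,
        "mean": float(sims.mean()),
        "median": float(np.median(sims)),
        "sd": float(sims.std(ddof=1)),
        "n_pairs": int(sims.size),
        "t": report.t,
        "df": report.df,
        "p": report.p,
        "pairs": pd.DataFrame(rows),
    }
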