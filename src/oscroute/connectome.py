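"""Structural graphs for the whole-brain model.

A :class:`StructuralGraph` holds a weighted connectivity matrix ``C`` (row
``n``, column ``p`` is the incoming strength from node ``p`` to node ``n``,
in streamline-count-like units), a distance matrix ``D`` in mm, and node
metadata (name, hemisphere, role) plus named cortical masks (e.g. the
posterior and dorsal networks).

The model graph has 200 cortical nodes plus one basal-ganglia-thalamus node
per hemisphere, obtained from a raw graph with 7 subcortical regions per
hemisphere by dropping amygdala/hippocampus and summing the remaining five
into a single node (:func:`collapse_subcortex`). Conduction delays are
proportional to distance; with the integrator timestep of 0.1 ms the default
convention is ``tau_steps = round(2 * D_mm)``, i.e. 0.2 ms of delay per mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StructuralGraph",
    "SUBCORTICAL_REGIONS",
    "DROPPED_REGIONS",
    "collapse_subcortex",
    "normalize_incoming",
    "delays_from_distance",
    "write_graph",
    "read_graph",
]

#: the 7 subcortical regions expected per hemisphere in a raw graph
SUBCORTICAL_REGIONS = (
    "accumbens", "amygdala", "caudate", "pallidum",
    "putamen", "thalamus", "hippocampus",
)
#: regions removed before collapsing (limbic, not part of the BG-thalamus loop)
DROPPED_REGIONS = ("amygdala", "hippocampus")


@dataclass
class StructuralGraph:
    """Weighted connectivity + distances + node metadata.

    nodes is a DataFrame with columns ``name``, ``hemisphere`` and ``role``
    (``cortical`` or ``subcortical`` raw; ``bg_thalamus`` after collapsing).
    masks maps mask names to integer node-index arrays.
    """

    C: np.ndarray
    D: np.ndarray
    nodes: pd.DataFrame
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        n = self.C.shape[0]
        if self.C.shape != (n, n) or self.D.shape != (n, n):
            raise ValueError("C and D must be square and the same shape")
        if len(self.nodes) != n:
            raise ValueError("node table length does not match matrix size")
        if np.any(self.C < 0):
            raise ValueError("connectivity weights must be nonnegative")
        if np.any(self.D[~np.eye(n, dtype=bool)] < 0):
            raise ValueError("distances must be nonnegative")
        self.masks = {k: np.asarray(v, dtype=int) for k, v in self.masks.items()}

    @property
    def n_nodes(self) -> int:
        return self.C.shape[0]

    def indices(self, role: str) -> np.ndarray:
        return np.flatnonzero((self.nodes["role"] == role).to_numpy())

    @property
    def cortical(self) -> np.ndarray:
        return self.indices("cortical")

    @property
    def subcortical(self) -> np.ndarray:
        return np.flatnonzero((self.nodes["role"] != "cortical").to_numpy())


def collapse_subcortex(raw: StructuralGraph) -> StructuralGraph:
    """Collapse the 14 subcortical nodes into one BG-thalamus node per hemisphere.

    Amygdala and hippocampus are dropped. The remaining five regions per
    hemisphere are summed into a single node: connection weights add;
    distances to the new node are the strength-weighted average over the
    constituents (falling back to the plain average where all weights are
    zero). Cortico-cortical entries are untouched. The collapsed node's role
    is ``bg_thalamus``: functionally its incoming connections are
    basal-ganglia afferents and its outgoing connections thalamic efferents.
    """
    names = raw.nodes["name"].str.lower()
    roles = raw.nodes["role"]
    keep_cortical = np.flatnonzero((roles == "cortical").to_numpy())
    new_order: list[np.ndarray] = [keep_cortical]
    groups: list[np.ndarray] = []
    for hemi in ("lh", "rh"):
        hemi_mask = (raw.nodes["hemisphere"] == hemi) & (roles != "cortical")
        sub_idx = np.flatnonzero(hemi_mask.to_numpy())
        present = {r for r in SUBCORTICAL_REGIONS
                   if any(r in names.iloc[i] for i in sub_idx)}
        missing = set(SUBCORTICAL_REGIONS) - present
        if missing:
            raise ValueError(
                f"hemisphere {hemi} is missing subcortical regions: {sorted(missing)}")
        keep = [i for i in sub_idx
                if not any(d in names.iloc[i] for d in DROPPED_REGIONS)]
        groups.append(np.asarray(keep, dtype=int))

    n_cort = keep_cortical.size
    n_new = n_cort + 2
    C = np.zeros((n_new, n_new))
    D = np.zeros((n_new, n_new))
    C[:n_cort, :n_cort] = raw.C[np.ix_(keep_cortical, keep_cortical)]
    D[:n_cort, :n_cort] = raw.D[np.ix_(keep_cortical, keep_cortical)]

    for gi, grp in enumerate(groups):
        j = n_cort + gi
        # incoming to collapsed node from cortical nodes, and outgoing
        c_in = raw.C[np.ix_(grp, keep_cortical)].sum(axis=0)
        c_out = raw.C[np.ix_(keep_cortical, grp)].sum(axis=1)
        C[j, :n_cort] = c_in
        C[:n_cort, j] = c_out
        w_in = raw.C[np.ix_(grp, keep_cortical)]
        d_in = raw.D[np.ix_(grp, keep_cortical)]
        D[j, :n_cort] = _weighted_mean(d_in, w_in, axis=0)
        D[:n_cort, j] = D[j, :n_cort]
    # between the two collapsed nodes
    g0, g1 = groups
    C[n_cort, n_cort + 1] = raw.C[np.ix_(g0, g1)].sum()
    C[n_cort + 1, n_cort] = raw.C[np.ix_(g1, g0)].sum()
    w01 = raw.C[np.ix_(g0, g1)]
    d01 = raw.D[np.ix_(g0, g1)]
    d_mean = float(np.average(d01, weights=w01) if w01.sum() > 0 else d01.mean())
    D[n_cort, n_cort + 1] = D[n_cort + 1, n_cort] = d_mean

    nodes = pd.concat(
        [
            raw.nodes.iloc[keep_cortical].reset_index(drop=True),
            pd.DataFrame(
                {"name": ["bg_thalamus_lh", "bg_thalamus_rh"],
                 "hemisphere": ["lh", "rh"],
                 "role": ["bg_thalamus", "bg_thalamus"]}
            ),
        ],
        ignore_index=True,
    )
    old_to_new = {int(o): i for i, o in enumerate(keep_cortical)}
    masks = {
        k: np.asarray([old_to_new[int(i)] for i in v if int(i) in old_to_new], dtype=int)
        for k, v in raw.masks.items()
    }
    return StructuralGraph(C=C, D=D, nodes=nodes, masks=masks)


def _weighted_mean(d: np.ndarray, w: np.ndarray, axis: int) -> np.ndarray:
    wsum = w.sum(axis=axis)
    out = np.where(wsum > 0, (d * w).sum(axis=axis) / np.where(wsum > 0, wsum, 1.0),
                   d.mean(axis=axis))
    return out


def normalize_incoming(g: StructuralGraph) -> StructuralGraph:
    """Scale each row of C so the incoming weights to every node sum to one."""
    C = g.C.copy()
    np.fill_diagonal(C, 0.0)
    row_sums = C.sum(axis=1)
    bad = np.flatnonzero(row_sums <= 0)
    if bad.size:
        names = g.nodes["name"].iloc[bad].tolist()
        raise ValueError(f"isolated nodes with no incoming weight: {names}")
    return replace(g, C=C / row_sums[:, None])


def delays_from_distance(g: StructuralGraph, factor: float = 2.0,
                         dt_ms: float = 0.1) -> tuple[np.ndarray, float]:
    """Delay matrix tau in integration steps, plus the mean delay in ms.

    ``tau = round(factor * D)`` interpreted in steps of ``dt_ms``; with the
    defaults (factor 2 steps/mm, dt 0.1 ms) a 115 mm connection carries a
    23 ms delay. The returned scalar is the mean delay in ms over distinct
    node pairs — the average time a signal takes to travel from one node to
    another — for calibration checks.
    """
    if factor <= 0:
        raise ValueError("delay factor must be positive")
    if np.any(g.D < 0):
        raise ValueError("negative distances")
    tau = np.rint(factor * g.D).astype(np.int64)
    off = ~np.eye(g.n_nodes, dtype=bool)
    mean_ms = float(np.mean(tau[off] * dt_ms))
    return tau, mean_ms


def write_graph(g: StructuralGraph, prefix: str | Path) -> None:
    """Write C/D as tab-separated square tables plus a node-metadata table."""
    prefix = Path(prefix)
    names = g.nodes["name"].tolist()
    pd.DataFrame(g.C, index=names, columns=names).to_csv(
        prefix.with_suffix(".connectivity.tsv"), sep="\t")
    pd.DataFrame(g.D, index=names, columns=names).to_csv(
        prefix.with_suffix(".distance.tsv"), sep="\t")
    meta = g.nodes.copy()
    for mask, idx in g.masks.items():
        col = np.zeros(len(meta), dtype=bool)
        col[idx] = True
        meta[f"mask_{mask}"] = col
    meta.to_csv(prefix.with_suffix(".nodes.tsv"), sep="\t", index=False)


def read_graph(prefix: str | Path) -> StructuralGraph:
    prefix = Path(prefix)
    C = pd.read_csv(prefix.with_suffix(".connectivity.tsv"), sep="\t", index_col=0)
    D = pd.read_csv(prefix.with_suffix(".distance.tsv"), sep="\t", index_col=0)
    meta = pd.read_csv(prefix.with_suffix(".nodes.tsv"), sep="\t")
    masks = {c[len("mask_"):]: np.flatnonzero(meta[c].to_numpy())
             for c in meta.columns if c.startswith("mask_")}
    nodes = meta[["name", "hemisphere", "role"]]
    return StructuralGraph(C=C.to_numpy(), D=D.to_numpy(), nodes=nodes, masks=masks)
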