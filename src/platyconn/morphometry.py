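"""Skeleton-level quantitative neuroanatomy.

Cable length is measured on *trimmed, unsmoothed* skeletons: terminal
twigs shorter than a threshold (default 2 µm) are pruned in a single pass
before summing Euclidean edge lengths. Sholl profiles are measured on
*smoothed, untrimmed* skeletons: smoothing is a Gaussian-weighted moving
average along each unbranched stretch (root, branch points and tips stay
anchored; implemented as Gaussian smoothing of chord residuals so that a
perfectly straight stretch is an exact fixed point). Radial synapse
density histograms the Euclidean soma-to-synapse distance in fixed-width
bins (default 1000 nm). All coordinates are nanometres; cable length is
reported in microns.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import CellClass, Connector, Dataset, Skeleton

NM_PER_UM = 1000.0


def _coords(sk: Skeleton) -> dict[int, np.ndarray]:
    return {
        nid: np.array([n.x, n.y, n.z], dtype=float)
        for nid, n in sk.nodes.items()
    }


def _edge_length(sk: Skeleton, a: int, b: int) -> float:
    na, nb = sk.nodes[a], sk.nodes[b]
    return float(
        np.linalg.norm(
            np.array([na.x - nb.x, na.y - nb.y, na.z - nb.z], dtype=float)
        )
    )


def cable_length(sk: Skeleton, prune_below_um: float = 2.0) -> float:
    """Total Euclidean cable length in µm after single-pass twig pruning.

    A twig is the path from a terminal tip up to (but excluding) the first
    branch point or the root; every twig shorter than ``prune_below_um``
    (measured on the original tree — no cascading) is removed before the
    edge lengths are summed.
    """
    if len(sk.nodes) <= 1:
        return 0.0
    children = sk.children_map()
    root = sk.root_id
    threshold_nm = prune_below_um * NM_PER_UM
    removed: set[int] = set()
    tips = [
        nid
        for nid, ch in children.items()
        if not ch and nid != root
    ]
    for tip in tips:
        path = [tip]
        length = 0.0
        cur = tip
        while True:
            parent = sk.nodes[cur].parent_id
            if parent is None or len(children[parent]) > 1:
                break
            length += _edge_length(sk, cur, parent)
            cur = parent
            path.append(cur)
        # include the edge connecting the twig to its branch point / root
        parent = sk.nodes[cur].parent_id
        if parent is not None:
            length += _edge_length(sk, cur, parent)
        if length < threshold_nm:
            removed.update(path)
    total = 0.0
    for parent, child in sk.edges():
        if parent.node_id in removed or child.node_id in removed:
            continue
        total += _edge_length(sk, parent.node_id, child.node_id)
    return total / NM_PER_UM


def _slabs(sk: Skeleton) -> Iterable[list[int]]:
    """Unbranched stretches between anchors (root / branch points / tips)."""
    children = sk.children_map()
    root = sk.root_id
    anchors = {root} | {
        nid for nid, ch in children.items() if len(ch) >= 2
    }
    for start in sorted(anchors):
        for child in sorted(children[start]):
            slab = [start, child]
            cur = child
            while cur not in anchors and len(children[cur]) == 1:
                cur = children[cur][0]
                slab.append(cur)
            yield slab


def smooth_skeleton(sk: Skeleton, sigma: float = 6000.0) -> Skeleton:
    """Gaussian smoothing of node coordinates along unbranched stretches.

    Interior nodes of each stretch are replaced by the chord-linear
    position plus a Gaussian-weighted (scale ``sigma`` nm, along
    arc-length) moving average of the chord residuals; stretch endpoints
    are anchored, topology, tags and radii are unchanged. ``sigma = 0`` is
    the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0 or len(sk.nodes) <= 2:
        return Skeleton(sk.skeleton_id, sk.cell_name, dict(sk.nodes))
    coords = _coords(sk)
    new_xyz = {nid: xyz.copy() for nid, xyz in coords.items()}
    for slab in _slabs(sk):
        if len(slab) < 3:
            continue
        pts = np.array([coords[nid] for nid in slab])
        seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seglen)])
        if s[-1] == 0:
            continue
        frac = s / s[-1]
        chord = pts[0] + np.outer(frac, pts[-1] - pts[0])
        resid = pts - chord
        smoothed = resid.copy()
        for i in range(1, len(slab) - 1):
            w = np.exp(-0.5 * ((s - s[i]) / sigma) ** 2)
            smoothed[i] = (w[:, None] * resid).sum(axis=0) / w.sum()
        out = chord + smoothed
        for i in range(1, len(slab) - 1):
            new_xyz[slab[i]] = out[i]
    nodes = {
        nid: replace(
            sk.nodes[nid],
            x=float(new_xyz[nid][0]),
            y=float(new_xyz[nid][1]),
            z=float(new_xyz[nid][2]),
        )
        for nid in sk.nodes
    }
    return Skeleton(sk.skeleton_id, sk.cell_name, nodes)


@dataclass
class ShollProfile:
    radii: np.ndarray  # nm, multiples of the step
    crossings: np.ndarray  # edges straddling each sphere

    def as_series(self) -> pd.Series:
        return pd.Series(self.crossings, index=self.radii)


def sholl(
    sk: Skeleton, step: float, max_radius: Optional[float] = None
) -> ShollProfile:
    """Count skeleton edges crossing concentric spheres centred on the root.

    An edge (parent-child segment) crosses the sphere of radius ``r`` when
    the endpoint nearer the root lies within r (inclusive) and the farther
    endpoint beyond it: ``min(d) <= r < max(d)`` with d the Euclidean
    node-to-root distances. The grid runs at step, 2*step, ... up to the
    maximal node distance (or ``max_radius``).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    coords = _coords(sk)
    root = coords[sk.root_id]
    dist = {nid: float(np.linalg.norm(xyz - root)) for nid, xyz in coords.items()}
    extent = max_radius if max_radius is not None else max(dist.values(), default=0.0)
    n_radii = int(np.ceil(extent / step)) if extent > 0 else 0
    radii = step * np.arange(1, n_radii + 1)
    crossings = np.zeros(n_radii, dtype=int)
    for parent, child in sk.edges():
        lo = min(dist[parent.node_id], dist[child.node_id])
        hi = max(dist[parent.node_id], dist[child.node_id])
        crossings += (lo <= radii) & (radii < hi)
    return ShollProfile(radii=radii, crossings=crossings)


@dataclass
class RadialDensityProfile:
    bin_edges: np.ndarray  # nm
    counts: np.ndarray
    density: np.ndarray  # counts normalised to sum to 1 (zeros if empty)


def radial_synapse_density(
    sk: Skeleton,
    connectors: Iterable[Connector],
    bin_nm: float = 1000.0,
    role: str = "pre",
    max_radius: Optional[float] = None,
) -> RadialDensityProfile:
    """Histogram of Euclidean soma-to-synapse distances, fixed-width bins."""
    if role not in ("pre", "post"):
        raise ValueError("role must be 'pre' or 'post'")
    soma_ids = [nid for nid, n in sk.nodes.items() if "soma" in n.tags]
    if not soma_ids:
        raise ValueError(f"no soma: skeleton {sk.skeleton_id} is a fragment")
    coords = _coords(sk)
    soma = coords[soma_ids[0]]
    dists = []
    for c in connectors:
        sid = c.pre_skeleton if role == "pre" else c.post_skeleton
        nid = c.pre_node if role == "pre" else c.post_node
        if sid == sk.skeleton_id:
            dists.append(float(np.linalg.norm(coords[nid] - soma)))
    extent = max_radius if max_radius is not None else (max(dists) if dists else bin_nm)
    n_bins = max(1, int(np.ceil(extent / bin_nm)))
    edges = bin_nm * np.arange(n_bins + 1)
    counts, _ = np.histogram(dists, bins=edges)
    total = counts.sum()
    density = counts / total if total else np.zeros_like(counts, dtype=float)
    return RadialDensityProfile(bin_edges=edges, counts=counts, density=density)


def mean_radial_profile(
    profiles: Sequence[RadialDensityProfile],
) -> RadialDensityProfile:
    """Average per-cell radial densities on a shared (zero-padded) grid."""
    if not profiles:
        raise ValueError("no profiles to average")
    bin_nm = profiles[0].bin_edges[1] - profiles[0].bin_edges[0]
    n = max(len(p.counts) for p in profiles)
    counts = np.zeros(n, dtype=float)
    density = np.zeros(n, dtype=float)
    for p in profiles:
        counts[: len(p.counts)] += p.counts
        density[: len(p.density)] += p.density
    return RadialDensityProfile(
        bin_edges=bin_nm * np.arange(n + 1),
        counts=counts / len(profiles),
        density=density / len(profiles),
    )


def polarity_table(ds: Dataset) -> pd.DataFrame:
    """Per-cell pre/post synapse counts and presynaptic fraction.

    ``pre_fraction`` = n_pre / (n_pre + n_post); cells with no synapses at
    all get NaN (undefined polarity). The ratio separates neuron classes:
    sensory neurons sit near 1, effectors at 0.
    """
    rows = {
        name: {"n_pre": 0, "n_post": 0, "cell_class": info.cell_class.value}
        for name, info in ds.cells.items()
    }
    for c in ds.connectors:
        rows[ds.cell_of(c.pre_skeleton)]["n_pre"] += 1
        rows[ds.cell_of(c.post_skeleton)]["n_post"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    tot = df["n_pre"] + df["n_post"]
    df["pre_fraction"] = np.where(tot > 0, df["n_pre"] / tot.replace(0, 1), np.nan)
    return df


def polarity_class_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Median pre/post counts per cell class (neurons and effectors)."""
    return (
        table.groupby("cell_class")[["n_pre", "n_post"]]
        .median()
        .rename(columns={"n_pre": "median_pre", "n_post": "median_post"})
    )
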