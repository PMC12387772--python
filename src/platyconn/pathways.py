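"""Sensory-to-effector paths, intersegmental and head-trunk censuses.

Sensory neurons are classified by their shortest directed path length
(hops = number of edges) to the nearest effector: direct sensory-motor
contact (1 hop), premotor (a direct synapse onto a motoneuron), 2+ hops,
or no path at all. Labels are multi-label: a sensory-motor cell may also
be premotor. Segment censuses sum synapse counts between soma body
regions; the head-trunk census ranks individual cells by their
cross-region output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Mapping

import networkx as nx
import pandas as pd

from .core import BODY_REGIONS, CellClass, CellInfo, Segment, TRUNK_REGIONS


def classify_sensory_paths(
    g: nx.DiGraph, classes: Mapping[Hashable, CellClass]
) -> tuple[pd.DataFrame, dict]:
    """Shortest-path classification of every sensory node.

    Works on the cell-level connectome or on a grouped type-level graph —
    ``classes`` maps each node to its cell class either way. Returns a
    per-sensory-node table (hops_to_effector, direct flags, labels) and a
    summary with the maximum finite hop count and the no-path set.
    """
    sensory = [n for n in g.nodes if classes.get(n) is CellClass.SENSORY]
    if not sensory:
        raise ValueError("no sensory neurons in graph")
    effectors = {n for n in g.nodes if classes.get(n) is CellClass.EFFECTOR}
    if not effectors:
        raise ValueError("no effector cells in graph")
    motoneurons = {n for n in g.nodes if classes.get(n) is CellClass.MOTONEURON}

    rows = []
    for sn in sorted(sensory, key=str):
        dist = nx.single_source_shortest_path_length(g, sn)
        hops = min(
            (d for n, d in dist.items() if n in effectors), default=math.inf
        )
        succ = set(g.successors(sn))
        direct_eff = bool(succ & effectors)
        direct_mn = bool(succ & motoneurons)
        labels = []
        if direct_eff:
            labels.append("sensory-motor")
        if direct_mn:
            labels.append("premotor")
        if 2 <= hops < math.inf:
            labels.append("indirect")
        if hops == math.inf:
            labels.append("no-path")
        rows.append(
            {
                "cell_name": sn,
                "hops_to_effector": hops,
                "direct_to_effector": direct_eff,
                "direct_to_motoneuron": direct_mn,
                "labels": tuple(labels),
            }
        )
    df = pd.DataFrame(rows).set_index("cell_name")
    finite = df["hops_to_effector"][df["hops_to_effector"] < math.inf]
    summary = {
        "n_sensory": len(df),
        "max_hops": int(finite.max()) if len(finite) else None,
        "n_sensory_motor": int(df["direct_to_effector"].sum()),
        "n_premotor": int(df["direct_to_motoneuron"].sum()),
        "n_no_path": int((df["hops_to_effector"] == math.inf).sum()),
        "no_path": sorted(
            df.index[df["hops_to_effector"] == math.inf], key=str
        ),
    }
    return df, summary


@dataclass
class SegmentMatrix:
    matrix: pd.DataFrame  # synapse counts, pre-soma region x post-soma region
    n_excluded_cells: int  # graph cells without a segment annotation


def segment_matrix(
    g: nx.DiGraph,
    cells: Mapping[str, CellInfo],
    by_class: bool = False,
) -> SegmentMatrix:
    """Synapse counts between soma body regions (head, sg0-3, pygidium).

    With ``by_class`` the rows/columns are (cell class, region) strata.
    Cells without a segment annotation are excluded and counted.
    """
    def _key(n):
        info = cells.get(n)
        if info is None or info.segment is Segment.NONE:
            return None
        if by_class:
            return (info.cell_class.value, info.segment.value)
        return info.segment.value

    keys = {n: _key(n) for n in g.nodes}
    excluded = sum(1 for k in keys.values() if k is None)
    if excluded == len(keys):
        raise ValueError("no segment-annotated cells in graph")
    if by_class:
        index = [
            (c.value, r.value)
            for c in CellClass
            if c is not CellClass.FRAGMENT
            for r in BODY_REGIONS
        ]
        index = pd.MultiIndex.from_tuples(index, names=["cell_class", "segment"])
    else:
        index = pd.Index([r.value for r in BODY_REGIONS], name="segment")
    mat = pd.DataFrame(0, index=index, columns=index)
    for u, v, d in g.edges(data=True):
        ku, kv = keys[u], keys[v]
        if ku is None or kv is None:
            continue
        mat.loc[[ku], [kv]] += d["weight"]
    return SegmentMatrix(matrix=mat, n_excluded_cells=excluded)


@dataclass
class HeadTrunkCensus:
    head_to_trunk: pd.DataFrame  # per head cell: synapses onto trunk cells
    trunk_to_head: pd.DataFrame  # per trunk cell: synapses onto head cells


def head_trunk_census(
    g: nx.DiGraph, cells: Mapping[str, CellInfo]
) -> HeadTrunkCensus:
    """Rank cells by cross-region synaptic output, with target-class splits.

    Head cells are ranked by their total synapse count onto trunk-soma
    cells (descending) with one column per target cell class; the
    trunk-to-head table is the mirror census. Region membership comes from
    soma annotations, never from coordinates.
    """
    trunk = {r for r in TRUNK_REGIONS}

    def _region(n):
        info = cells.get(n)
        return None if info is None else info.segment

    target_classes = [c.value for c in CellClass]

    def _census(source_pred, target_pred) -> pd.DataFrame:
        per_cell: dict[str, dict] = {}
        for u, v, d in g.edges(data=True):
            ru, rv = _region(u), _region(v)
            if ru is None or rv is None:
                continue
            if not (source_pred(ru) and target_pred(rv)):
                continue
            rec = per_cell.setdefault(
                u, {"n_synapses": 0, **{c: 0 for c in target_classes}}
            )
            rec["n_synapses"] += d["weight"]
            rec[cells[v].cell_class.value] += d["weight"]
        df = pd.DataFrame.from_dict(per_cell, orient="index")
        if df.empty:
            df = pd.DataFrame(columns=["n_synapses", *target_classes])
        return df

    h2t = _census(lambda r: r is Segment.HEAD, lambda r: r in trunk)
    t2h = _census(lambda r: r in trunk, lambda r: r is Segment.HEAD)
    h2t = h2t.sort_values("n_synapses", ascending=False, kind="stable")
    t2h = t2h.sort_values("n_synapses", ascending=False, kind="stable")
    return HeadTrunkCensus(head_to_trunk=h2t, trunk_to_head=t2h)
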