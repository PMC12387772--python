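"""Derive the cell-level connectome graph and the grouped cell-type graph.

The connectome is built from the synapse (connector) table in three steps:
every synapse contributes weight one and parallel synapses between the
same ordered cell pair are summed; cells whose total incident synapse
count (in + out) falls below a threshold (default 3) are dropped in a
single pass; the graph is then restricted to its largest weakly connected
component. Edge weights are raw summed synapse counts throughout; the
square-root transform used for display in grouped graphs is stored as a
separate ``display_weight`` attribute and never enters any analysis.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Callable, Mapping, Optional

import networkx as nx

from .core import CellClass, CellInfo, Dataset


def _node_attrs(info: CellInfo) -> dict:
    return {
        "cell_class": info.cell_class.value,
        "cell_type": info.cell_type or "",
        "segment": info.segment.value,
        "side": info.side.value,
    }


def _largest_weak_component(g: nx.DiGraph) -> set:
    """Largest weakly connected component; ties broken by edge count then
    by lexicographically smallest member name."""
    comps = list(nx.weakly_connected_components(g))
    comps.sort(
        key=lambda c: (
            -len(c),
            -g.subgraph(c).number_of_edges(),
            min(map(str, c)),
        )
    )
    return comps[0]


def build_connectome(
    ds: Dataset, min_synapses: int = 3, iterative: bool = False
) -> nx.DiGraph:
    """Aggregate synapses, filter weakly connected cells, keep the main component.

    Parameters
    ----------
    min_synapses
        Cells with fewer total incident synapses (in + out, counted on the
        aggregated multigraph) are removed.
    iterative
        If True, repeat the removal until stable (k-core-like variant);
        the default is the single-pass rule.
    """
    if not ds.connectors:
        raise ValueError("no synapses: cannot build a connectome")

    edge_syn: Counter[tuple[str, str]] = Counter()
    for c in ds.connectors:
        pre = ds.cell_of(c.pre_skeleton)
        post = ds.cell_of(c.post_skeleton)
        edge_syn[(pre, post)] += 1

    incident: Counter[str] = Counter()
    for (pre, post), w in edge_syn.items():
        incident[pre] += w
        incident[post] += w

    keep = {n for n, tot in incident.items() if tot >= min_synapses}
    n_low = len(incident) - len(keep)
    if iterative:
        while True:
            inc = Counter()
            for (pre, post), w in edge_syn.items():
                if pre in keep and post in keep:
                    inc[pre] += w
                    inc[post] += w
            new_keep = {n for n in keep if inc[n] >= min_synapses}
            if new_keep == keep:
                break
            keep = new_keep
        n_low = len(incident) - len(keep)

    g = nx.DiGraph()
    for n in keep:
        g.add_node(n, **_node_attrs(ds.cells[n]))
    for (pre, post), w in edge_syn.items():
        if pre in keep and post in keep:
            g.add_edge(pre, post, weight=w)
    # Filtering can strand nodes with no surviving edge; they leave with
    # the component step below.
    if g.number_of_nodes() == 0:
        raise ValueError(
            f"graph empty after filtering: {len(incident)} cells seen, "
            f"{n_low} below min_synapses={min_synapses}"
        )

    main = _largest_weak_component(g)
    n_comp_removed = g.number_of_nodes() - len(main)
    g = g.subgraph(main).copy()

    g.graph.update(
        min_synapses=min_synapses,
        iterative=iterative,
        n_cells_seen=len(incident),
        n_removed_low_synapse=n_low,
        n_removed_off_component=n_comp_removed,
        n_synapses_total=len(ds.connectors),
        n_synapses_in_graph=sum(d["weight"] for _, _, d in g.edges(data=True)),
    )
    return g


def synapse_graph(ds: Dataset) -> nx.DiGraph:
    """Aggregated synapse graph with no filtering or component selection.

    Step one of :func:`build_connectome` on its own — useful when an
    analysis must see every synapse (e.g. stereotypy matrices).
    """
    g = nx.DiGraph()
    edge_syn: Counter[tuple[str, str]] = Counter()
    for c in ds.connectors:
        edge_syn[(ds.cell_of(c.pre_skeleton), ds.cell_of(c.post_skeleton))] += 1
    for (pre, post), w in edge_syn.items():
        for n in (pre, post):
            if n not in g:
                g.add_node(n, **_node_attrs(ds.cells[n]))
        g.add_edge(pre, post, weight=w)
    return g


def graph_density(g: nx.DiGraph) -> float:
    """Directed simple-graph density e / (n * (n - 1))."""
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("density undefined for graphs with fewer than 2 nodes")
    return directed_density(n, g.number_of_edges())


def directed_density(n_nodes: int, n_edges: int) -> float:
    """Density of a directed simple graph given node and edge counts."""
    if n_nodes < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return n_edges / (n_nodes * (n_nodes - 1))


def group_by_type(
    g: nx.DiGraph, cells: Mapping[str, CellInfo]
) -> nx.DiGraph:
    """Collapse same-type cells into one node, summing synapse counts.

    Untyped cells and fragments are excluded (their count is recorded in
    graph metadata). Within-type synapses become self-loops. The summed
    weight drives all analyses; ``display_weight`` = sqrt(weight) is
    attached for plotting parity with grouped-graph figures.
    """
    type_of = {
        n: cells[n].cell_type
        for n in g.nodes
        if n in cells
        and cells[n].cell_type is not None
        and cells[n].cell_class is not CellClass.FRAGMENT
    }
    if not type_of:
        raise ValueError("no typed cells in graph")
    tg = nx.DiGraph()
    members: dict[str, list[str]] = {}
    for n, t in type_of.items():
        members.setdefault(t, []).append(n)
    for t, mem in members.items():
        tg.add_node(
            t,
            cell_class=g.nodes[mem[0]]["cell_class"],
            n_cells=len(mem),
        )
    for u, v, d in g.edges(data=True):
        tu, tv = type_of.get(u), type_of.get(v)
        if tu is None or tv is None:
            continue
        w = d["weight"]
        if tg.has_edge(tu, tv):
            tg[tu][tv]["weight"] += w
        else:
            tg.add_edge(tu, tv, weight=w)
    for u, v, d in tg.edges(data=True):
        d["display_weight"] = math.sqrt(d["weight"])
    tg.graph.update(
        n_untyped_excluded=g.number_of_nodes() - len(type_of),
        grouped_from_nodes=len(type_of),
    )
    return tg


def subset(
    g: nx.DiGraph,
    cells: Mapping[str, CellInfo],
    predicate: Callable[[CellInfo], bool],
    rebuild: Optional[int] = None,
) -> nx.DiGraph:
    """Induced subgraph over cells satisfying an annotation predicate.

    Weights are untouched; no re-filtering happens unless ``rebuild`` gives
    a minimum incident synapse count to re-apply on the subgraph.
    """
    chosen = [n for n in g.nodes if n in cells and predicate(cells[n])]
    if not chosen:
        raise ValueError("subset predicate selects no cells")
    sub = g.subgraph(chosen).copy()
    if rebuild is not None:
        inc = Counter()
        for u, v, d in sub.edges(data=True):
            inc[u] += d["weight"]
            inc[v] += d["weight"]
        sub = sub.subgraph(
            [n for n in sub.nodes if inc[n] >= rebuild]
        ).copy()
    return sub
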