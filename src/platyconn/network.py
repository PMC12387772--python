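"""Module detection, centrality ranking, source/sink roles and flow tables.

Community detection uses the Leiden algorithm on the directed, synapse-
weighted graph with the modularity (RB-configuration) objective; the
resolution parameter controls module granularity and a sweep helper is
provided because the recovered module count depends on it. Centralities:
weighted degree (summed in + out synapse counts), PageRank (damping 0.85
on weighted out-edges, uniform teleport for dangling nodes), betweenness
on the unweighted directed graph (synapse counts are affinities, not
distances), and HITS authority on the weighted adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import igraph as ig
import leidenalg as la
import networkx as nx
import pandas as pd


@dataclass
class ModulePartition:
    assignment: dict[Hashable, int]
    resolution: float
    seed: int
    quality: float  # modularity of the partition on the weighted digraph

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))


def _to_igraph(g: nx.DiGraph) -> tuple[ig.Graph, list]:
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    h = ig.Graph(directed=True)
    h.add_vertices(len(nodes))
    h.add_edges([(index[u], index[v]) for u, v in g.edges])
    h.es["weight"] = [d.get("weight", 1) for _, _, d in g.edges(data=True)]
    return h, nodes


def leiden_modules(
    g: nx.DiGraph,
    resolution: float = 1.0,
    seed: int = 0,
    n_iterations: int = 2,
) -> ModulePartition:
    """Leiden community detection; deterministic under a fixed seed."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    h, nodes = _to_igraph(g)
    part = la.find_partition(
        h,
        la.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=n_iterations,
    )
    assignment = {nodes[i]: m for i, m in enumerate(part.membership)}
    quality = h.modularity(part.membership, weights="weight", directed=True)
    return ModulePartition(assignment, resolution, seed, quality)


def leiden_sweep(
    g: nx.DiGraph, resolutions: Sequence[float], seed: int = 0
) -> list[ModulePartition]:
    """Run :func:`leiden_modules` across a resolution sweep."""
    return [leiden_modules(g, r, seed=seed) for r in resolutions]


def centrality_table(g: nx.DiGraph) -> pd.DataFrame:
    """Per-node centralities with min-rank columns (rank 1 = most central)."""
    wdeg = {
        n: g.in_degree(n, weight="weight") + g.out_degree(n, weight="weight")
        for n in g.nodes
    }
    pr = nx.pagerank(g, alpha=0.85, weight="weight", tol=1e-12, max_iter=1000)
    btw = nx.betweenness_centrality(g, normalized=False, weight=None)
    _, authority = nx.hits(g, max_iter=1000, normalized=True)
    df = pd.DataFrame(
        {
            "weighted_degree": pd.Series(wdeg),
            "pagerank": pd.Series(pr),
            "betweenness": pd.Series(btw),
            "authority": pd.Series(authority),
        }
    )
    for col in ("weighted_degree", "pagerank", "betweenness", "authority"):
        df[f"rank_{col}"] = (
            df[col].rank(method="min", ascending=False).astype(int)
        )
    return df


def classify_source_sink(
    g: nx.DiGraph,
) -> tuple[pd.Series, pd.DataFrame]:
    """Label every node source / sink / internal / isolated.

    Sources only send (out > 0, in = 0) — in the larva mostly sensory
    neurons; sinks only receive — mostly effectors. Returns the per-node
    labels and a cell-class x role count table (classes taken from node
    attributes where present).
    """
    roles = {}
    for n in g.nodes:
        indeg = g.in_degree(n)
        outdeg = g.out_degree(n)
        if indeg == 0 and outdeg == 0:
            roles[n] = "isolated"
        elif indeg == 0:
            roles[n] = "source"
        elif outdeg == 0:
            roles[n] = "sink"
        else:
            roles[n] = "internal"
    s = pd.Series(roles, name="role")
    classes = pd.Series(
        {n: g.nodes[n].get("cell_class", "unknown") for n in g.nodes},
        name="cell_class",
    )
    counts = (
        pd.crosstab(classes, s)
        .reindex(columns=["source", "internal", "sink", "isolated"], fill_value=0)
    )
    return s, counts


def flow_table(
    g: nx.DiGraph,
    grouping: Mapping[Hashable, str],
    order: Sequence[str],
    min_weight: int = 11,
) -> pd.DataFrame:
    """Aggregate edges by node category and flag backward flow.

    Grouped weights are summed synapse counts; records below ``min_weight``
    are dropped (default keeps connections with >10 synapses, the
    convention of grouped flow diagrams). An edge is "backward" when the
    target category precedes the source category in ``order``.
    """
    for n in g.nodes:
        if n not in grouping:
            raise ValueError(f"node {n!r} has no category in grouping")
    pos = {c: i for i, c in enumerate(order)}
    agg: dict[tuple[str, str], int] = {}
    for u, v, d in g.edges(data=True):
        key = (grouping[u], grouping[v])
        agg[key] = agg.get(key, 0) + d["weight"]
    rows = [
        {
            "source": s,
            "target": t,
            "weight": w,
            "backward": pos.get(t, len(order)) < pos.get(s, len(order)),
        }
        for (s, t), w in sorted(agg.items())
        if w >= min_weight
    ]
    return pd.DataFrame(rows, columns=["source", "target", "weight", "backward"])


@dataclass
class ModuleMixing:
    per_module: pd.DataFrame  # within_weight, between_weight, within_fraction
    total_within: int = 0
    total_between: int = 0


def module_mixing(g: nx.DiGraph, part: ModulePartition) -> ModuleMixing:
    """Within- vs between-module synapse weight, per module and overall.

    ``within_fraction`` is the share of a module's incident weight that
    stays inside it; in a well-mixed modular graph it exceeds the
    between-module share. Self-loops count as within weight. Overall,
    total_within + total_between equals the graph's total edge weight.
    """
    assign = part.assignment
    missing = [n for n in g.nodes if n not in assign]
    if missing:
        raise ValueError(f"partition does not cover node {missing[0]!r}")
    modules = sorted(set(assign.values()))
    within = {m: 0 for m in modules}
    between = {m: 0 for m in modules}
    total_between = 0
    for u, v, d in g.edges(data=True):
        mu, mv = assign[u], assign[v]
        w = d["weight"]
        if mu == mv:
            within[mu] += w
        else:
            between[mu] += w
            between[mv] += w
            total_between += w
    rows = []
    for m in modules:
        denom = within[m] + between[m]
        rows.append(
            {
                "module": m,
                "within_weight": within[m],
                "between_weight": between[m],
                "within_fraction": within[m] / denom if denom else float("nan"),
            }
        )
    return ModuleMixing(
        per_module=pd.DataFrame(rows).set_index("module"),
        total_within=sum(within.values()),
        total_between=total_between,
    )
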