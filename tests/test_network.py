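"""Module detection, centralities, roles, flow tables, mixing."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from platyconn import graphs, metrics, network, synthetic
from platyconn.core import CellClass

from conftest import dataset_from_edges, random_small_dataset


def two_cliques(k=5):
    g = nx.DiGraph()
    for off, tag in ((0, "a"), (k, "b")):
        for i in range(k):
            for j in range(k):
                if i != j:
                    g.add_edge(f"{tag}{i}", f"{tag}{j}", weight=1)
    return g


def test_leiden_separates_disconnected_cliques():
    g = two_cliques()
    part = network.leiden_modules(g, seed=0)
    assert part.n_modules == 2
    mods_a = {part.assignment[f"a{i}"] for i in range(5)}
    mods_b = {part.assignment[f"b{i}"] for i in range(5)}
    assert len(mods_a) == 1 and len(mods_b) == 1 and mods_a != mods_b


def test_leiden_single_node_graph():
    g = nx.DiGraph()
    g.add_node("only")
    part = network.leiden_modules(g, seed=0)
    assert part.assignment == {"only": 0}


def test_leiden_rejects_nonpositive_resolution():
    with pytest.raises(ValueError):
        network.leiden_modules(two_cliques(), resolution=0)


def test_leiden_beats_singleton_partition_modularity():
    g, _ = synthetic.planted_partition_graph(seed=2)
    part = network.leiden_modules(g, seed=0)
    assert part.quality >= 0.0  # singleton partition has modularity <= 0


def test_leiden_reproducible_under_seed():
    g, _ = synthetic.planted_partition_graph(seed=3)
    p1 = network.leiden_modules(g, seed=42)
    p2 = network.leiden_modules(g, seed=42)
    assert p1.assignment == p2.assignment and p1.quality == p2.quality


def test_leiden_recovers_planted_modules():
    hits = 0
    for seed in range(20):
        g, labels = synthetic.planted_partition_graph(
            n_modules=3, cells_per_module=20, p_within=0.4, p_between=0.01, seed=seed
        )
        part = network.leiden_modules(g, resolution=1.0, seed=seed)
        if metrics.adjusted_rand_index(labels, part.assignment) >= 0.9:
            hits += 1
    assert hits >= 19


def test_pagerank_symmetric_two_cycle():
    g = nx.DiGraph()
    g.add_edge("A", "B", weight=2)
    g.add_edge("B", "A", weight=2)
    tab = network.centrality_table(g)
    assert tab.loc["A", "pagerank"] == pytest.approx(0.5)
    assert tab.loc["B", "pagerank"] == pytest.approx(0.5)


def test_betweenness_directed_path():
    g = nx.DiGraph()
    g.add_edge("A", "B", weight=1)
    g.add_edge("B", "C", weight=1)
    tab = network.centrality_table(g)
    assert tab.loc["B", "betweenness"] == 1.0
    assert tab.loc["A", "betweenness"] == 0.0
    assert tab.loc["C", "betweenness"] == 0.0


def pagerank_power_iteration(g, alpha=0.85, tol=1e-14):
    """Independent oracle: dense power iteration with uniform teleport and
    uniform redistribution of dangling mass, on weighted out-edges."""
    nodes = list(g.nodes)
    n = len(nodes)
    ix = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        W[ix[u], ix[v]] = d.get("weight", 1)
    out = W.sum(axis=1)
    r = np.full(n, 1 / n)
    for _ in range(10000):
        send = np.where(out > 0, r / np.where(out > 0, out, 1), 0.0)
        new = alpha * (W.T @ send) + alpha * r[out == 0].sum() / n + (1 - alpha) / n
        if np.abs(new - r).sum() < tol:
            r = new
            break
        r = new
    return dict(zip(nodes, r))


def test_pagerank_matches_power_iteration_oracle():
    rng = np.random.default_rng(5)
    g = nx.DiGraph()
    for _ in range(40):
        a, b = rng.integers(0, 15, 2)
        if a != b:
            g.add_edge(int(a), int(b), weight=int(rng.integers(1, 6)))
    tab = network.centrality_table(g)
    oracle = pagerank_power_iteration(g)
    for node, val in oracle.items():
        assert tab.loc[node, "pagerank"] == pytest.approx(val, abs=1e-8)


@pytest.mark.parametrize("seed", range(5))
def test_pagerank_sums_to_one_and_is_label_invariant(seed):
    ds = random_small_dataset(seed + 40)
    g = graphs.build_connectome(ds, min_synapses=1)
    tab = network.centrality_table(g)
    assert tab["pagerank"].sum() == pytest.approx(1.0, abs=1e-9)
    relabel = nx.relabel_nodes(g, {n: f"z_{n}" for n in g.nodes})
    tab2 = network.centrality_table(relabel)
    for n in g.nodes:
        assert tab.loc[n, "pagerank"] == pytest.approx(
            tab2.loc[f"z_{n}", "pagerank"], abs=1e-12
        )


def test_ties_share_min_rank():
    g = nx.DiGraph()
    g.add_edge("A", "B", weight=2)
    g.add_edge("C", "B", weight=2)
    tab = network.centrality_table(g)
    assert tab.loc["A", "rank_weighted_degree"] == 2
    assert tab.loc["C", "rank_weighted_degree"] == 2
    assert tab.loc["B", "rank_weighted_degree"] == 1


def test_source_sink_roles():
    g = nx.DiGraph()
    g.add_edge("A", "B", weight=1)
    roles, _ = network.classify_source_sink(g)
    assert roles["A"] == "source" and roles["B"] == "sink"
    g2 = nx.DiGraph()
    g2.add_edge("A", "B", weight=1)
    g2.add_edge("B", "A", weight=1)
    roles2, _ = network.classify_source_sink(g2)
    assert set(roles2) == {"internal"}


def test_effectors_are_sinks_in_feedforward_fixture():
    ds, _ = synthetic.generate_dataset(seed=11)
    g = graphs.synapse_graph(ds)
    roles, counts = network.classify_source_sink(g)
    for n, role in roles.items():
        if ds.cells[n].cell_class is CellClass.EFFECTOR:
            assert role in ("sink", "isolated")
    assert counts.loc["effector", "source"] == 0


def test_flow_table_direction_and_threshold():
    g = nx.DiGraph()
    g.add_edge("s1", "i1", weight=7)
    g.add_edge("s2", "i1", weight=5)
    g.add_edge("i1", "s1", weight=15)
    g.add_edge("i1", "m1", weight=4)
    grouping = {"s1": "SN", "s2": "SN", "i1": "IN", "m1": "MN"}
    tab = network.flow_table(g, grouping, order=["SN", "IN", "MN"])
    recs = {(r.source, r.target): r for r in tab.itertuples()}
    assert recs[("SN", "IN")].weight == 12 and not recs[("SN", "IN")].backward
    assert recs[("IN", "SN")].weight == 15 and recs[("IN", "SN")].backward
    assert ("IN", "MN") not in recs  # below >10-synapse display threshold


def test_flow_table_requires_full_grouping():
    g = nx.DiGraph()
    g.add_edge("a", "b", weight=20)
    with pytest.raises(ValueError, match="'b'"):
        network.flow_table(g, {"a": "X"}, order=["X"])


def test_flow_table_totals_conserved_before_threshold():
    ds = random_small_dataset(60)
    g = graphs.build_connectome(ds, min_synapses=1)
    grouping = {n: ds.cells[n].cell_class.value for n in g.nodes}
    tab = network.flow_table(g, grouping, order=[], min_weight=0)
    assert tab.weight.sum() == sum(d["weight"] for _, _, d in g.edges(data=True))


def test_module_mixing_disconnected_cliques():
    g = two_cliques()
    part = network.leiden_modules(g, seed=0)
    mix = network.module_mixing(g, part)
    assert (mix.per_module["within_fraction"] == 1.0).all()
    assert mix.total_between == 0


def test_module_mixing_matches_exhaustive_count():
    g = nx.complete_graph(6, create_using=nx.DiGraph)
    for u, v in g.edges:
        g[u][v]["weight"] = 1
    part = network.ModulePartition(
        assignment={n: n % 2 for n in g.nodes}, resolution=1.0, seed=0, quality=0.0
    )
    mix = network.module_mixing(g, part)
    # exhaustive: per module 3 nodes -> 6 ordered internal pairs
    assert mix.total_within == 12
    assert mix.total_between == 18
    assert mix.total_within + mix.total_between == g.number_of_edges()


def test_module_mixing_singleton_partition_counts_self_loops_only():
    g = nx.DiGraph()
    g.add_edge("a", "b", weight=3)
    g.add_edge("a", "a", weight=2)
    part = network.ModulePartition(
        assignment={"a": 0, "b": 1}, resolution=1.0, seed=0, quality=0.0
    )
    mix = network.module_mixing(g, part)
    assert mix.total_within == 2  # only the self-loop
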