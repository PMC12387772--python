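"""Cable length, smoothing, Sholl, radial density, polarity."""

from __future__ import annotations

import numpy as np
import pytest

from platyconn import morphometry, synthetic
from platyconn.core import Connector, Dataset, CellInfo, CellClass

from conftest import dataset_from_edges, line_skeleton, make_skeleton


def random_tree(seed, n=30, scale=1500.0, sid=1):
    r = np.random.default_rng(seed)
    pts = [(0.0, 0.0, 0.0)]
    parents = [None]
    for i in range(1, n):
        par = int(r.integers(0, i))
        pts.append(tuple(np.asarray(pts[par]) + r.normal(0, scale, 3)))
        parents.append(par)
    return make_skeleton(sid, f"t{sid}", pts, parents)


def total_edge_length(sk):
    return sum(
        np.linalg.norm(
            np.array([p.x - c.x, p.y - c.y, p.z - c.z])
        )
        for p, c in sk.edges()
    ) / 1000.0


def test_collinear_three_nodes():
    sk = line_skeleton(1, "line", 3, step_nm=1000.0)
    assert morphometry.cable_length(sk, prune_below_um=0.0) == pytest.approx(2.0)


def test_prune_zero_equals_total_length():
    for seed in range(5):
        sk = random_tree(seed)
        assert morphometry.cable_length(sk, 0.0) == pytest.approx(
            total_edge_length(sk)
        )


def test_short_twig_is_pruned():
    # backbone 0..10 um along y, with a 1.5 um twig off the node at 5 um
    pts = [(0.0, 1000.0 * i, 0.0) for i in range(11)]
    parents = [None] + list(range(10))
    pts.append((1500.0, 5000.0, 0.0))  # twig tip
    parents.append(5)
    sk = make_skeleton(1, "Y", pts, parents)
    assert morphometry.cable_length(sk, prune_below_um=2.0) == pytest.approx(10.0)
    assert morphometry.cable_length(sk, prune_below_um=1.0) == pytest.approx(11.5)


def test_single_node_skeleton_has_zero_cable():
    assert morphometry.cable_length(line_skeleton(1, "dot", 1)) == 0.0


def test_cable_length_rigid_motion_invariant():
    rng = np.random.default_rng(0)
    sk = random_tree(3)
    # random rotation (QR) + translation
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    t = rng.normal(0, 1e5, 3)
    moved = {}
    for nid, n in sk.nodes.items():
        p = q @ np.array([n.x, n.y, n.z]) + t
        moved[nid] = (p[0], p[1], p[2])
    import dataclasses

    sk2 = make_skeleton(
        2,
        "moved",
        [moved[i] for i in sorted(sk.nodes)],
        [None if sk.nodes[i].parent_id is None else sk.nodes[i].parent_id - 1
         for i in sorted(sk.nodes)],
    )
    for prune in (0.0, 2.0):
        assert morphometry.cable_length(sk2, prune) == pytest.approx(
            morphometry.cable_length(sk, prune), abs=1e-6
        )


def test_smoothing_straight_line_is_fixed_point():
    sk = line_skeleton(1, "line", 12, step_nm=1000.0)
    sm = morphometry.smooth_skeleton(sk, sigma=6000.0)
    for nid in sk.nodes:
        a, b = sk.nodes[nid], sm.nodes[nid]
        assert abs(a.x - b.x) < 1e-9
        assert abs(a.y - b.y) < 1e-9
        assert abs(a.z - b.z) < 1e-9


def test_smoothing_sigma_zero_is_identity():
    sk = random_tree(4)
    sm = morphometry.smooth_skeleton(sk, sigma=0.0)
    assert sm.nodes == sk.nodes


def test_smoothing_rejects_negative_sigma():
    with pytest.raises(ValueError):
        morphometry.smooth_skeleton(line_skeleton(1, "l", 3), sigma=-1.0)


def test_smoothing_preserves_topology_and_tags():
    sk = random_tree(5)
    sm = morphometry.smooth_skeleton(sk, sigma=3000.0)
    assert set(sm.nodes) == set(sk.nodes)
    for nid in sk.nodes:
        assert sm.nodes[nid].parent_id == sk.nodes[nid].parent_id
        assert sm.nodes[nid].tags == sk.nodes[nid].tags


@pytest.mark.parametrize("seed", range(100))
def test_smoothing_never_lengthens_a_path(seed):
    r = np.random.default_rng(seed)
    n = int(r.integers(5, 30))
    pts = np.cumsum(r.normal(0, 1200, size=(n, 3)), axis=0)
    sk = make_skeleton(1, "p", [tuple(p) for p in pts], [None] + list(range(n - 1)))
    sm = morphometry.smooth_skeleton(sk, sigma=float(r.uniform(500, 8000)))
    assert total_edge_length(sm) <= total_edge_length(sk) + 1e-9


def test_sholl_unbranched_line():
    sk = line_skeleton(1, "line", 11, step_nm=1000.0)  # 10 um long
    prof = morphometry.sholl(sk, step=1000.0)
    assert list(prof.radii) == [1000.0 * i for i in range(1, 11)]
    assert list(prof.crossings[:9]) == [1] * 9
    assert prof.crossings[9] == 0  # nothing beyond the distal tip


def test_sholl_four_arm_star():
    pts = [(0.0, 0.0, 0.0)]
    parents = [None]
    for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        prev = 0
        for i in range(1, 6):
            pts.append((dx * i * 1000.0, dy * i * 1000.0, 0.0))
            parents.append(prev)
            prev = len(pts) - 1
    sk = make_skeleton(1, "star", pts, parents)
    prof = morphometry.sholl(sk, step=1000.0)
    assert (prof.crossings[:4] == 4).all()  # radii 1..4 um, arms are 5 um


def test_sholl_near_zero_radius_equals_root_degree(rng):
    for seed in range(5):
        sk = random_tree(seed)
        prof = morphometry.sholl(sk, step=1.0)  # first sphere at 1 nm
        root_degree = len(sk.children_map()[sk.root_id])
        assert prof.crossings[0] == root_degree


@pytest.mark.parametrize("seed", range(10))
def test_sholl_matches_bruteforce_straddle_check(seed):
    sk = random_tree(seed)
    step = 700.0
    prof = morphometry.sholl(sk, step)
    root = sk.nodes[sk.root_id]
    r0 = np.array([root.x, root.y, root.z])
    for r, got in zip(prof.radii, prof.crossings):
        count = 0
        for parent, child in sk.edges():
            d1 = np.linalg.norm(np.array([parent.x, parent.y, parent.z]) - r0)
            d2 = np.linalg.norm(np.array([child.x, child.y, child.z]) - r0)
            if min(d1, d2) <= r < max(d1, d2):
                count += 1
        assert got == count


def _skeleton_with_synapses(dists, bin_nm=1000.0):
    pts = [(0.0, 0.0, 0.0)] + [(0.0, d, 0.0) for d in dists]
    parents = [None] + [0] * len(dists)
    sk = make_skeleton(1, "cell", pts, parents)
    sk2 = line_skeleton(2, "partner", 2, soma=True)
    conns = [
        Connector(i + 1, 1, i + 2, 2, 1) for i in range(len(dists))
    ]
    return sk, conns


def test_radial_density_direct_binning():
    sk, conns = _skeleton_with_synapses([500.0, 1500.0, 1500.0])
    prof = morphometry.radial_synapse_density(sk, conns, bin_nm=1000.0, role="pre")
    assert list(prof.counts) == [1, 2]
    assert prof.density.sum() == pytest.approx(1.0)


def test_radial_density_no_synapses_is_all_zero():
    sk, _ = _skeleton_with_synapses([500.0])
    prof = morphometry.radial_synapse_density(sk, [], role="pre")
    assert prof.counts.sum() == 0
    assert (prof.density == 0).all()


def test_radial_density_requires_soma():
    sk = line_skeleton(1, "frag", 4, soma=False)
    with pytest.raises(ValueError, match="no soma"):
        morphometry.radial_synapse_density(sk, [], role="pre")


def test_class_mean_radial_density_matches_bruteforce():
    ds, _ = synthetic.generate_dataset(seed=31)
    sensory = [
        sid
        for sid, name in ds.skeleton_to_cell.items()
        if ds.cells[name].cell_class is CellClass.SENSORY
    ]
    profiles = [
        morphometry.radial_synapse_density(
            ds.skeletons[sid], ds.connectors, bin_nm=1000.0, role="pre"
        )
        for sid in sensory
    ]
    mean = morphometry.mean_radial_profile(profiles)
    n = max(len(p.counts) for p in profiles)
    brute = np.zeros(n)
    for p in profiles:
        brute[: len(p.counts)] += p.counts
    brute /= len(profiles)
    assert np.allclose(mean.counts, brute)


def test_polarity_arithmetic_and_conservation():
    ds, _ = synthetic.generate_dataset(seed=32)
    tab = morphometry.polarity_table(ds)
    assert tab.n_pre.sum() == tab.n_post.sum() == len(ds.connectors)
    row = tab[(tab.n_pre > 0) | (tab.n_post > 0)].iloc[0]
    assert row.pre_fraction == pytest.approx(
        row.n_pre / (row.n_pre + row.n_post)
    )
    effectors = tab[tab.cell_class == "effector"]
    assert (effectors.n_pre == 0).all()


def test_cell_with_eight_pre_six_post():
    ds = dataset_from_edges({("a", "b"): 8, ("c", "a"): 6})
    tab = morphometry.polarity_table(ds)
    assert tab.loc["a", "pre_fraction"] == pytest.approx(8 / 14)


def test_zero_synapse_cell_polarity_is_undefined():
    ds = dataset_from_edges({("a", "b"): 1}, extra_cells=["lonely"])
    tab = morphometry.polarity_table(ds)
    assert np.isnan(tab.loc["lonely", "pre_fraction"])
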