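"""Synthetic segmented-larva connectome generator with known ground truth.

Emulates the structure of a whole-body annelid larval dataset: six body
regions (head, segments 0-3, pygidium), cell types drawn from the four
classes sensory / interneuron / motoneuron / effector with two cells per
type (one left, one right homolog), soma-less fragments, monadic chemical
synapses with a feed-forward sensory -> inter -> motor -> effector bias,
planted connectivity modules, and mirror-symmetric left-right
connectivity with tunable noise. Every distributional choice here is test
scaffolding with a recoverable ground truth, not a claim about any real
animal.

All stages derive child random generators deterministically from a single
master seed via ``numpy.random.SeedSequence([seed, stage])``, so each
stage is independently reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .core import (
    BODY_REGIONS,
    CLASS_RANK,
    CellClass,
    CellInfo,
    Connector,
    Dataset,
    Segment,
    Side,
    Skeleton,
    SkeletonNode,
)

_STAGE_BODY, _STAGE_SKEL, _STAGE_SYN = 1, 2, 3

_CLASS_PREFIX = {
    CellClass.SENSORY: "SN",
    CellClass.INTERNEURON: "IN",
    CellClass.MOTONEURON: "MN",
    CellClass.EFFECTOR: "EFF",
}
_SIDE_SUFFIX = {Side.LEFT: "l", Side.RIGHT: "r", Side.MIDDLE: "m"}

GENERATOR_CLASSES = tuple(_CLASS_PREFIX)


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


@dataclass
class BodyPlanConfig:
    """Which cell types exist where.

    ``n_types_per_class_per_segment`` maps each class to the number of
    cell types planted in every body region; with ``cells_per_type = 2``
    each type yields one left and one right homolog (1 yields a midline
    cell; odd counts add one midline cell).
    """

    n_types_per_class_per_segment: Mapping[CellClass, int] = field(
        default_factory=lambda: {
            CellClass.SENSORY: 2,
            CellClass.INTERNEURON: 2,
            CellClass.MOTONEURON: 1,
            CellClass.EFFECTOR: 1,
        }
    )
    segments: Sequence[Segment] = BODY_REGIONS
    cells_per_type: int = 2
    fragment_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_type < 1:
            raise ValueError("cells_per_type must be >= 1")
        if not 0 <= self.fragment_fraction < 1:
            raise ValueError("fragment_fraction must be in [0, 1)")


@dataclass
class SkeletonGeometry:
    """Simple arbor model: soma + main neurite + Poisson-count twigs."""

    n_main_nodes: int = 8
    main_step_nm: float = 2000.0
    twig_rate: float = 2.0  # Poisson mean twig count per neuron
    twig_nodes: int = 3
    twig_step_nm: float = 800.0
    soma_offset_x_nm: float = 10000.0  # lateral soma position (mirror plane x=0)
    segment_pitch_nm: float = 30000.0  # anterior-posterior spacing of regions
    jitter_nm: float = 1500.0


@dataclass
class ConnectivityConfig:
    """Planted-module, feed-forward-biased, mirror-symmetric wiring.

    ``mirror_noise`` is the fraction of left-side type-level edges whose
    right-side mirror is resampled to a random target (0 = perfect
    symmetry, 1 = independent sides). Per-edge synapse counts are
    1 + NegBin(dispersion, mean - 1): overdispersed counts with mean
    ``synapse_mean``.
    """

    n_modules: int = 3
    p_within: float = 0.26
    p_between: float = 0.03
    class_order_bias: float = 0.9
    mirror_noise: float = 0.1
    synapse_mean: float = 3.0
    synapse_dispersion: float = 2.0
    fragment_attach_prob: float = 0.5  # chance a fragment joins the network

    def __post_init__(self) -> None:
        for name in ("p_within", "p_between", "class_order_bias", "mirror_noise"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.synapse_mean < 1:
            raise ValueError("synapse_mean must be >= 1")


@dataclass
class GroundTruth:
    module_of: dict[str, int] = field(default_factory=dict)  # cell -> module
    homolog_pairs: list[tuple[str, str]] = field(default_factory=list)
    type_of: dict[str, str] = field(default_factory=dict)
    class_of: dict[str, str] = field(default_factory=dict)
    segment_of: dict[str, str] = field(default_factory=dict)
    cable_length_um: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: Path | str) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "module_of": self.module_of,
                    "homolog_pairs": self.homolog_pairs,
                    "type_of": self.type_of,
                    "class_of": self.class_of,
                    "segment_of": self.segment_of,
                    "cable_length_um": self.cable_length_um,
                },
                indent=1,
                sort_keys=True,
            )
        )


def generate_body_plan(
    cfg: BodyPlanConfig,
) -> tuple[dict[str, CellInfo], GroundTruth]:
    """Lay out cell types per class per segment, plus soma-less fragments."""
    cells: dict[str, CellInfo] = {}
    gt = GroundTruth()
    type_counter = 0
    for seg in cfg.segments:
        for cls in GENERATOR_CLASSES:
            for _ in range(cfg.n_types_per_class_per_segment.get(cls, 0)):
                type_counter += 1
                type_label = f"celltype{type_counter}"
                base = f"{_CLASS_PREFIX[cls]}{type_counter}_{seg.value}"
                members: list[str] = []
                for k in range(cfg.cells_per_type):
                    if cfg.cells_per_type == 1:
                        side = Side.MIDDLE
                    elif k == 0:
                        side = Side.LEFT
                    elif k == 1:
                        side = Side.RIGHT
                    else:
                        side = Side.MIDDLE
                    suffix = _SIDE_SUFFIX[side]
                    name = base + "_" + (
                        suffix if k < 3 else f"{suffix}{k}"
                    )
                    cells[name] = CellInfo(
                        cell_name=name,
                        cell_class=cls,
                        cell_type=type_label,
                        segment=seg,
                        side=side,
                    )
                    gt.type_of[name] = type_label
                    gt.class_of[name] = cls.value
                    gt.segment_of[name] = seg.value
                    members.append(name)
                if cfg.cells_per_type == 2:
                    gt.homolog_pairs.append((members[0], members[1]))
    n_fragments = round(cfg.fragment_fraction * len(cells))
    for i in range(1, n_fragments + 1):
        name = f"frag_{i}"
        cells[name] = CellInfo(cell_name=name, cell_class=CellClass.FRAGMENT)
        gt.class_of[name] = CellClass.FRAGMENT.value
    return cells, gt


def _grow_arbor(
    rng: np.random.Generator, geom: SkeletonGeometry, soma: np.ndarray
) -> tuple[list[np.ndarray], list[Optional[int]]]:
    """Node positions for soma + main neurite + twigs (parent = index map)."""
    pts = [soma.copy()]
    parents = [None]
    direction = np.array([0.0, 1.0, 0.0])
    for i in range(geom.n_main_nodes):
        step = direction * geom.main_step_nm + rng.normal(
            0, geom.jitter_nm, 3
        )
        pts.append(pts[-1 if i else 0] + step)
        parents.append(len(pts) - 2)
    n_twigs = rng.poisson(geom.twig_rate)
    for _ in range(n_twigs):
        attach = int(rng.integers(1, len(parents))) if len(parents) > 1 else 0
        base = attach
        heading = rng.normal(0, 1, 3)
        heading /= np.linalg.norm(heading)
        for _ in range(geom.twig_nodes):
            pts.append(
                pts[base] + heading * geom.twig_step_nm
                + rng.normal(0, geom.jitter_nm / 3, 3)
            )
            parents.append(base)
            base = len(pts) - 1
    return [np.asarray(p) for p in pts], parents


def _points_to_skeleton(
    skeleton_id: int,
    cell_name: str,
    pts: Sequence[np.ndarray],
    parents: Sequence[Optional[int]],
    soma: bool,
) -> Skeleton:
    nodes = {}
    for i, (p, par) in enumerate(zip(pts, parents), start=1):
        tags = frozenset({"soma"}) if (soma and par is None) else frozenset()
        nodes[i] = SkeletonNode(
            node_id=i,
            parent_id=None if par is None else par + 1,
            x=float(p[0]),
            y=float(p[1]),
            z=float(p[2]),
            radius=1000.0 if (soma and par is None) else 100.0,
            tags=tags,
        )
    return Skeleton(skeleton_id=skeleton_id, cell_name=cell_name, nodes=nodes)


def _mirror_skeleton(sk: Skeleton, skeleton_id: int, cell_name: str) -> Skeleton:
    nodes = {
        nid: SkeletonNode(
            node_id=n.node_id,
            parent_id=n.parent_id,
            x=-n.x,
            y=n.y,
            z=n.z,
            radius=n.radius,
            tags=n.tags,
        )
        for nid, n in sk.nodes.items()
    }
    return Skeleton(skeleton_id=skeleton_id, cell_name=cell_name, nodes=nodes)


def generate_skeletons(
    cells: Mapping[str, CellInfo],
    geom: Optional[SkeletonGeometry] = None,
    seed: int = 0,
    gt: Optional[GroundTruth] = None,
) -> tuple[dict[int, Skeleton], dict[int, str]]:
    """Grow one skeleton per cell; right homologs are exact mirror images.

    Somas sit at a lateral offset whose sign encodes the body side
    (mirror plane x = 0) and an anterior-posterior position set by the
    segment. Fragments are short soma-less skeletons. When a
    ``GroundTruth`` is given, the generator's running cable-length sum for
    each skeleton is recorded there as an independent oracle.
    """
    geom = geom or SkeletonGeometry()
    skeletons: dict[int, Skeleton] = {}
    name_map: dict[int, str] = {}
    seg_index = {r: i for i, r in enumerate(BODY_REGIONS)}
    pending_mirror: dict[str, Skeleton] = {}
    by_type: dict[str, list[str]] = {}
    for name, info in cells.items():
        if info.cell_type:
            by_type.setdefault(info.cell_type, []).append(name)

    sid = 0
    for name in sorted(cells):
        info = cells[name]
        sid += 1
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [seed, _STAGE_SKEL, zlib.crc32((info.cell_type or name).encode())]
            )
        )
        if info.cell_class is CellClass.FRAGMENT:
            frng = np.random.default_rng(
                np.random.SeedSequence([seed, _STAGE_SKEL, sid, 7])
            )
            start = frng.uniform(-40000, 40000, 3)
            n = int(frng.integers(3, 8))
            pts = [start]
            parents: list[Optional[int]] = [None]
            for i in range(n - 1):
                pts.append(pts[-1] + frng.normal(0, geom.twig_step_nm, 3))
                parents.append(i)
            skeletons[sid] = _points_to_skeleton(sid, name, pts, parents, soma=False)
            name_map[sid] = name
            continue

        members = sorted(by_type.get(info.cell_type or "", [name]))
        is_right_of_pair = (
            info.side is Side.RIGHT
            and len(members) == 2
            and cells[members[0]].side is Side.LEFT
        )
        if is_right_of_pair:
            left_sk = pending_mirror[members[0]]
            skeletons[sid] = _mirror_skeleton(left_sk, sid, name)
        else:
            x0 = {
                Side.LEFT: geom.soma_offset_x_nm,
                Side.RIGHT: -geom.soma_offset_x_nm,
                Side.MIDDLE: 0.0,
                Side.NONE: 0.0,
            }[info.side]
            soma = np.array(
                [
                    x0,
                    seg_index.get(info.segment, 0) * geom.segment_pitch_nm,
                    float(rng.uniform(-geom.jitter_nm, geom.jitter_nm)),
                ]
            )
            pts, parents = _grow_arbor(rng, geom, soma)
            skeletons[sid] = _points_to_skeleton(sid, name, pts, parents, soma=True)
            if info.side is Side.LEFT:
                pending_mirror[name] = skeletons[sid]
        name_map[sid] = name

    if gt is not None:
        for sid, sk in skeletons.items():
            total = sum(
                float(
                    np.linalg.norm(
                        np.array([p.x - c.x, p.y - c.y, p.z - c.z])
                    )
                )
                for p, c in sk.edges()
            )
            gt.cable_length_um[name_map[sid]] = total / 1000.0
    return skeletons, name_map


def _synapse_count(rng: np.random.Generator, cc: ConnectivityConfig) -> int:
    """1 + negative binomial: overdispersed counts with mean synapse_mean."""
    extra_mean = cc.synapse_mean - 1.0
    if extra_mean <= 0:
        return 1
    r = cc.synapse_dispersion
    p = r / (r + extra_mean)
    return 1 + int(rng.negative_binomial(r, p))


def generate_synapses(
    cells: Mapping[str, CellInfo],
    skeletons: Mapping[int, Skeleton],
    name_map: Mapping[int, str],
    cc: Optional[ConnectivityConfig] = None,
    seed: int = 0,
    gt: Optional[GroundTruth] = None,
) -> tuple[list[Connector], dict[str, int]]:
    """Wire the cells: planted modules, feed-forward bias, mirrored sides.

    Cell types are assigned round-robin to ``n_modules`` planted modules
    (homolog pairs share a module). Type-level edges are sampled with
    probability ``p_within`` inside a module and ``p_between`` across
    modules; edges running against the sensory -> inter -> motor ->
    effector order are additionally thinned by ``1 - class_order_bias``.
    Effectors never send synapses. Each left-side type edge is mirrored to
    the right side with the same synapse count, except a ``mirror_noise``
    fraction whose right-side target type and count are resampled.
    Synapses land on uniformly drawn skeleton nodes.
    """
    cc = cc or ConnectivityConfig()
    rng = _rng(seed, _STAGE_SYN)
    sid_of_cell = {name: sid for sid, name in name_map.items()}

    by_type: dict[str, list[str]] = {}
    for name, info in cells.items():
        if info.cell_type and info.cell_class is not CellClass.FRAGMENT:
            by_type.setdefault(info.cell_type, []).append(name)
    types = sorted(by_type)
    perm = rng.permutation(len(types))
    module_of_type = {
        types[i]: int(perm[i] % cc.n_modules) for i in range(len(types))
    }
    module_of = {
        name: module_of_type[t] for t in types for name in by_type[t]
    }

    def members(t: str, side: Side) -> list[str]:
        mem = sorted(by_type[t])
        chosen = [m for m in mem if cells[m].side is side]
        return chosen or mem

    class_of_type = {t: cells[by_type[t][0]].cell_class for t in types}

    synapse_plan: list[tuple[str, str, int]] = []  # (pre cell, post cell, count)
    for t1 in types:
        if class_of_type[t1] is CellClass.EFFECTOR:
            continue
        for t2 in types:
            p = cc.p_within if module_of_type[t1] == module_of_type[t2] else cc.p_between
            if CLASS_RANK[class_of_type[t2]] < CLASS_RANK[class_of_type[t1]]:
                p *= 1.0 - cc.class_order_bias
            if rng.random() >= p:
                continue
            k = _synapse_count(rng, cc)
            pre_l = members(t1, Side.LEFT)[0]
            post_l = members(t2, Side.LEFT)[0]
            synapse_plan.append((pre_l, post_l, k))
            pre_r_list = [m for m in sorted(by_type[t1]) if cells[m].side is Side.RIGHT]
            if not pre_r_list:
                continue  # midline presynaptic type: nothing to mirror
            pre_r = pre_r_list[0]
            if rng.random() < cc.mirror_noise:
                t2_new = types[int(rng.integers(len(types)))]
                post_r = members(t2_new, Side.RIGHT)[0]
                k_r = _synapse_count(rng, cc)
            else:
                post_r = members(t2, Side.RIGHT)[0]
                k_r = k
            synapse_plan.append((pre_r, post_r, k_r))

    # Fragments attach sparsely: a few synapses to/from random neurons.
    neuron_names = sorted(
        n
        for n, i in cells.items()
        if i.cell_class in (CellClass.SENSORY, CellClass.INTERNEURON, CellClass.MOTONEURON)
    )
    fragments = sorted(
        n for n, i in cells.items() if i.cell_class is CellClass.FRAGMENT
    )
    for frag in fragments:
        if not neuron_names or rng.random() >= cc.fragment_attach_prob:
            continue
        partner = neuron_names[int(rng.integers(len(neuron_names)))]
        k = _synapse_count(rng, cc)
        if rng.random() < 0.5:
            synapse_plan.append((frag, partner, k))
        else:
            synapse_plan.append((partner, frag, k))

    connectors: list[Connector] = []
    cid = 0
    for pre, post, k in synapse_plan:
        pre_sk = skeletons[sid_of_cell[pre]]
        post_sk = skeletons[sid_of_cell[post]]
        pre_nodes = sorted(pre_sk.nodes)
        post_nodes = sorted(post_sk.nodes)
        for _ in range(k):
            cid += 1
            connectors.append(
                Connector(
                    connector_id=cid,
                    pre_skeleton=pre_sk.skeleton_id,
                    pre_node=int(pre_nodes[rng.integers(len(pre_nodes))]),
                    post_skeleton=post_sk.skeleton_id,
                    post_node=int(post_nodes[rng.integers(len(post_nodes))]),
                )
            )
    if gt is not None:
        gt.module_of.update(module_of)
    return connectors, module_of


def generate_dataset(
    body: Optional[BodyPlanConfig] = None,
    conn: Optional[ConnectivityConfig] = None,
    geom: Optional[SkeletonGeometry] = None,
    seed: int = 0,
) -> tuple[Dataset, GroundTruth]:
    """Full pipeline: body plan -> skeletons -> synapses, with ground truth."""
    body = body or BodyPlanConfig(seed=seed)
    cells, gt = generate_body_plan(body)
    skeletons, name_map = generate_skeletons(cells, geom, seed=seed, gt=gt)
    connectors, _ = generate_synapses(
        cells, skeletons, name_map, conn, seed=seed, gt=gt
    )
    ds = Dataset(
        skeletons=skeletons,
        connectors=connectors,
        cells=dict(cells),
        skeleton_to_cell=dict(name_map),
    )
    return ds, gt


def planted_partition_graph(
    n_modules: int = 3,
    cells_per_module: int = 20,
    p_within: float = 0.4,
    p_between: float = 0.01,
    seed: int = 0,
) -> tuple[nx.DiGraph, dict[str, int]]:
    """Directed planted-partition benchmark graph with unit edge weights.

    Every ordered node pair gets an edge with probability ``p_within``
    inside a module and ``p_between`` across modules. Returns the graph
    and the ground-truth module labels.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    nodes = [
        f"m{m}_c{c}" for m in range(n_modules) for c in range(cells_per_module)
    ]
    labels = {
        f"m{m}_c{c}": m
        for m in range(n_modules)
        for c in range(cells_per_module)
    }
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for u in nodes:
        for v in nodes:
            if u == v:
                continue
            p = p_within if labels[u] == labels[v] else p_between
            if rng.random() < p:
                g.add_edge(u, v, weight=1)
    return g, labels
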