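"""Shared fixture builders: tiny hand-made datasets and skeletons."""

from __future__ import annotations

import numpy as np
import pytest

from platyconn.core import (
    CellClass,
    CellInfo,
    Connector,
    Dataset,
    Segment,
    Side,
    Skeleton,
    SkeletonNode,
)


def make_skeleton(
    skeleton_id: int,
    cell_name: str,
    points: list[tuple[float, float, float]],
    parents: list[int | None],
    soma: bool = True,
    radii: list[float] | None = None,
) -> Skeleton:
    nodes = {}
    for i, (p, par) in enumerate(zip(points, parents), start=1):
        tags = frozenset({"soma"}) if (soma and par is None) else frozenset()
        nodes[i] = SkeletonNode(
            node_id=i,
            parent_id=None if par is None else par + 1,
            x=float(p[0]),
            y=float(p[1]),
            z=float(p[2]),
            radius=float(radii[i - 1]) if radii else 0.0,
            tags=tags,
        )
    return Skeleton(skeleton_id=skeleton_id, cell_name=cell_name, nodes=nodes)


def line_skeleton(
    skeleton_id: int,
    cell_name: str,
    n: int,
    step_nm: float = 1000.0,
    soma: bool = True,
) -> Skeleton:
    pts = [(0.0, i * step_nm, 0.0) for i in range(n)]
    parents = [None] + list(range(n - 1))
    return make_skeleton(skeleton_id, cell_name, pts, parents, soma=soma)


def dataset_from_edges(
    edges: dict[tuple[str, str], int],
    classes: dict[str, CellClass] | None = None,
    types: dict[str, str] | None = None,
    segments: dict[str, Segment] | None = None,
    sides: dict[str, Side] | None = None,
    annotations: dict[str, set[str]] | None = None,
    extra_cells: list[str] = (),
) -> Dataset:
    """Build a minimal valid dataset realising a weighted edge list.

    Every cell gets a two-node skeleton; each synapse of edge (a, b) runs
    from a node of a's skeleton onto a node of b's skeleton.
    """
    classes = classes or {}
    names = sorted(
        {n for e in edges for n in e} | set(extra_cells) | set(classes)
    )
    ds = Dataset()
    for sid, name in enumerate(names, start=1):
        ds.skeletons[sid] = line_skeleton(sid, name, 2)
        ds.skeleton_to_cell[sid] = name
        ds.cells[name] = CellInfo(
            cell_name=name,
            cell_class=classes.get(name, CellClass.INTERNEURON),
            cell_type=(types or {}).get(name),
            segment=(segments or {}).get(name, Segment.NONE),
            side=(sides or {}).get(name, Side.NONE),
            annotations=frozenset((annotations or {}).get(name, set())),
        )
    sid_of = {name: sid for sid, name in ds.skeleton_to_cell.items()}
    cid = 0
    for (a, b), w in sorted(edges.items()):
        for _ in range(w):
            cid += 1
            ds.connectors.append(
                Connector(cid, sid_of[a], 2, sid_of[b], 1)
            )
    return ds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_small_dataset(seed: int, max_cells: int = 40) -> Dataset:
    """Random weighted digraph realised as a dataset — fast fuzz fixture."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_cells + 1))
    names = [f"c{i}" for i in range(n)]
    edges: dict[tuple[str, str], int] = {}
    n_edges = int(rng.integers(n, 4 * n))
    for _ in range(n_edges):
        a, b = rng.integers(0, n, 2)
        if a == b:
            continue
        key = (names[a], names[b])
        edges[key] = edges.get(key, 0) + int(rng.integers(1, 4))
    classes = {
        name: [
            CellClass.SENSORY,
            CellClass.INTERNEURON,
            CellClass.MOTONEURON,
            CellClass.EFFECTOR,
        ][int(rng.integers(0, 4))]
        for name in names
    }
    return dataset_from_edges(edges, classes=classes, extra_cells=names)
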