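"""Domain types and validation for whole-body connectome datasets.

The data model mirrors a CATMAID-style export: per-cell skeletons (rooted
trees of 3D nodes in nanometres), a connector table of monadic chemical
synapses (one presynaptic skeleton node onto one postsynaptic skeleton
node), and a per-cell annotation table carrying cell class, cell type,
body segment and body side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional


class CellClass(str, Enum):
    SENSORY = "sensory"
    INTERNEURON = "interneuron"
    MOTONEURON = "motoneuron"
    EFFECTOR = "effector"
    OTHER = "other_non_neuronal"
    FRAGMENT = "fragment"


#: Neuron classes in feed-forward order; effectors are terminal targets.
NEURON_CLASSES = (CellClass.SENSORY, CellClass.INTERNEURON, CellClass.MOTONEURON)

#: Rank used to orient sensory -> inter -> motor -> effector information flow.
CLASS_RANK = {
    CellClass.SENSORY: 0,
    CellClass.INTERNEURON: 1,
    CellClass.MOTONEURON: 2,
    CellClass.EFFECTOR: 3,
}


class Segment(str, Enum):
    HEAD = "head"
    SEGMENT_0 = "segment_0"
    SEGMENT_1 = "segment_1"
    SEGMENT_2 = "segment_2"
    SEGMENT_3 = "segment_3"
    PYGIDIUM = "pygidium"
    NONE = "none"


#: The six annotated body regions, anterior to posterior.
BODY_REGIONS = (
    Segment.HEAD,
    Segment.SEGMENT_0,
    Segment.SEGMENT_1,
    Segment.SEGMENT_2,
    Segment.SEGMENT_3,
    Segment.PYGIDIUM,
)

#: Everything posterior to the head counts as trunk in head-trunk censuses.
TRUNK_REGIONS = tuple(r for r in BODY_REGIONS if r is not Segment.HEAD)


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    MIDDLE = "middle"
    NONE = "none"


@dataclass(frozen=True)
class SkeletonNode:
    """One treenode of a skeleton; coordinates in nanometres."""

    node_id: int
    parent_id: Optional[int]  # None marks the root
    x: float
    y: float
    z: float
    radius: float = 0.0  # nm; 0 = unknown
    tags: frozenset[str] = frozenset()


@dataclass
class Skeleton:
    """A rooted tree tracing one cell or unattached fragment."""

    skeleton_id: int
    cell_name: str
    nodes: dict[int, SkeletonNode] = field(default_factory=dict)

    @property
    def has_soma(self) -> bool:
        return any("soma" in n.tags for n in self.nodes.values())

    @property
    def root_id(self) -> int:
        roots = [n.node_id for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise ValueError(
                f"skeleton {self.skeleton_id} ({self.cell_name}) has "
                f"{len(roots)} roots; expected exactly 1"
            )
        return roots[0]

    def edges(self) -> Iterator[tuple[SkeletonNode, SkeletonNode]]:
        """Yield (parent, child) node pairs."""
        for n in self.nodes.values():
            if n.parent_id is not None:
                yield self.nodes[n.parent_id], n

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for n in self.nodes.values():
            if n.parent_id is not None:
                out[n.parent_id].append(n.node_id)
        return out


@dataclass(frozen=True)
class Connector:
    """One monadic chemical synapse: pre skeleton node -> post skeleton node."""

    connector_id: int
    pre_skeleton: int
    pre_node: int
    post_skeleton: int
    post_node: int


@dataclass
class CellInfo:
    cell_name: str
    cell_class: CellClass
    cell_type: Optional[str] = None  # e.g. "celltype23"; one type per cell
    segment: Segment = Segment.NONE
    side: Side = Side.NONE
    annotations: frozenset[str] = frozenset()


@dataclass
class Dataset:
    """Container tying skeletons, connectors and cell annotations together."""

    skeletons: dict[int, Skeleton] = field(default_factory=dict)
    connectors: list[Connector] = field(default_factory=list)
    cells: dict[str, CellInfo] = field(default_factory=dict)
    skeleton_to_cell: dict[int, str] = field(default_factory=dict)

    def cell_of(self, skeleton_id: int) -> str:
        return self.skeleton_to_cell[skeleton_id]

    def skeleton_of_cell(self, cell_name: str) -> Skeleton:
        for sid, name in self.skeleton_to_cell.items():
            if name == cell_name:
                return self.skeletons[sid]
        raise KeyError(cell_name)


@dataclass(frozen=True)
class Violation:
    """One invariant breach found by :func:`validate`."""

    entity: str
    rule: str
    message: str


def _skeleton_violations(sk: Skeleton) -> list[Violation]:
    out = []
    ent = f"skeleton {sk.skeleton_id} ({sk.cell_name})"
    roots = [n for n in sk.nodes.values() if n.parent_id is None]
    if len(roots) != 1:
        out.append(
            Violation(ent, "single root", f"found {len(roots)} root nodes")
        )
    for n in sk.nodes.values():
        if n.parent_id is not None and n.parent_id not in sk.nodes:
            out.append(
                Violation(
                    ent,
                    "parent reference",
                    f"node {n.node_id} references absent parent {n.parent_id}",
                )
            )
    # Acyclicity: walk each node towards the root, flag revisits.
    seen_ok: set[int] = set()
    for start in sk.nodes:
        trail: list[int] = []
        cur: Optional[int] = start
        while cur is not None and cur in sk.nodes and cur not in seen_ok:
            if cur in trail:
                out.append(
                    Violation(
                        ent, "acyclicity", f"parent cycle through node {cur}"
                    )
                )
                break
            trail.append(cur)
            cur = sk.nodes[cur].parent_id
        else:
            seen_ok.update(trail)
    return out


def validate(ds: Dataset) -> list[Violation]:
    """Check every dataset invariant; report violations, never raise.

    Returns an empty list iff the dataset is well formed.
    """
    out: list[Violation] = []
    for sk in ds.skeletons.values():
        out.extend(_skeleton_violations(sk))
        if sk.skeleton_id not in ds.skeleton_to_cell:
            out.append(
                Violation(
                    f"skeleton {sk.skeleton_id}",
                    "cell mapping",
                    "skeleton maps to no cell_name",
                )
            )
        elif ds.skeleton_to_cell[sk.skeleton_id] not in ds.cells:
            out.append(
                Violation(
                    f"skeleton {sk.skeleton_id}",
                    "cell mapping",
                    f"maps to unknown cell "
                    f"{ds.skeleton_to_cell[sk.skeleton_id]!r}",
                )
            )
    for c in ds.connectors:
        ent = f"connector {c.connector_id}"
        for role, sid, nid in (
            ("pre", c.pre_skeleton, c.pre_node),
            ("post", c.post_skeleton, c.post_node),
        ):
            if sid not in ds.skeletons:
                out.append(
                    Violation(
                        ent,
                        "endpoint resolution",
                        f"{role} skeleton {sid} not in dataset",
                    )
                )
            elif nid not in ds.skeletons[sid].nodes:
                out.append(
                    Violation(
                        ent,
                        "endpoint resolution",
                        f"{role} node {nid} not in skeleton {sid}",
                    )
                )
    for info in ds.cells.values():
        if info.cell_class is CellClass.FRAGMENT and (
            info.cell_type is not None or info.segment is not Segment.NONE
        ):
            out.append(
                Violation(
                    f"cell {info.cell_name}",
                    "fragment typing",
                    "fragments must carry no cell_type or segment",
                )
            )
    return out
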