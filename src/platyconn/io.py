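"""Read and write the interchange formats: SWC skeletons + TSV tables.

One SWC file per skeleton (``<cell_name>.swc``), the standard seven-column
layout (index, structure type, x, y, z, radius, parent; parent -1 = root;
type 1 = soma, 0 = undefined). Node tags other than "soma" cannot live in
the type column, so they are preserved in ``# tag <node_id> <tag>`` header
comments, which any standard SWC reader ignores.

``connectors.tsv``: connector_id, pre_skeleton, pre_node, post_skeleton,
post_node. ``annotations.tsv``: cell_name, skeleton_id, cell_class,
cell_type, segment, side, annotations (semicolon-joined).

The pair :func:`read_dataset` / :func:`write_dataset` is an exact
round-trip: serialisation is deterministic (sorted ids, ``repr`` floats).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .core import (
    CellClass,
    CellInfo,
    Connector,
    Dataset,
    Segment,
    Side,
    Skeleton,
    SkeletonNode,
    validate,
)

CONNECTOR_COLUMNS = [
    "connector_id",
    "pre_skeleton",
    "pre_node",
    "post_skeleton",
    "post_node",
]
ANNOTATION_COLUMNS = [
    "cell_name",
    "skeleton_id",
    "cell_class",
    "cell_type",
    "segment",
    "side",
    "annotations",
]


def _fmt(x: float) -> str:
    return repr(float(x))


def write_swc(sk: Skeleton, path: Path) -> None:
    lines = [f"# skeleton_id {sk.skeleton_id}", f"# cell_name {sk.cell_name}"]
    for nid in sorted(sk.nodes):
        for tag in sorted(sk.nodes[nid].tags - {"soma"}):
            lines.append(f"# tag {nid} {tag}")
    for nid in sorted(sk.nodes):
        n = sk.nodes[nid]
        stype = 1 if "soma" in n.tags else 0
        parent = -1 if n.parent_id is None else n.parent_id
        lines.append(
            f"{n.node_id} {stype} {_fmt(n.x)} {_fmt(n.y)} {_fmt(n.z)} "
            f"{_fmt(n.radius)} {parent}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_swc(path: Path) -> Skeleton:
    skeleton_id: Optional[int] = None
    cell_name = path.stem
    extra_tags: dict[int, set[str]] = {}
    nodes: dict[int, SkeletonNode] = {}
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) >= 2 and parts[0] == "skeleton_id":
                skeleton_id = int(parts[1])
            elif len(parts) >= 2 and parts[0] == "cell_name":
                cell_name = parts[1]
            elif len(parts) >= 3 and parts[0] == "tag":
                extra_tags.setdefault(int(parts[1]), set()).add(
                    " ".join(parts[2:])
                )
            continue
        cols = line.split()
        if len(cols) != 7:
            raise ValueError(f"{path}: malformed SWC row {line!r}")
        nid, stype, parent = int(cols[0]), int(cols[1]), int(cols[6])
        if nid in nodes:
            raise ValueError(f"{path}: duplicate node id {nid}")
        tags = set(extra_tags.get(nid, set()))
        if stype == 1:
            tags.add("soma")
        nodes[nid] = SkeletonNode(
            node_id=nid,
            parent_id=None if parent == -1 else parent,
            x=float(cols[2]),
            y=float(cols[3]),
            z=float(cols[4]),
            radius=float(cols[5]),
            tags=frozenset(tags),
        )
    if skeleton_id is None:
        raise ValueError(f"{path}: missing '# skeleton_id' header")
    sk = Skeleton(skeleton_id=skeleton_id, cell_name=cell_name, nodes=nodes)
    roots = [n for n in nodes.values() if n.parent_id is None]
    if len(roots) != 1:
        raise ValueError(
            f"{path}: skeleton {skeleton_id} has {len(roots)} roots"
        )
    return sk


def write_dataset(ds: Dataset, out_dir: Path | str) -> None:
    """Emit one SWC per skeleton plus connectors.tsv and annotations.tsv."""
    out_dir = Path(out_dir)
    skel_dir = out_dir / "skeletons"
    skel_dir.mkdir(parents=True, exist_ok=True)
    for sid in sorted(ds.skeletons):
        sk = ds.skeletons[sid]
        write_swc(sk, skel_dir / f"{sk.cell_name}.swc")

    conn = pd.DataFrame(
        [
            (c.connector_id, c.pre_skeleton, c.pre_node, c.post_skeleton, c.post_node)
            for c in sorted(ds.connectors, key=lambda c: c.connector_id)
        ],
        columns=CONNECTOR_COLUMNS,
    )
    conn.to_csv(out_dir / "connectors.tsv", sep="\t", index=False)

    name_to_sid = {v: k for k, v in ds.skeleton_to_cell.items()}
    rows = []
    for name in sorted(ds.cells):
        info = ds.cells[name]
        rows.append(
            (
                name,
                name_to_sid.get(name, -1),
                info.cell_class.value,
                info.cell_type if info.cell_type is not None else "",
                info.segment.value,
                info.side.value,
                ";".join(sorted(info.annotations)),
            )
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        out_dir / "annotations.tsv", sep="\t", index=False
    )


def _read_annotations(path: Path) -> list[dict]:
    if path.suffix == ".json":
        return json.loads(path.read_text())
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return df.to_dict("records")


def read_dataset(
    skeleton_dir: Path | str,
    connectors: Path | str,
    annotations: Path | str,
    check: bool = True,
) -> Dataset:
    """Load a dataset from interchange files and validate referential integrity.

    Raises ``ValueError`` on a connector referencing an absent skeleton or
    node (naming the connector), a duplicated cell name, or a skeleton with
    more than one root.
    """
    skeleton_dir = Path(skeleton_dir)
    ds = Dataset()
    for swc in sorted(skeleton_dir.glob("*.swc")):
        sk = read_swc(swc)
        if sk.skeleton_id in ds.skeletons:
            raise ValueError(f"duplicate skeleton_id {sk.skeleton_id}")
        ds.skeletons[sk.skeleton_id] = sk

    for rec in _read_annotations(Path(annotations)):
        name = rec["cell_name"]
        if name in ds.cells:
            raise ValueError(f"duplicate cell_name {name!r}")
        ann = rec.get("annotations", "")
        if isinstance(ann, str):
            ann = [a for a in ann.split(";") if a]
        ctype = rec.get("cell_type") or None
        ds.cells[name] = CellInfo(
            cell_name=name,
            cell_class=CellClass(rec["cell_class"]),
            cell_type=ctype,
            segment=Segment(rec.get("segment") or "none"),
            side=Side(rec.get("side") or "none"),
            annotations=frozenset(ann),
        )
        sid = int(rec["skeleton_id"])
        if sid >= 0:
            ds.skeleton_to_cell[sid] = name

    conn = pd.read_csv(Path(connectors), sep="\t")
    for rec in conn.to_dict("records"):
        c = Connector(
            connector_id=int(rec["connector_id"]),
            pre_skeleton=int(rec["pre_skeleton"]),
            pre_node=int(rec["pre_node"]),
            post_skeleton=int(rec["post_skeleton"]),
            post_node=int(rec["post_node"]),
        )
        if check:
            for role, sid, nid in (
                ("pre", c.pre_skeleton, c.pre_node),
                ("post", c.post_skeleton, c.post_node),
            ):
                if sid not in ds.skeletons:
                    raise ValueError(
                        f"connector {c.connector_id}: {role} skeleton "
                        f"{sid} not in dataset"
                    )
                if nid not in ds.skeletons[sid].nodes:
                    raise ValueError(
                        f"connector {c.connector_id}: {role} node {nid} "
                        f"not in skeleton {sid}"
                    )
        ds.connectors.append(c)

    if check:
        bad = [
            v
            for v in validate(ds)
            if v.rule in ("single root", "cell mapping")
        ]
        if bad:
            raise ValueError("; ".join(f"{v.entity}: {v.message}" for v in bad))
    return ds
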