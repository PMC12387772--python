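"""Machine-readable dataset summaries and graph export."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .core import CellClass, Dataset
from .graphs import graph_density


def pct(numerator: float, denominator: float) -> float:
    """Percentage of a printed-count ratio (raw double, no rounding)."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return 100.0 * numerator / denominator


@dataclass
class DatasetReport:
    n_cells_with_soma: int
    n_fragments: int
    n_nodes_total: int
    n_nodes_on_fragments: int
    n_pre_total: int
    n_pre_on_fragments: int
    n_post_total: int
    n_post_on_fragments: int
    fraction_nodes_on_fragments: float
    fraction_pre_on_fragments: float
    fraction_post_on_fragments: float
    connectome_nodes: int
    connectome_edges: int
    connectome_synapses: int
    density: float
    n_types_per_class: dict[str, int] = field(default_factory=dict)
    n_cell_types_total: int = 0
    fraction_types_with_transmitter: float = float("nan")

    def to_json(self, path: Path | str | None = None) -> str:
        """Serialise; percentages are additionally given at 1 decimal place."""
        d = asdict(self)
        for key in (
            "fraction_nodes_on_fragments",
            "fraction_pre_on_fragments",
            "fraction_post_on_fragments",
            "fraction_types_with_transmitter",
        ):
            if d[key] == d[key]:  # skip NaN
                d[f"{key}_pct_1dp"] = round(d[key], 1)
        text = json.dumps(d, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def dataset_report(ds: Dataset, g: nx.DiGraph) -> DatasetReport:
    """Assemble the dataset-level census: skeleton totals, fragment shares,
    connectome size/density, and the cell-type census per class.

    The transmitter-assignment fraction counts neuronal cell types where
    any member cell carries an annotation starting with ``transmitter:``.
    """
    frag_sids = {
        sid
        for sid, name in ds.skeleton_to_cell.items()
        if ds.cells[name].cell_class is CellClass.FRAGMENT
    }
    n_nodes = sum(len(sk.nodes) for sk in ds.skeletons.values())
    n_nodes_frag = sum(
        len(sk.nodes) for sid, sk in ds.skeletons.items() if sid in frag_sids
    )
    n_pre = len(ds.connectors)
    n_post = len(ds.connectors)
    n_pre_frag = sum(1 for c in ds.connectors if c.pre_skeleton in frag_sids)
    n_post_frag = sum(1 for c in ds.connectors if c.post_skeleton in frag_sids)

    types_per_class: dict[str, set[str]] = {}
    transmitter_types: set[str] = set()
    neuron_types: set[str] = set()
    for info in ds.cells.values():
        if info.cell_type is None:
            continue
        types_per_class.setdefault(info.cell_class.value, set()).add(info.cell_type)
        if info.cell_class in (
            CellClass.SENSORY,
            CellClass.INTERNEURON,
            CellClass.MOTONEURON,
        ):
            neuron_types.add(info.cell_type)
            if any(a.startswith("transmitter:") for a in info.annotations):
                transmitter_types.add(info.cell_type)

    census = {k: len(v) for k, v in sorted(types_per_class.items())}
    return DatasetReport(
        n_cells_with_soma=sum(
            1
            for info in ds.cells.values()
            if info.cell_class is not CellClass.FRAGMENT
        ),
        n_fragments=sum(
            1
            for info in ds.cells.values()
            if info.cell_class is CellClass.FRAGMENT
        ),
        n_nodes_total=n_nodes,
        n_nodes_on_fragments=n_nodes_frag,
        n_pre_total=n_pre,
        n_pre_on_fragments=n_pre_frag,
        n_post_total=n_post,
        n_post_on_fragments=n_post_frag,
        fraction_nodes_on_fragments=pct(n_nodes_frag, n_nodes) if n_nodes else 0.0,
        fraction_pre_on_fragments=pct(n_pre_frag, n_pre) if n_pre else 0.0,
        fraction_post_on_fragments=pct(n_post_frag, n_post) if n_post else 0.0,
        connectome_nodes=g.number_of_nodes(),
        connectome_edges=g.number_of_edges(),
        connectome_synapses=sum(d["weight"] for _, _, d in g.edges(data=True)),
        density=graph_density(g),
        n_types_per_class=census,
        n_cell_types_total=sum(census.values()),
        fraction_types_with_transmitter=(
            pct(len(transmitter_types), len(neuron_types))
            if neuron_types
            else float("nan")
        ),
    )


_FORMATS = ("graphml", "gexf", "edge-tsv")


def export_graph(g: nx.DiGraph, path: Path | str, format: str = "graphml") -> None:
    """Write a graph losslessly (node attributes, weights, module labels)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "gexf":
        nx.write_gexf(g, path)
    elif format == "edge-tsv":
        rows = [
            {"source": u, "target": v, **d} for u, v, d in g.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")


def import_graph(path: Path | str, format: str = "graphml") -> nx.DiGraph:
    """Read back a graph written by :func:`export_graph` (not edge-tsv)."""
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "gexf":
        return nx.read_gexf(path)
    raise ValueError(f"unknown or write-only format {format!r}")
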