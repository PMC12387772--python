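"""Left-right stereotypy of connectivity and morphology.

Most cell types in a bilaterian larva come as one left and one right
homolog. Connectivity stereotypy is quantified by building two type-level
synapse matrices — one restricted to left-side presynaptic cells, one to
right-side — and correlating their entries (Pearson, raw counts, zeros
included). Morphological stereotypy compares Sholl profiles of the two
homologous skeletons on a shared radius grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import CellClass, CellInfo, Side, Skeleton
from .morphometry import sholl


@dataclass
class HomologPairing:
    pairs: list[tuple[str, str]]  # (left cell, right cell)
    pair_type: dict[str, tuple[str, str]]  # cell_type -> pair
    unpaired: dict[str, str]  # cell_type -> reason


def pair_homologs(cells: Mapping[str, CellInfo]) -> HomologPairing:
    """Pair left/right cells per cell type.

    Only types with exactly one left and one right member form a pair;
    midline types and types with unbalanced member counts are listed
    unpaired with the reason.
    """
    by_type: dict[str, list[CellInfo]] = {}
    for info in cells.values():
        if info.cell_type is not None and info.cell_class is not CellClass.FRAGMENT:
            by_type.setdefault(info.cell_type, []).append(info)
    pairs: list[tuple[str, str]] = []
    pair_type: dict[str, tuple[str, str]] = {}
    unpaired: dict[str, str] = {}
    for t in sorted(by_type):
        members = by_type[t]
        left = sorted(m.cell_name for m in members if m.side is Side.LEFT)
        right = sorted(m.cell_name for m in members if m.side is Side.RIGHT)
        other = [m for m in members if m.side not in (Side.LEFT, Side.RIGHT)]
        if len(left) == 1 and len(right) == 1 and not other:
            pairs.append((left[0], right[0]))
            pair_type[t] = (left[0], right[0])
        elif other and not left and not right:
            unpaired[t] = "middle"
        else:
            unpaired[t] = "unbalanced"
    return HomologPairing(pairs=pairs, pair_type=pair_type, unpaired=unpaired)


@dataclass
class SideMatrices:
    types: list[str]  # shared row/column order
    left: pd.DataFrame  # synapses from left members of row type onto col type
    right: pd.DataFrame


def side_matrices(
    g: nx.DiGraph,
    cells: Mapping[str, CellInfo],
    scope: Optional[Sequence[str]] = None,
) -> SideMatrices:
    """Type-level synapse matrices split by presynaptic body side.

    Entry ``left[T1, T2]`` sums synapses from the left member of type T1
    onto members of T2 on either side; the right matrix is defined in
    mirror. Both matrices share the paired-type index; zero entries are
    retained. Types without a clean left/right pair are excluded.
    """
    pairing = pair_homologs(cells)
    types = sorted(pairing.pair_type)
    if scope is not None:
        scope_set = set(scope)
        types = [t for t in types if t in scope_set]
    if not types:
        raise ValueError("no left-right paired types available")
    tindex = {t: i for i, t in enumerate(types)}
    side_of_pre: dict[str, tuple[str, Side]] = {}
    member_type: dict[str, str] = {}
    for t, (lcell, rcell) in pairing.pair_type.items():
        if t not in tindex:
            continue
        side_of_pre[lcell] = (t, Side.LEFT)
        side_of_pre[rcell] = (t, Side.RIGHT)
        member_type[lcell] = t
        member_type[rcell] = t
    n = len(types)
    left = np.zeros((n, n), dtype=int)
    right = np.zeros((n, n), dtype=int)
    for u, v, d in g.edges(data=True):
        if u not in side_of_pre or v not in member_type:
            continue
        t1, side = side_of_pre[u]
        t2 = member_type[v]
        mat = left if side is Side.LEFT else right
        mat[tindex[t1], tindex[t2]] += d["weight"]
    return SideMatrices(
        types=types,
        left=pd.DataFrame(left, index=types, columns=types),
        right=pd.DataFrame(right, index=types, columns=types),
    )


def lr_correlation(m: SideMatrices, transform: Optional[str] = None) -> float:
    """Pearson correlation of the flattened left/right matrices.

    ``transform='sqrt'`` correlates square-rooted counts instead of raw
    ones. Raises on constant matrices (correlation undefined).
    """
    a = m.left.to_numpy(dtype=float).ravel()
    b = m.right.to_numpy(dtype=float).ravel()
    if transform == "sqrt":
        a, b = np.sqrt(a), np.sqrt(b)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("undefined correlation: constant side matrix")
    if np.array_equal(a, b):  # perfect mirror symmetry is exactly 1
        return 1.0
    return float(stats.pearsonr(a, b).statistic)


def sholl_similarity(
    left: Skeleton, right: Skeleton, step: float
) -> float:
    """Pearson correlation of two Sholl profiles on a shared radius grid.

    The grid extends to the larger of the two skeleton extents so both
    profiles cover identical radii (shorter one padded with zeros by
    construction). A mirror-image pair correlates at exactly 1.
    """
    if len(left.nodes) < 2 or len(right.nodes) < 2:
        raise ValueError("degenerate single-node skeleton")

    def _extent(sk: Skeleton) -> float:
        root = sk.nodes[sk.root_id]
        r0 = np.array([root.x, root.y, root.z])
        return max(
            float(np.linalg.norm(np.array([n.x, n.y, n.z]) - r0))
            for n in sk.nodes.values()
        )

    extent = max(_extent(left), _extent(right))
    pl = sholl(left, step, max_radius=extent)
    pr = sholl(right, step, max_radius=extent)
    a = pl.crossings.astype(float)
    b = pr.crossings.astype(float)
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("undefined correlation: constant Sholl profile")
    return float(stats.pearsonr(a, b).statistic)
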