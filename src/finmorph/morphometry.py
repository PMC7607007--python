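"""Interbranch re-segmentation and the 13-parameter morphometric feature vector.

A traced afferent is re-segmented into *interbranch segments*: maximal node
paths between consecutive critical nodes (soma, branch point, terminal).
Eleven tree-shape parameters are computed from the segments, and two supplied
soma scalars (soma area, anteroposterior soma position) complete the
13-parameter vector used for neuron classification:

1. number of branch points
2. maximum branch order (branch points on the deepest root-to-tip path, + 1)
3. Strahler number (terminals = 1; a parent increments when its maximal
   daughters tie, otherwise inherits the maximum)
4. mean partition asymmetry, ``|l - r| / (l + r - 2)`` over bifurcations with
   subtree tip counts ``l, r`` where ``l + r > 2``
5. maximum path distance from the soma to any terminal (μm)
6. mean contraction (chord length / arc length per segment; 1 = straight)
7. mean branch angle (amplitude between the immediate daughter nodes, degrees)
8. mean local angle (amplitude ``local_offset`` nodes into each daughter)
9. mean remote angle (amplitude at the daughters' next critical nodes)
10. mean fractal dimension (per-segment log-log slope of cumulative path
    length against chord length; exactly 1 for a straight segment)
11. total length of all segments (μm)
12. soma area (μm², pass-through)
13. anteroposterior soma position (μm, signed, pass-through)

Metrics can be restricted to a label subset — typically the fin surface
labels — in which case the subtree induced by the labeled nodes is analyzed,
optionally together with the unbranched processes leading from the soma to
the fin (``include_root_path``), mirroring how fin afferents are quantified
"from the initial branch off the soma".

Quantities that are undefined on a given tree (angles and partition asymmetry
on an unbranched afferent) are reported as NaN sentinels; downstream
clustering imputes them per column with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np

from .swc_io import FIN_LABELS, NeuronMetadata, NeuronTree

__all__ = [
    "InterbranchSegment",
    "FeatureVector",
    "FEATURE_COLUMNS",
    "DisconnectedSelectionError",
    "EmptySelectionError",
    "resegment",
    "topology_metrics",
    "geometry_metrics",
    "angle_metrics",
    "feature_vector",
    "restricted_length",
]

#: Column order of the exported feature table (11 tree + 2 soma parameters).
FEATURE_COLUMNS = [
    "n_branch_points",
    "max_branch_order",
    "strahler",
    "mean_partition_asymmetry",
    "max_path_distance",
    "mean_contraction",
    "mean_branch_angle",
    "mean_local_angle",
    "mean_remote_angle",
    "mean_fractal_dimension",
    "total_length",
    "soma_area",
    "ap_position",
]

#: Minimum nodes for the per-segment fractal-dimension regression.
MIN_FRACTAL_NODES = 5

#: Default node offset for the local angle.
DEFAULT_LOCAL_OFFSET = 10


class EmptySelectionError(ValueError):
    """The restriction selects no nodes."""


class DisconnectedSelectionError(ValueError):
    """The restriction selects a disconnected node set (and no root path was requested)."""


@dataclass(frozen=True)
class InterbranchSegment:
    """A maximal path between consecutive critical nodes.

    ``node_ids[0]`` is a critical node (subtree root or branch point) and
    ``node_ids[-1]`` the next critical node (branch point or terminal);
    interior nodes have exactly one child.  ``branch_order`` counts the branch
    points on the path from the soma to the segment's start, start included.
    """

    node_ids: tuple[int, ...]
    arc_length: float
    euclidean_length: float
    branch_order: int

    def __len__(self) -> int:
        return len(self.node_ids)


# ---------------------------------------------------------------------------
# Subtree selection
# ---------------------------------------------------------------------------

class _Subtree:
    """Restriction of a tree to a node subset, re-rooted at its highest node."""

    __slots__ = ("tree", "root", "children", "nodes")

    def __init__(self, tree: NeuronTree, root: int, children: dict[int, list[int]]):
        self.tree = tree
        self.root = root
        self.children = children
        self.nodes = set(children)


def _select_subtree(
    tree: NeuronTree,
    restriction: Sequence[str] | str = "all",
    include_root_path: bool = True,
) -> _Subtree:
    if restriction == "all":
        children = {nid: list(tree.children(nid)) for nid in tree.node_ids}
        return _Subtree(tree, tree.root_id, children)

    labels = set(restriction)
    selected = {nid for nid in tree.node_ids if tree.label(nid) in labels}
    if not selected:
        raise EmptySelectionError(f"no nodes carry any of the labels {sorted(labels)}")

    if include_root_path:
        # Close the selection upward so that it is a single tree rooted at the
        # soma; the added nodes are the "processes leading up" to the region.
        closure: set[int] = set()
        for nid in selected:
            cur = nid
            while cur != -1 and cur not in closure:
                closure.add(cur)
                cur = tree.parent(cur)
        selected = closure
        root = tree.root_id
    else:
        # The induced node set must itself be connected.
        tops = [nid for nid in selected if tree.parent(nid) not in selected]
        if len(tops) != 1:
            raise DisconnectedSelectionError(
                f"restriction selects {len(tops)} disconnected components "
                f"with top nodes {sorted(tops)}"
            )
        root = tops[0]

    children = {
        nid: [c for c in tree.children(nid) if c in selected] for nid in selected
    }
    return _Subtree(tree, root, children)


def _postorder(sub: _Subtree) -> list[int]:
    """Iterative post-order over the subtree (children before parents)."""
    order: list[int] = []
    stack: list[int] = [sub.root]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(sub.children[nid])
    order.reverse()
    return order


# ---------------------------------------------------------------------------
# Re-segmentation
# ---------------------------------------------------------------------------

def _segment_paths(sub: _Subtree) -> list[tuple[int, ...]]:
    """Node paths of every interbranch segment, in deterministic DFS order."""
    paths: list[tuple[int, ...]] = []
    stack: list[int] = [sub.root]
    while stack:
        start = stack.pop()
        for first in reversed(sub.children[start]):
            path = [start, first]
            cur = first
            while len(sub.children[cur]) == 1:
                cur = sub.children[cur][0]
                path.append(cur)
            paths.append(tuple(path))
            if sub.children[cur]:
                stack.append(cur)
    return paths


def _branch_orders(sub: _Subtree) -> dict[int, int]:
    """Branch points on the root path of each node (node itself included)."""
    orders: dict[int, int] = {}
    stack: list[tuple[int, int]] = [(sub.root, 0)]
    while stack:
        nid, upstream = stack.pop()
        here = upstream + (1 if len(sub.children[nid]) >= 2 else 0)
        orders[nid] = here
        for c in sub.children[nid]:
            stack.append((c, here))
    return orders


def resegment(
    tree: NeuronTree,
    restriction: Sequence[str] | str = "all",
    include_root_path: bool = True,
) -> list[InterbranchSegment]:
    """Split the (restricted) tree into interbranch segments.

    For a tree whose root bears a single stem, the number of segments equals
    the number of terminals plus the number of branch points, a multifurcation
    of arity ``a`` yielding ``a`` child segments but counting once.
    """
    sub = _select_subtree(tree, restriction, include_root_path)
    orders = _branch_orders(sub)
    segments = []
    for path in _segment_paths(sub):
        pos = np.array([tree.position(n) for n in path])
        steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        arc = float(steps.sum())
        chord = float(np.linalg.norm(pos[-1] - pos[0]))
        # order at the segment start (branch points from soma up to and
        # including the start node)
        segments.append(InterbranchSegment(path, arc, chord, orders[path[0]]))
    return segments


# ---------------------------------------------------------------------------
# Topology metrics
# ---------------------------------------------------------------------------

def _tip_counts(sub: _Subtree) -> dict[int, int]:
    counts: dict[int, int] = {}
    for nid in _postorder(sub):
        ch = sub.children[nid]
        counts[nid] = 1 if not ch else sum(counts[c] for c in ch)
    return counts


def _strahler_numbers(sub: _Subtree) -> dict[int, int]:
    strahler: dict[int, int] = {}
    for nid in _postorder(sub):
        ch = sub.children[nid]
        if not ch:
            strahler[nid] = 1
        else:
            vals = [strahler[c] for c in ch]
            m = max(vals)
            strahler[nid] = m + 1 if vals.count(m) >= 2 else m
    return strahler


def _pair_asymmetries(sub: _Subtree) -> list[float]:
    tips = _tip_counts(sub)
    out: list[float] = []
    for nid in sub.nodes:
        ch = sub.children[nid]
        if len(ch) < 2:
            continue
        counts = [tips[c] for c in ch]
        for i in range(len(counts)):
            for j in range(i + 1, len(counts)):
                l, r = counts[i], counts[j]
                if l + r > 2:
                    out.append(abs(l - r) / (l + r - 2))
    return out


def topology_metrics(
    tree: NeuronTree,
    restriction: Sequence[str] | str = "all",
    include_root_path: bool = True,
) -> tuple[int, int, int, float]:
    """Return (n_branch_points, max_branch_order, strahler, mean_partition_asymmetry).

    On an unbranched selection: 0 branch points, order 1, Strahler 1 and a NaN
    asymmetry sentinel.  Multifurcations contribute every unordered daughter
    pair to the asymmetry average; (1,1) bifurcations are undefined and
    excluded.
    """
    sub = _select_subtree(tree, restriction, include_root_path)
    n_branch = sum(1 for nid in sub.nodes if len(sub.children[nid]) >= 2)
    orders = _branch_orders(sub)
    terminals = [nid for nid in sub.nodes if not sub.children[nid]]
    max_order = max((orders[t] for t in terminals), default=0) + 1
    strahler = _strahler_numbers(sub)[sub.root]
    asyms = _pair_asymmetries(sub)
    mean_asym = float(np.mean(asyms)) if asyms else math.nan
    return n_branch, max_order, strahler, mean_asym


# ---------------------------------------------------------------------------
# Geometry metrics
# ---------------------------------------------------------------------------

def _segment_fractal_dimension(positions: np.ndarray) -> float:
    """Log-log slope of cumulative path length vs. chord length along a segment."""
    steps = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    cum_path = np.cumsum(steps)
    chords = np.linalg.norm(positions[1:] - positions[0], axis=1)
    ok = (cum_path > 0) & (chords > 0)
    if ok.sum() < 2:
        return math.nan
    x = np.log(chords[ok])
    y = np.log(cum_path[ok])
    if np.ptp(x) < 1e-12:
        return math.nan
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def geometry_metrics(
    tree: NeuronTree,
    restriction: Sequence[str] | str = "all",
    include_root_path: bool = True,
) -> tuple[float, float, float, float]:
    """Return (max_path_distance, mean_contraction, mean_fractal_dimension, total_length).

    Contraction is chord/arc per segment averaged over segments; segments of
    zero arc length are excluded from the ratio averages.  The fractal
    dimension needs at least ``MIN_FRACTAL_NODES`` nodes per segment.
    """
    sub = _select_subtree(tree, restriction, include_root_path)
    segments = resegment(tree, restriction, include_root_path)
    total = float(sum(s.arc_length for s in segments))

    # deepest root-to-terminal path distance
    dist: dict[int, float] = {sub.root: 0.0}
    stack = [sub.root]
    max_path = 0.0
    while stack:
        nid = stack.pop()
        ch = sub.children[nid]
        if not ch:
            max_path = max(max_path, dist[nid])
        p = tree.position(nid)
        for c in ch:
            dist[c] = dist[nid] + float(np.linalg.norm(tree.position(c) - p))
            stack.append(c)

    contractions = [
        s.euclidean_length / s.arc_length for s in segments if s.arc_length > 0
    ]
    if len(contractions) < len(segments):
        warnings.warn("segments with zero arc length excluded from contraction average")
    mean_contraction = float(np.mean(contractions)) if contractions else math.nan

    fds = []
    for s in segments:
        if len(s) < MIN_FRACTAL_NODES or s.arc_length <= 0:
            continue
        pos = np.array([tree.position(n) for n in s.node_ids])
        fd = _segment_fractal_dimension(pos)
        if math.isfinite(fd):
            fds.append(fd)
    mean_fd = float(np.mean(fds)) if fds else math.nan

    return max_path, mean_contraction, mean_fd, total


def restricted_length(tree: NeuronTree, labels: Sequence[str]) -> float:
    """Summed length of edges whose child node carries one of ``labels``.

    This edge-labeled total is additive over a label partition of the tree
    (unlike the feature-vector total, which may include the unlabeled path
    from the soma to the region of interest).
    """
    label_set = set(labels)
    return float(
        sum(
            tree.edge_length(child)
            for _, child in tree.edges()
            if tree.label(child) in label_set
        )
    )


# ---------------------------------------------------------------------------
# Angle metrics
# ---------------------------------------------------------------------------

def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return math.nan
    c = float(np.dot(v1, v2) / (n1 * n2))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def angle_metrics(
    tree: NeuronTree,
    restriction: Sequence[str] | str = "all",
    include_root_path: bool = True,
    local_offset: int = DEFAULT_LOCAL_OFFSET,
) -> tuple[float, float, float]:
    """Return (mean_branch_angle, mean_local_angle, mean_remote_angle) in degrees.

    At every branch point, for every unordered daughter pair, three amplitude
    angles between vectors rooted at the branch point are measured: to the
    immediate daughter nodes (branch angle), to the nodes ``local_offset``
    trace nodes into each daughter (local angle; clamped to the daughter
    segment's end when it is shorter), and to each daughter's next critical
    node (remote angle).  Averages are unweighted over all pairs; trees
    without branch points report NaN sentinels.
    """
    if local_offset < 1:
        raise ValueError("local_offset must be >= 1")
    sub = _select_subtree(tree, restriction, include_root_path)

    # daughter path from each branch point child to its next critical node
    def daughter_path(branch: int, first: int) -> list[int]:
        path = [branch, first]
        cur = first
        while len(sub.children[cur]) == 1:
            cur = sub.children[cur][0]
            path.append(cur)
        return path

    branch_angles: list[float] = []
    local_angles: list[float] = []
    remote_angles: list[float] = []
    for nid in sub.nodes:
        ch = sub.children[nid]
        if len(ch) < 2:
            continue
        origin = tree.position(nid)
        paths = [daughter_path(nid, c) for c in ch]
        for i in range(len(paths)):
            for j in range(i + 1, len(paths)):
                pi, pj = paths[i], paths[j]
                trio = []
                for pick in (
                    lambda p: p[1],  # immediate
                    lambda p: p[min(local_offset, len(p) - 1)],  # local
                    lambda p: p[-1],  # remote
                ):
                    a = _angle_deg(
                        tree.position(pick(pi)) - origin,
                        tree.position(pick(pj)) - origin,
                    )
                    trio.append(a)
                if all(math.isfinite(a) for a in trio):
                    branch_angles.append(trio[0])
                    local_angles.append(trio[1])
                    remote_angles.append(trio[2])

    if not branch_angles:
        return math.nan, math.nan, math.nan
    return (
        float(np.mean(branch_angles)),
        float(np.mean(local_angles)),
        float(np.mean(remote_angles)),
    )


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """The 13 morphological parameters of one neuron (see module docstring)."""

    neuron_id: str
    n_branch_points: int
    max_branch_order: int
    strahler: int
    mean_partition_asymmetry: float
    max_path_distance: float
    mean_contraction: float
    mean_branch_angle: float
    mean_local_angle: float
    mean_remote_angle: float
    mean_fractal_dimension: float
    total_length: float
    soma_area: float
    ap_position: float

    @property
    def clusterable(self) -> bool:
        """Neurons that never branch in the analyzed region are excluded from clustering."""
        return self.n_branch_points > 0

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def feature_vector(
    tree: NeuronTree,
    meta: NeuronMetadata,
    restriction: Sequence[str] | str = FIN_LABELS,
    local_offset: int = DEFAULT_LOCAL_OFFSET,
) -> FeatureVector:
    """Assemble the full 13-parameter vector for one neuron.

    By default metrics are computed on the fin-labeled subtree together with
    the processes leading from the soma to the fin; pass ``"all"`` to analyze
    the entire arbor.
    """
    if meta is None:
        raise ValueError("missing metadata for neuron")
    nb, order, strahler, asym = topology_metrics(tree, restriction)
    max_path, contraction, fd, total = geometry_metrics(tree, restriction)
    ba, la, ra = angle_metrics(tree, restriction, local_offset=local_offset)
    return FeatureVector(
        neuron_id=meta.neuron_id,
        n_branch_points=nb,
        max_branch_order=order,
        strahler=strahler,
        mean_partition_asymmetry=asym,
        max_path_distance=max_path,
        mean_contraction=contraction,
        mean_branch_angle=ba,
        mean_local_angle=la,
        mean_remote_angle=ra,
        mean_fractal_dimension=fd,
        total_length=total,
        soma_area=meta.soma_area,
        ap_position=meta.ap_position,
    )
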