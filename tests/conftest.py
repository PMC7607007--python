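"""Shared fixtures: hand-built trees, random tree generators, brute-force oracles.

The oracle functions here are deliberately naive (full recursive enumeration)
and independent of the package's iterative implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from finmorph.swc_io import NeuronNode, NeuronTree


# ---------------------------------------------------------------------------
# Tree construction helpers
# ---------------------------------------------------------------------------

def tree_from_table(rows, annotations=None) -> NeuronTree:
    """rows: (node_id, parent_id, x, y, z)."""
    nodes = [
        NeuronNode(nid, pid, np.array([x, y, z], dtype=float))
        for nid, pid, x, y, z in rows
    ]
    return NeuronTree(nodes, annotations)


def path_tree(points, annotations=None) -> NeuronTree:
    """Unbranched path through the given 3D points."""
    rows = [
        (i + 1, i if i else -1, *map(float, p)) for i, p in enumerate(points)
    ]
    return tree_from_table(rows, annotations)


def random_binary_tree(rng: np.random.Generator, max_tips: int = 50) -> NeuronTree:
    """A random bifurcating tree with 2..max_tips tips and randomized geometry.

    Interior path segments of random node counts between critical nodes, so
    re-segmentation is exercised too.
    """
    n_tips = int(rng.integers(2, max_tips + 1))
    rows = [(1, -1, *rng.normal(0, 50, 3))]
    next_id = 2
    # leaves available for expansion: start with one stem below the root
    leaves = []

    def add_path(parent: int, n_nodes: int) -> int:
        nonlocal next_id
        for _ in range(n_nodes):
            pos = rng.normal(0, 50, 3)
            rows.append((next_id, parent, *pos))
            parent = next_id
            next_id += 1
        return parent

    leaves.append(add_path(1, int(rng.integers(1, 4))))
    # each expansion turns one leaf into a bifurcation: +1 tip
    while len(leaves) < n_tips:
        idx = int(rng.integers(0, len(leaves)))
        parent = leaves.pop(idx)
        for _ in range(2):
            leaves.append(add_path(parent, int(rng.integers(1, 5))))
    return tree_from_table(rows)


# ---------------------------------------------------------------------------
# Brute-force oracles (naive recursion, independent of the implementation)
# ---------------------------------------------------------------------------

def brute_children(tree: NeuronTree) -> dict[int, list[int]]:
    ch: dict[int, list[int]] = {nid: [] for nid in tree.node_ids}
    for nid in tree.node_ids:
        p = tree.parent(nid)
        if p != -1:
            ch[p].append(nid)
    return ch


def brute_tip_count(ch: dict[int, list[int]], nid: int) -> int:
    if not ch[nid]:
        return 1
    return sum(brute_tip_count(ch, c) for c in ch[nid])


def brute_strahler(ch: dict[int, list[int]], nid: int) -> int:
    if not ch[nid]:
        return 1
    vals = sorted((brute_strahler(ch, c) for c in ch[nid]), reverse=True)
    if len(vals) == 1:
        return vals[0]
    return vals[0] + 1 if vals[1] == vals[0] else vals[0]


def brute_mean_asymmetry(tree: NeuronTree) -> float:
    ch = brute_children(tree)
    vals = []
    for nid in tree.node_ids:
        kids = ch[nid]
        if len(kids) < 2:
            continue
        tips = [brute_tip_count(ch, c) for c in kids]
        for i in range(len(tips)):
            for j in range(i + 1, len(tips)):
                l, r = tips[i], tips[j]
                if l + r > 2:
                    vals.append(abs(l - r) / (l + r - 2))
    return float(np.mean(vals)) if vals else math.nan


def brute_segment_count(tree: NeuronTree) -> int:
    """Each child edge of a critical node (root, branch point, terminal)
    starts exactly one interbranch segment."""
    ch = brute_children(tree)
    count = 0
    for nid in tree.node_ids:
        if nid == tree.root_id or len(ch[nid]) != 1:
            count += len(ch[nid])
    return count


def brute_total_length(tree: NeuronTree) -> float:
    total = 0.0
    for nid in tree.node_ids:
        p = tree.parent(nid)
        if p != -1:
            total += float(np.linalg.norm(tree.position(nid) - tree.position(p)))
    return total


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240527)


@pytest.fixture()
def straight_path() -> NeuronTree:
    """11 nodes every 2 μm along +z (10 steps, 20 μm)."""
    return path_tree([(0.0, 0.0, 2.0 * i) for i in range(11)])


@pytest.fixture()
def simple_y() -> NeuronTree:
    """Stem up +y, then two straight daughters 90 degrees apart (±45° from +y)."""
    rows = [(1, -1, 0, 0, 0), (2, 1, 0, 10, 0)]
    nid = 3
    for sx in (+1, -1):
        parent = 2
        for k in range(1, 13):
            d = k * math.sqrt(2) / 2
            rows.append((nid, parent, sx * d, 10 + d, 0))
            parent = nid
            nid += 1
    return tree_from_table(rows)


@pytest.fixture()
def balanced_four_tips() -> NeuronTree:
    rows = [
        (1, -1, 0, 0, 0),
        (2, 1, 0, 10, 0),          # first bifurcation
        (3, 2, -10, 20, 0), (4, 2, 10, 20, 0),   # second level
        (5, 3, -15, 30, 0), (6, 3, -5, 30, 0),
        (7, 4, 5, 30, 0), (8, 4, 15, 30, 0),
    ]
    return tree_from_table(rows)


@pytest.fixture()
def caterpillar() -> NeuronTree:
    """Three bifurcations along a spine, each shedding one tip; 4 tips total."""
    rows = [
        (1, -1, 0, 0, 0),
        (2, 1, 0, 10, 0),
        (3, 2, -10, 15, 0),        # tip off bifurcation 1
        (4, 2, 0, 20, 0),
        (5, 4, 10, 25, 0),         # tip off bifurcation 2
        (6, 4, 0, 30, 0),
        (7, 6, -10, 35, 0),        # tip off bifurcation 3
        (8, 6, 0, 40, 0),          # spine tip
    ]
    return tree_from_table(rows)
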