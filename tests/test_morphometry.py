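"""Interbranch segmentation and the 13-parameter feature vector.

Topology metrics are checked against naive recursive oracles; geometry
metrics against closed-form constructions; all tree metrics against rigid
motions of the coordinates.
"""

import math

import numpy as np
import pytest

from finmorph.morphometry import (
    EmptySelectionError,
    angle_metrics,
    feature_vector,
    geometry_metrics,
    resegment,
    restricted_length,
    topology_metrics,
)
from finmorph.swc_io import NeuronMetadata

from conftest import (
    brute_mean_asymmetry,
    brute_segment_count,
    brute_strahler,
    brute_children,
    brute_total_length,
    path_tree,
    random_binary_tree,
    tree_from_table,
)


# ---------------------------------------------------------------------------
# Re-segmentation
# ---------------------------------------------------------------------------

def test_unbranched_path_is_one_segment(straight_path):
    segs = resegment(straight_path)
    assert len(segs) == 1
    assert segs[0].branch_order == 0
    assert segs[0].arc_length == pytest.approx(20.0)
    assert segs[0].euclidean_length == pytest.approx(20.0)


def test_single_bifurcation_gives_three_segments(simple_y):
    segs = resegment(simple_y)
    assert len(segs) == 3  # terminals (2) + branch points (1)
    orders = sorted(s.branch_order for s in segs)
    assert orders == [0, 1, 1]


def test_segment_identity_on_random_trees(rng):
    for _ in range(100):
        tree = random_binary_tree(rng, max_tips=50)
        segs = resegment(tree)
        tips = len(tree.terminals())
        bifs = sum(1 for n in tree.node_ids if len(tree.children(n)) >= 2)
        assert len(segs) == tips + bifs == brute_segment_count(tree)
        # segments partition the edges
        assert sum(len(s) - 1 for s in segs) == len(tree) - 1
        for s in segs:
            assert s.arc_length >= s.euclidean_length - 1e-9 >= -1e-9


# ---------------------------------------------------------------------------
# Topology metrics
# ---------------------------------------------------------------------------

def test_balanced_tree_topology(balanced_four_tips):
    nb, order, strahler, asym = topology_metrics(balanced_four_tips)
    assert (nb, order, strahler) == (3, 3, 3)
    assert asym == pytest.approx(0.0)  # (2,2) counted; (1,1) pairs excluded


def test_caterpillar_topology(caterpillar):
    nb, order, strahler, asym = topology_metrics(caterpillar)
    assert nb == 3
    assert strahler == 2
    # qualifying bifurcations: (3,1) -> 1.0 and (2,1) -> 1.0; (1,1) excluded
    assert asym == pytest.approx(1.0)
    assert order == 4  # deepest tip passes 3 branch points


def test_unbranched_path_topology(straight_path):
    nb, order, strahler, asym = topology_metrics(straight_path)
    assert (nb, order, strahler) == (0, 1, 1)
    assert math.isnan(asym)


def test_strahler_and_asymmetry_match_bruteforce_on_random_trees(rng):
    for _ in range(100):
        tree = random_binary_tree(rng, max_tips=50)
        _, _, strahler, asym = topology_metrics(tree)
        ch = brute_children(tree)
        assert strahler == brute_strahler(ch, tree.root_id)
        expected = brute_mean_asymmetry(tree)
        if math.isnan(expected):
            assert math.isnan(asym)
        else:
            assert asym == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# Geometry metrics
# ---------------------------------------------------------------------------

def test_straight_segment_geometry(straight_path):
    max_path, contraction, fd, total = geometry_metrics(straight_path)
    assert total == pytest.approx(20.0)
    assert max_path == pytest.approx(20.0)
    assert contraction == pytest.approx(1.0)
    assert fd == pytest.approx(1.0, abs=1e-9)


def test_right_angle_contraction():
    # two 1 μm legs meeting at 90°: chord = sqrt(2), path = 2
    tree = path_tree([(0, 0, 0), (1, 0, 0), (1, 1, 0)])
    _, contraction, _, total = geometry_metrics(tree)
    assert total == pytest.approx(2.0)
    assert contraction == pytest.approx(math.sqrt(2) / 2, abs=1e-12)


def test_total_length_matches_edge_sum_oracle(rng):
    for _ in range(30):
        tree = random_binary_tree(rng, max_tips=40)
        *_, total = geometry_metrics(tree)
        assert total == pytest.approx(brute_total_length(tree), rel=1e-9)


def test_meandering_segment_has_fractal_dimension_above_one(rng):
    pts = [(0.0, 0.0, 0.0)]
    ang = 0.0
    for _ in range(200):
        ang += rng.normal(0, 0.6)
        pts.append((pts[-1][0] + math.cos(ang), pts[-1][1] + math.sin(ang), 0.0))
    _, contraction, fd, _ = geometry_metrics(path_tree(pts))
    assert contraction < 1.0
    assert fd > 1.0


def test_contraction_is_one_iff_collinear():
    collinear = path_tree([(0, 0, 0), (3, 0, 0), (7, 0, 0), (11, 0, 0)])
    bent = path_tree([(0, 0, 0), (3, 0, 0), (7, 0.5, 0), (11, 0, 0)])
    assert geometry_metrics(collinear)[1] == pytest.approx(1.0)
    assert geometry_metrics(bent)[1] < 1.0


# ---------------------------------------------------------------------------
# Angle metrics
# ---------------------------------------------------------------------------

def test_symmetric_y_all_angles_equal_90(simple_y):
    ba, la, ra = angle_metrics(simple_y)
    for a in (ba, la, ra):
        assert a == pytest.approx(90.0, abs=1e-9)


def test_collinear_opposite_daughters_measure_180():
    rows = [(1, -1, 0, 0, 0), (2, 1, 0, 10, 0)]
    nid = 3
    for sx in (+1, -1):
        parent = 2
        for k in range(1, 12):
            rows.append((nid, parent, sx * k, 10, 0))
            parent = nid
            nid += 1
    ba, la, ra = angle_metrics(tree_from_table(rows))
    for a in (ba, la, ra):
        assert a == pytest.approx(180.0, abs=1e-9)


def test_local_angle_uses_offset_nodes_remote_uses_endpoints():
    """Daughters straight (45° apart) for 10 nodes, then one bends sharply."""
    rows = [(1, -1, 0, 0, 0), (2, 1, 0, 10, 0)]
    nid = 3
    ends = {}
    for sx in (+1, -1):
        parent = 2
        x, y = 0.0, 10.0
        for k in range(15):
            if sx < 0 or k < 10:
                dx, dy = sx * math.sqrt(2) / 2, math.sqrt(2) / 2
            else:
                dx, dy = 1.0, 0.0  # right daughter turns horizontal
            x, y = x + dx, y + dy
            rows.append((nid, parent, x, y, 0))
            parent = nid
            nid += 1
        ends[sx] = (x, y)
    tree = tree_from_table(rows)
    ba, la, ra = angle_metrics(tree, local_offset=10)
    assert ba == pytest.approx(90.0, abs=1e-9)
    assert la == pytest.approx(90.0, abs=1e-9)  # both straight for 10 nodes
    # remote angle uses the endpoints, where the right daughter has bent
    origin = np.array([0.0, 10.0])
    v1 = np.array(ends[+1]) - origin
    v2 = np.array(ends[-1]) - origin
    expected = math.degrees(
        math.acos(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    )
    assert ra == pytest.approx(expected, abs=1e-9)
    assert abs(ra - la) > 5.0


def test_short_daughters_clamp_the_local_offset():
    rows = [
        (1, -1, 0, 0, 0), (2, 1, 0, 10, 0),
        (3, 2, 5, 15, 0), (4, 2, -5, 15, 0),  # one-node daughters
    ]
    ba, la, ra = angle_metrics(tree_from_table(rows), local_offset=10)
    assert ba == la == ra == pytest.approx(90.0, abs=1e-9)


def test_no_bifurcations_yields_nan_sentinels(straight_path):
    ba, la, ra = angle_metrics(straight_path)
    assert all(math.isnan(a) for a in (ba, la, ra))


# ---------------------------------------------------------------------------
# Restrictions
# ---------------------------------------------------------------------------

def _labeled_tree():
    """Stem (axial) -> fin path that bifurcates; labels partition non-root nodes."""
    rows = [
        (1, -1, 0, 0, 0),
        (2, 1, 0, 10, 0),   # axial
        (3, 2, 0, 20, 0),   # axial
        (4, 3, 0, 30, 0),   # fin_medial
        (5, 4, -10, 40, 0),  # fin_medial
        (6, 4, 10, 40, 0),  # fin_lateral
        (7, 3, 20, 20, 0),  # axial side branch
    ]
    ann = {2: "axial", 3: "axial", 4: "fin_medial", 5: "fin_medial",
           6: "fin_lateral", 7: "axial"}
    return tree_from_table(rows, ann)


def test_restriction_selects_fin_subtree_with_root_path():
    tree = _labeled_tree()
    nb, order, strahler, _ = topology_metrics(tree, ("fin_medial", "fin_lateral"))
    assert nb == 1  # node 4; the axial side branch is excluded by the closure
    assert strahler == 2
    max_path, _, _, total = geometry_metrics(tree, ("fin_medial", "fin_lateral"))
    # root path included: 30 μm of stem plus the two fin daughters
    assert total == pytest.approx(30 + 2 * math.sqrt(200))
    assert max_path == pytest.approx(30 + math.sqrt(200))


def test_restricted_length_is_additive_over_label_partition():
    tree = _labeled_tree()
    fin = restricted_length(tree, ("fin_medial", "fin_lateral"))
    axial = restricted_length(tree, ("axial",))
    everything = restricted_length(
        tree, ("axial", "fin_medial", "fin_lateral", "unlabeled")
    )
    assert fin + axial == pytest.approx(everything, rel=1e-12)
    assert fin == pytest.approx(10 + 2 * math.sqrt(200))


def test_empty_selection_raises():
    tree = _labeled_tree()
    with pytest.raises(EmptySelectionError):
        topology_metrics(tree, ())


# ---------------------------------------------------------------------------
# Rigid-motion invariance and assembly
# ---------------------------------------------------------------------------

def _random_rotation(rng):
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def test_metrics_invariant_under_rigid_motion(rng):
    meta = NeuronMetadata("t", 100.0, -50.0)
    for _ in range(5):
        tree = random_binary_tree(rng, max_tips=25)
        ref = feature_vector(tree, meta, restriction="all")
        R = _random_rotation(rng)
        t = rng.normal(0, 100, 3)
        moved = feature_vector(tree.transformed(R, t), meta, restriction="all")
        for name in (
            "n_branch_points", "max_branch_order", "strahler",
            "mean_partition_asymmetry", "max_path_distance", "mean_contraction",
            "mean_branch_angle", "mean_local_angle", "mean_remote_angle",
            "mean_fractal_dimension", "total_length",
        ):
            a, b = getattr(ref, name), getattr(moved, name)
            if isinstance(a, float) and math.isnan(a):
                assert math.isnan(b), name
            else:
                assert a == pytest.approx(b, rel=1e-9), name


def test_feature_vector_unbranched_and_passthrough(straight_path):
    ann = {nid: "fin_medial" for nid in straight_path.node_ids if nid != 1}
    tree = straight_path.with_annotations(ann)
    meta = NeuronMetadata("u", 93.77, -120.5)
    fv = feature_vector(tree, meta)
    assert not fv.clusterable
    assert fv.n_branch_points == 0 and fv.strahler == 1
    assert math.isnan(fv.mean_partition_asymmetry)
    assert math.isnan(fv.mean_branch_angle)
    assert fv.soma_area == 93.77
    assert fv.ap_position == -120.5


def test_feature_vector_requires_metadata(straight_path):
    with pytest.raises(ValueError):
        feature_vector(straight_path, None, restriction="all")
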