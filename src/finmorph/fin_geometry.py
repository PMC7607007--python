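"""Fin-plane fitting, quadrant/octant partitioning and innervation mapping.

The pectoral fin is described by 18 labeled 3D landmarks: nine on the outer
edge of the fin body (FB, bounded distally by the blood vessel) and nine on
the edge of the fin membrane (FM).  Each ring of nine has two base points
(one per side), one apex at maximum distance from the base, and three flank
points per side.  By convention the ``*_1``-side landmarks (``fb_base_1``,
``fb_flank_1..3``, and their FM counterparts) mark the dorsal side.

The 14 non-base points define a total-least-squares plane.  All landmarks
and neuron traces are orthogonally projected onto it.  The in-plane frame is
anchored to the landmarks (first axis along the FB base, second toward the
FM apex), so every derived quantity is equivariant under rigid motion of the
raw coordinates and deterministic.

The projected fin footprint (FM ring closed along the base) is divided into
four quadrants — dorsal/ventral membrane (DM, VM) and dorsal/ventral base
(DB, VB) — by the projected FB ring (the blood-vessel boundary) and by the
dorsoventral boundary line, drawn from the midpoint between the FB base
midpoint and the FB apex through the FM apex.  Crossing each quadrant with
the medial/lateral surface tags gives eight octants.

Innervation is assigned per trace edge: edges are split exactly where their
2D projections cross region boundaries, each piece is classified by its
midpoint, and the *3D arc length* of the piece is recorded, so the eight
octant lengths sum exactly to the fin-restricted total length.  Pieces whose
midpoints project outside the footprint are attributed to the nearest region
and counted.  Boundary ties resolve deterministically to the dorsal, then
membrane, side.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
import shapely.ops
import shapely.validation
from shapely.geometry import LineString, Point, Polygon

from .swc_io import FIN_LABELS, NeuronTree

__all__ = [
    "FB_LABELS",
    "FM_LABELS",
    "LANDMARK_LABELS",
    "REGIONS",
    "SURFACES",
    "GeometryError",
    "FinLandmarkSet",
    "FitPlane",
    "FinRegionPartition",
    "RegionInnervationTable",
    "ModelFin",
    "read_landmarks",
    "write_landmarks",
    "fit_plane",
    "project",
    "build_regions",
    "assign_region_lengths",
    "build_model_fin",
    "register_model_fin",
    "axial_overlap",
]

_SIDE1 = ["flank_1", "flank_2", "flank_3"]
_SIDE2 = ["flank_4", "flank_5", "flank_6"]
#: Ring order: dorsal base, dorsal flanks, apex, ventral flanks, ventral base.
_RING_ORDER = ["base_1"] + _SIDE1 + ["apex"] + _SIDE2 + ["base_2"]

FB_LABELS = tuple(f"fb_{s}" for s in _RING_ORDER)
FM_LABELS = tuple(f"fm_{s}" for s in _RING_ORDER)
LANDMARK_LABELS = FB_LABELS + FM_LABELS
_BASE_LABELS = ("fb_base_1", "fb_base_2", "fm_base_1", "fm_base_2")

#: Fin quadrants, in the deterministic tie-break priority order
#: (dorsal before ventral, membrane before base).
REGIONS = ("DM", "DB", "VM", "VB")
SURFACES = ("medial", "lateral")


class GeometryError(ValueError):
    """Degenerate or self-intersecting fin geometry."""


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FinLandmarkSet:
    """The 18 labeled fin-edge points (micrometres)."""

    points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = set(LANDMARK_LABELS) - set(self.points)
        extra = set(self.points) - set(LANDMARK_LABELS)
        if missing or extra:
            raise GeometryError(
                f"landmark set must contain exactly the 18 labels; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        pts = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}
        coords = np.array([pts[k] for k in LANDMARK_LABELS])
        if not np.all(np.isfinite(coords)):
            raise GeometryError("non-finite landmark coordinates")
        if len(np.unique(np.round(coords, 9), axis=0)) != len(coords):
            raise GeometryError("duplicate landmark coordinates")
        object.__setattr__(self, "points", pts)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.points[label]

    def ring(self, prefix: str) -> np.ndarray:
        """The 9 ring points of ``prefix`` ('fb' or 'fm') in ring order."""
        return np.array([self.points[f"{prefix}_{s}"] for s in _RING_ORDER])

    def non_base_points(self) -> np.ndarray:
        return np.array(
            [self.points[k] for k in LANDMARK_LABELS if k not in _BASE_LABELS]
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "FinLandmarkSet":
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return FinLandmarkSet({k: R @ v + t for k, v in self.points.items()})


def read_landmarks(path: str | Path) -> FinLandmarkSet:
    """Load a landmark CSV (label, x_um, y_um, z_um; 18 rows)."""
    df = pd.read_csv(path, comment="#")
    required = {"label", "x_um", "y_um", "z_um"}
    if not required <= set(df.columns):
        raise GeometryError(f"landmark file must have columns {sorted(required)}")
    pts = {
        str(r.label): np.array([r.x_um, r.y_um, r.z_um], dtype=float)
        for r in df.itertuples(index=False)
    }
    return FinLandmarkSet(pts)


def write_landmarks(landmarks: FinLandmarkSet, path: str | Path) -> None:
    rows = [
        {"label": k, "x_um": v[0], "y_um": v[1], "z_um": v[2]}
        for k, v in ((k, landmarks[k]) for k in LANDMARK_LABELS)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Plane fitting and projection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitPlane:
    """A best-fit plane with a landmark-anchored in-plane frame.

    ``basis[0]`` points along the FB base (side 1 -> side 2), ``basis[1]``
    toward the FM apex; ``normal = basis[0] x basis[1]``, so the sign of the
    signed distance is fixed by landmark chirality (positive = medial side
    under the synthetic-data convention).
    """

    centroid: np.ndarray  # (3,)
    normal: np.ndarray  # (3,), unit
    basis: np.ndarray  # (2, 3), orthonormal rows

    def to_2d(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.centroid) @ self.basis.T

    def to_3d(self, coords2d: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(np.asarray(coords2d, dtype=float))
        return self.centroid + q @ self.basis

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.centroid) @ self.normal


def fit_plane(landmarks: FinLandmarkSet) -> FitPlane:
    """Total-least-squares plane through the 14 non-base landmarks.

    Minimizes the summed squared orthogonal distances (smallest principal
    component of the centered points).  Base points are excluded from the fit
    but project like any other point.  Raises ``GeometryError`` when the
    non-base points are (near-)collinear.
    """
    pts = landmarks.non_base_points()
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    scale = max(svals[0], 1.0)
    if svals[1] <= 1e-9 * scale:
        raise GeometryError("non-base landmarks are collinear; plane is underdetermined")
    n0 = vt[2]

    base_dir = landmarks["fb_base_2"] - landmarks["fb_base_1"]
    u = base_dir - (base_dir @ n0) * n0
    norm_u = np.linalg.norm(u)
    if norm_u <= 1e-12:
        raise GeometryError("FB base direction is perpendicular to the fitted plane")
    u = u / norm_u
    v = np.cross(n0, u)
    if (landmarks["fm_apex"] - centroid) @ v < 0:
        v = -v
    normal = np.cross(u, v)
    return FitPlane(centroid=centroid, normal=normal, basis=np.array([u, v]))


def project(points: np.ndarray, plane: FitPlane) -> np.ndarray:
    """Orthogonal projection to in-plane 2D coordinates (idempotent)."""
    return plane.to_2d(points)


# ---------------------------------------------------------------------------
# Low-level 2D predicates (vectorized; these carry the conservation guarantee)
# ---------------------------------------------------------------------------

def _points_in_ring(pts: np.ndarray, ring: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) containment of points in a closed ring."""
    pts = np.atleast_2d(pts)
    x = pts[:, 0][:, None]
    y = pts[:, 1][:, None]
    x1 = ring[:, 0][None, :]
    y1 = ring[:, 1][None, :]
    x2 = np.roll(ring[:, 0], -1)[None, :]
    y2 = np.roll(ring[:, 1], -1)[None, :]
    crosses = (y1 > y) != (y2 > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
    hits = crosses & (x < xint)
    return hits.sum(axis=1) % 2 == 1


def _ring_segments(ring: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return ring, np.roll(ring, -1, axis=0)


def _edge_cut_params(
    a: np.ndarray, b: np.ndarray, seg_p: np.ndarray, seg_q: np.ndarray
) -> list[np.ndarray]:
    """Intersection parameters t in (0,1) of edges a->b with boundary segments.

    Fully vectorized over edges x segments; collinear overlaps contribute the
    projections of the overlapping segment's endpoints so that interval
    midpoints never straddle a boundary.
    """
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    r = (b - a)[:, None, :]  # (E,1,2)
    s = (seg_q - seg_p)[None, :, :]  # (1,S,2)
    qp = seg_p[None, :, :] - a[:, None, :]  # (E,S,2)

    def cross(v, w):
        return v[..., 0] * w[..., 1] - v[..., 1] * w[..., 0]

    denom = cross(r, s)
    qpxr = cross(qp, r)
    qpxs = cross(qp, s)
    scale = np.maximum(np.linalg.norm(r, axis=-1) * np.linalg.norm(s, axis=-1), 1e-300)
    proper = np.abs(denom) > 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(proper, qpxs / denom, np.nan)
        u = np.where(proper, qpxr / denom, np.nan)
    valid = proper & (t > 0) & (t < 1) & (u >= 0) & (u <= 1)

    # collinear overlap: project segment endpoints onto the edge parameter
    r2 = np.maximum(np.einsum("eij,eij->ei", r, r), 1e-300)
    collinear = (~proper) & (np.abs(qpxr) <= 1e-9 * scale)
    tp = np.einsum("esj,eij->es", qp, r) / r2
    tq = np.einsum("esj,eij->es", seg_q[None, :, :] - a[:, None, :], r) / r2

    out: list[np.ndarray] = []
    for e in range(a.shape[0]):
        ts = [t[e][valid[e]]]
        if collinear[e].any():
            extra = np.concatenate([tp[e][collinear[e]], tq[e][collinear[e]]])
            ts.append(extra[(extra > 0) & (extra < 1)])
        out.append(np.concatenate(ts) if ts else np.empty(0))
    return out


# ---------------------------------------------------------------------------
# Region partition
# ---------------------------------------------------------------------------

@dataclass
class FinRegionPartition:
    """Fitted plane plus the four projected fin quadrants.

    ``polygons`` maps region name to a shapely polygon (used for areas,
    nearest-region queries and export); the authoritative point classifier is
    :meth:`region_of_points`, built from the same rings and boundary line.
    """

    plane: FitPlane
    footprint_ring: np.ndarray  # (9, 2), FM ring in order; closed along the base
    fb_ring: np.ndarray  # (9, 2)
    dv_point: np.ndarray  # (2,), point on the dorsoventral boundary
    dv_dir: np.ndarray  # (2,), unit direction of the boundary
    dorsal_sign: float  # side of the boundary that is dorsal
    polygons: dict[str, Polygon]
    dv_boundary: LineString

    @property
    def footprint(self) -> Polygon:
        return Polygon(self.footprint_ring)

    def side_values(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        d = self.dv_dir
        rel = pts - self.dv_point
        return (d[0] * rel[:, 1] - d[1] * rel[:, 0]) * self.dorsal_sign

    def region_of_points(self, pts: np.ndarray) -> list[str | None]:
        """Quadrant of each 2D point, or None outside the footprint.

        Ties resolve to the dorsal (side value 0 -> dorsal) and membrane
        (even-odd FB containment) sides deterministically.
        """
        pts = np.atleast_2d(pts)
        inside = _points_in_ring(pts, self.footprint_ring)
        in_fb = _points_in_ring(pts, self.fb_ring)
        dorsal = self.side_values(pts) >= 0
        out: list[str | None] = []
        for i in range(len(pts)):
            if not inside[i]:
                out.append(None)
            else:
                out.append(("D" if dorsal[i] else "V") + ("B" if in_fb[i] else "M"))
        return out

    def nearest_region(self, pt: np.ndarray) -> str:
        p = Point(pt)
        dists = [(self.polygons[r].distance(p), i, r) for i, r in enumerate(REGIONS)]
        return min(dists)[2]

    def mean_edge_length(self) -> float:
        return float(np.linalg.norm(np.ptp(self.footprint_ring, axis=0)))


def build_regions(landmarks: FinLandmarkSet, plane: FitPlane) -> FinRegionPartition:
    """Partition the projected fin footprint into the four quadrants.

    The footprint is the projected FM ring closed along the base; the FB ring
    polygon marks the blood-vessel boundary between base and membrane; the
    dorsoventral boundary is the line from the midpoint between the FB base
    midpoint and the FB apex, through the FM apex, clipped to the footprint.
    """
    fb2 = plane.to_2d(landmarks.ring("fb"))
    fm2 = plane.to_2d(landmarks.ring("fm"))
    footprint = Polygon(fm2)
    fb_poly = Polygon(fb2)
    for name, poly in (("FM", footprint), ("FB", fb_poly)):
        if not poly.is_valid:
            raise GeometryError(
                f"projected {name} ring self-intersects: "
                f"{shapely.validation.explain_validity(poly)}"
            )

    base_mid = 0.5 * (fb2[0] + fb2[8])  # fb_base_1, fb_base_2
    apex_fb = fb2[4]
    M = 0.5 * (base_mid + apex_fb)
    apex_fm = fm2[4]
    d = apex_fm - M
    nd = np.linalg.norm(d)
    if nd <= 1e-12:
        raise GeometryError("degenerate dorsoventral boundary (FM apex coincides with M)")
    d = d / nd

    # dorsal is the side of the *_1 flank landmarks
    flank1 = np.mean(fm2[1:4], axis=0)
    raw_side = d[0] * (flank1[1] - M[1]) - d[1] * (flank1[0] - M[0])
    if abs(raw_side) <= 1e-12:
        raise GeometryError("cannot orient dorsoventral boundary from flank landmarks")
    dorsal_sign = 1.0 if raw_side > 0 else -1.0

    span = 10.0 * max(footprint.length, 1.0)
    long_line = LineString([M - span * d, M + span * d])
    dv_boundary = footprint.intersection(long_line)

    membrane = footprint.difference(fb_poly)
    polygons: dict[str, list] = {r: [] for r in REGIONS}
    for kind, geom in (("B", fb_poly), ("M", membrane)):
        pieces = shapely.ops.split(geom, long_line).geoms
        for piece in pieces:
            if piece.is_empty or piece.area <= 0:
                continue
            rp = piece.representative_point()
            side = (
                d[0] * (rp.y - M[1]) - d[1] * (rp.x - M[0])
            ) * dorsal_sign
            polygons["D" + kind if side >= 0 else "V" + kind].append(piece)
    merged = {}
    for r in REGIONS:
        if not polygons[r]:
            raise GeometryError(f"region {r} is empty; fin geometry is degenerate")
        merged[r] = shapely.ops.unary_union(polygons[r])

    return FinRegionPartition(
        plane=plane,
        footprint_ring=fm2,
        fb_ring=fb2,
        dv_point=M,
        dv_dir=d,
        dorsal_sign=dorsal_sign,
        polygons=merged,
        dv_boundary=dv_boundary,
    )


# ---------------------------------------------------------------------------
# Innervation assignment
# ---------------------------------------------------------------------------

@dataclass
class RegionInnervationTable:
    """Per-octant afferent lengths/terminals plus axial summaries for one neuron."""

    lengths: dict[tuple[str, str], float] = field(
        default_factory=lambda: {(r, s): 0.0 for r in REGIONS for s in SURFACES}
    )
    terminals: dict[tuple[str, str], int] = field(
        default_factory=lambda: {(r, s): 0 for r in REGIONS for s in SURFACES}
    )
    axial_length: float = 0.0
    axial_under_fin_length: float = 0.0
    axial_terminals: int = 0
    axial_under_fin_terminals: int = 0
    outside_footprint_length: float = 0.0
    n_outside_points: int = 0

    def fin_total_length(self) -> float:
        return float(sum(self.lengths.values()))

    def surface_length(self, surface: str) -> float:
        return float(sum(v for (r, s), v in self.lengths.items() if s == surface))

    def surface_terminals(self, surface: str) -> int:
        return int(sum(v for (r, s), v in self.terminals.items() if s == surface))

    def to_dataframe(self, neuron_id: str) -> pd.DataFrame:
        rows = [
            {
                "neuron_id": neuron_id,
                "region": r,
                "surface": s,
                "length_um": self.lengths[(r, s)],
                "terminals": self.terminals[(r, s)],
            }
            for r in REGIONS
            for s in SURFACES
        ]
        rows.append(
            {
                "neuron_id": neuron_id,
                "region": "axial",
                "surface": "axial",
                "length_um": self.axial_length,
                "terminals": self.axial_terminals,
            }
        )
        rows.append(
            {
                "neuron_id": neuron_id,
                "region": "axial_under_fin",
                "surface": "axial",
                "length_um": self.axial_under_fin_length,
                "terminals": self.axial_under_fin_terminals,
            }
        )
        return pd.DataFrame(rows)


def _collect_edges(
    tree: NeuronTree, labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """3D endpoints (parent, child) and child labels of edges in a label set."""
    a, b, labs = [], [], []
    lset = set(labels)
    for parent, child in tree.edges():
        lab = tree.label(child)
        if lab in lset:
            a.append(tree.position(parent))
            b.append(tree.position(child))
            labs.append(lab)
    if not a:
        return np.empty((0, 3)), np.empty((0, 3)), []
    return np.array(a), np.array(b), labs


def _split_lengths_by_polygon(
    a2: np.ndarray,
    b2: np.ndarray,
    lengths3d: np.ndarray,
    ring: np.ndarray,
) -> np.ndarray:
    """3D length fraction of each edge whose projection falls inside a ring."""
    if len(a2) == 0:
        return np.empty(0)
    p, q = _ring_segments(ring)
    cuts = _edge_cut_params(a2, b2, p, q)
    inside = np.zeros(len(a2))
    for e in range(len(a2)):
        ts = np.unique(np.concatenate([[0.0, 1.0], cuts[e]]))
        mids = a2[e] + np.outer((ts[:-1] + ts[1:]) / 2.0, b2[e] - a2[e])
        frac = (ts[1:] - ts[:-1])[_points_in_ring(mids, ring)].sum()
        inside[e] = frac * lengths3d[e]
    return inside


def assign_region_lengths(
    tree: NeuronTree,
    partition: FinRegionPartition,
    surface_from_geometry: bool = False,
) -> RegionInnervationTable:
    """Distribute a neuron's fin innervation over the eight octants.

    Each fin-labeled trace edge is split exactly where its projection crosses
    a region boundary; pieces carry their 3D arc length, so octant lengths
    sum to the fin-restricted total exactly.  ``surface_from_geometry``
    replaces the sidecar medial/lateral tags by the sign of the distance to
    the fitted plane (positive = medial), useful for synthetic data.
    """
    plane = partition.plane
    table = RegionInnervationTable()

    a3, b3, labs = _collect_edges(tree, FIN_LABELS)
    if len(a3):
        L3 = np.linalg.norm(b3 - a3, axis=1)
        a2 = plane.to_2d(a3)
        b2 = plane.to_2d(b3)
        if surface_from_geometry:
            mid_sd = plane.signed_distance((a3 + b3) / 2.0)
            surfaces = ["medial" if s >= 0 else "lateral" for s in mid_sd]
        else:
            surfaces = ["medial" if l == "fin_medial" else "lateral" for l in labs]

        boundaries_p = []
        boundaries_q = []
        for ring in (partition.footprint_ring, partition.fb_ring):
            p, q = _ring_segments(ring)
            boundaries_p.append(p)
            boundaries_q.append(q)
        span = 10.0 * max(Polygon(partition.footprint_ring).length, 1.0)
        boundaries_p.append((partition.dv_point - span * partition.dv_dir)[None, :])
        boundaries_q.append((partition.dv_point + span * partition.dv_dir)[None, :])
        seg_p = np.concatenate(boundaries_p)
        seg_q = np.concatenate(boundaries_q)

        cuts = _edge_cut_params(a2, b2, seg_p, seg_q)
        for e in range(len(a3)):
            ts = np.unique(np.concatenate([[0.0, 1.0], cuts[e]]))
            mids = a2[e] + np.outer((ts[:-1] + ts[1:]) / 2.0, b2[e] - a2[e])
            regions = partition.region_of_points(mids)
            for k, region in enumerate(regions):
                piece = (ts[k + 1] - ts[k]) * L3[e]
                if piece <= 0:
                    continue
                if region is None:
                    region = partition.nearest_region(mids[k])
                    table.outside_footprint_length += piece
                    table.n_outside_points += 1
                table.lengths[(region, surfaces[e])] += piece

    # fin terminals
    for nid in tree.terminals():
        lab = tree.label(nid)
        if lab in FIN_LABELS:
            pt = plane.to_2d(tree.position(nid))[0]
            if surface_from_geometry:
                sd = plane.signed_distance(tree.position(nid))[0]
                surface = "medial" if sd >= 0 else "lateral"
            else:
                surface = "medial" if lab == "fin_medial" else "lateral"
            region = partition.region_of_points(pt[None, :])[0]
            if region is None:
                region = partition.nearest_region(pt)
                table.n_outside_points += 1
            table.terminals[(region, surface)] += 1
        elif lab == "axial":
            table.axial_terminals += 1
            pt = plane.to_2d(tree.position(nid))
            if _points_in_ring(pt, partition.footprint_ring)[0]:
                table.axial_under_fin_terminals += 1

    # axial innervation under the actual fin footprint
    aa3, ab3, _ = _collect_edges(tree, ["axial"])
    if len(aa3):
        aL3 = np.linalg.norm(ab3 - aa3, axis=1)
        table.axial_length = float(aL3.sum())
        inside = _split_lengths_by_polygon(
            plane.to_2d(aa3), plane.to_2d(ab3), aL3, partition.footprint_ring
        )
        table.axial_under_fin_length = float(inside.sum())

    if table.n_outside_points:
        warnings.warn(
            f"{table.n_outside_points} fin-labeled pieces projected outside the "
            f"footprint ({table.outside_footprint_length:.3g} um assigned to nearest region)"
        )
    return table


# ---------------------------------------------------------------------------
# Model fin and axial overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelFin:
    """A stereotyped 2D fin outline with its base edge.

    The base angle convention: the angle (degrees, counterclockwise) between
    the base direction (side 1 -> side 2, i.e. running along the body axis)
    and the +x axis of the 2D frame in which the polygon lives.
    """

    outline: np.ndarray  # (9, 2) FM-ring-shaped outline, closed along the base
    base: np.ndarray  # (2, 2): base point side 1, base point side 2

    def __post_init__(self) -> None:
        poly = Polygon(self.outline)
        if not poly.is_valid:
            raise GeometryError("model fin outline self-intersects")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.outline)

    @property
    def base_midpoint(self) -> np.ndarray:
        return self.base.mean(axis=0)

    @property
    def base_angle_deg(self) -> float:
        d = self.base[1] - self.base[0]
        return math.degrees(math.atan2(d[1], d[0]))


def build_model_fin(
    fins: Iterable[tuple[FinLandmarkSet, FitPlane]]
) -> ModelFin:
    """Mean projected fin outline across a cohort, in a canonical base frame.

    Each fish's projected FM ring is moved so its base midpoint sits at the
    origin with the base along +x, then corresponding vertices are averaged.
    """
    rings = []
    for landmarks, plane in fins:
        fm2 = plane.to_2d(landmarks.ring("fm"))
        b1, b2 = fm2[0], fm2[8]
        mid = 0.5 * (b1 + b2)
        d = b2 - b1
        ang = math.atan2(d[1], d[0])
        c, s = math.cos(-ang), math.sin(-ang)
        R = np.array([[c, -s], [s, c]])
        rings.append((fm2 - mid) @ R.T)
    if not rings:
        raise GeometryError("no fins supplied")
    mean_ring = np.mean(rings, axis=0)
    return ModelFin(outline=mean_ring, base=np.array([mean_ring[0], mean_ring[8]]))


def register_model_fin(
    model: ModelFin, fish_base_midpoint: np.ndarray, fish_base_angle: float
) -> Polygon:
    """Rigidly place the model fin (rotation + translation, no scaling).

    The model's base midpoint lands on ``fish_base_midpoint`` and its base
    direction makes ``fish_base_angle`` degrees with the +x axis.
    """
    poly = model.polygon
    rotated = shapely.affinity.rotate(
        poly,
        fish_base_angle - model.base_angle_deg,
        origin=tuple(model.base_midpoint),
    )
    t = np.asarray(fish_base_midpoint, dtype=float) - model.base_midpoint
    return shapely.affinity.translate(rotated, xoff=t[0], yoff=t[1])


def axial_overlap(
    tree: NeuronTree, placed_fin: Polygon | np.ndarray, plane: FitPlane
) -> tuple[float, float]:
    """Axial innervation projected inside a placed fin outline.

    Returns ``(length_within_um, percent_of_total_axial)``; the length is 3D
    arc length of the clipped pieces.  A neuron without axial innervation
    returns ``(0.0, 0.0)`` with a warning.
    """
    if isinstance(placed_fin, Polygon):
        ring = np.asarray(placed_fin.exterior.coords)[:-1]
    else:
        ring = np.asarray(placed_fin, dtype=float)
    a3, b3, _ = _collect_edges(tree, ["axial"])
    if len(a3) == 0:
        warnings.warn("neuron has no axial innervation; overlap is 0")
        return 0.0, 0.0
    L3 = np.linalg.norm(b3 - a3, axis=1)
    total = float(L3.sum())
    if total <= 0:
        warnings.warn("axial innervation has zero length; overlap is 0")
        return 0.0, 0.0
    inside = _split_lengths_by_polygon(plane.to_2d(a3), plane.to_2d(b3), L3, ring)
    within = float(inside.sum())
    return within, 100.0 * within / total
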