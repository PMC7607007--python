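"""Reading, validating and writing traced neuron reconstructions.

Neuron traces are exchanged as standard 7-column SWC files
(``id type x y z radius parent``, ``#`` comments allowed).  Coordinates are
interpreted as micrometres throughout; no unit conversion is applied.

Surface membership (axial body wall vs. medial or lateral fin surface) is not
encoded in SWC structure codes but carried in a sidecar two-column TSV mapping
``node_id`` to a label, keeping the SWC files standard-compliant.  Per-neuron
scalar metadata (soma area, anteroposterior soma position relative to the
myomere 3/4 boundary) travel in a small CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SURFACE_LABELS",
    "FIN_LABELS",
    "SWCFormatError",
    "SWCStructureError",
    "NeuronNode",
    "NeuronTree",
    "NeuronMetadata",
    "read_swc",
    "write_swc",
    "read_annotations",
    "write_annotations",
    "read_metadata",
    "write_metadata",
]

#: Allowed surface annotation labels.
SURFACE_LABELS = ("axial", "fin_medial", "fin_lateral", "unlabeled")
#: Labels marking innervation of the fin proper.
FIN_LABELS = ("fin_medial", "fin_lateral")

#: Radius written out when a node carries no radius (centerline metrics ignore it).
DEFAULT_RADIUS = 1.0


class SWCFormatError(ValueError):
    """Malformed SWC content (wrong column count, duplicate ids, bad numbers)."""


class SWCStructureError(ValueError):
    """Structurally invalid tree (missing parents, cycles, multiple roots)."""


@dataclass(frozen=True)
class NeuronNode:
    """A single traced sample point."""

    node_id: int
    parent_id: int  # -1 for the root (soma)
    position: np.ndarray  # (3,) in micrometres
    radius: float | None = None
    structure_label: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise SWCFormatError(f"node {self.node_id}: position must be 3D")
        if not np.all(np.isfinite(pos)):
            raise SWCFormatError(f"node {self.node_id}: non-finite coordinates")
        object.__setattr__(self, "position", pos)


class NeuronTree:
    """A validated rooted tree of traced nodes with optional surface labels.

    Parameters
    ----------
    nodes:
        Nodes in file order.  Exactly one node must have ``parent_id == -1``
        (the root, taken to be the soma); every other parent must resolve to a
        node in the collection and the parent links must form a single
        connected, acyclic tree.
    annotations:
        Optional mapping node_id -> surface label.  Nodes absent from the
        mapping are reported as ``"unlabeled"``.
    """

    def __init__(
        self,
        nodes: Iterable[NeuronNode],
        annotations: Mapping[int, str] | None = None,
    ) -> None:
        node_list = list(nodes)
        if not node_list:
            raise SWCFormatError("tree has zero nodes")
        self._nodes: dict[int, NeuronNode] = {}
        roots = []
        for n in node_list:
            if n.node_id in self._nodes:
                raise SWCFormatError(f"duplicate node_id {n.node_id}")
            if n.node_id <= 0:
                raise SWCFormatError(f"node_id must be positive, got {n.node_id}")
            self._nodes[n.node_id] = n
            if n.parent_id == -1:
                roots.append(n.node_id)
        if len(roots) != 1:
            raise SWCStructureError(
                f"expected exactly one root (parent_id == -1), found {len(roots)}"
            )
        self.root_id: int = roots[0]

        self._children: dict[int, list[int]] = {nid: [] for nid in self._nodes}
        for n in node_list:
            if n.parent_id == -1:
                continue
            if n.parent_id not in self._nodes:
                raise SWCStructureError(
                    f"node {n.node_id} references missing parent {n.parent_id}"
                )
            self._children[n.parent_id].append(n.node_id)

        # Reachability from the root: every node has exactly one parent link, so
        # unreachable nodes (all of whose parents resolve) necessarily sit on a
        # cycle detached from the root.
        seen = set()
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            seen.add(nid)
            stack.extend(self._children[nid])
        if len(seen) != len(self._nodes):
            orphans = sorted(set(self._nodes) - seen)
            raise SWCStructureError(
                f"cycle detected: nodes {orphans[:10]} are not reachable from the root"
            )

        self.annotations: dict[int, str] = {}
        if annotations:
            for nid, lab in annotations.items():
                self._check_annotation(nid, lab)
                self.annotations[int(nid)] = lab

    # -- basic accessors ---------------------------------------------------

    def _check_annotation(self, node_id: int, label: str) -> None:
        if label not in SURFACE_LABELS:
            raise ValueError(
                f"unknown surface label {label!r}; allowed: {SURFACE_LABELS}"
            )
        if int(node_id) not in self._nodes:
            raise ValueError(f"annotation for node {node_id} not present in tree")

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, node_id: int) -> bool:
        return node_id in self._nodes

    @property
    def node_ids(self) -> list[int]:
        return list(self._nodes)

    def node(self, node_id: int) -> NeuronNode:
        return self._nodes[node_id]

    def position(self, node_id: int) -> np.ndarray:
        return self._nodes[node_id].position

    def parent(self, node_id: int) -> int:
        return self._nodes[node_id].parent_id

    def children(self, node_id: int) -> list[int]:
        return self._children[node_id]

    def label(self, node_id: int) -> str:
        return self.annotations.get(node_id, "unlabeled")

    def terminals(self) -> list[int]:
        return [nid for nid, ch in self._children.items() if not ch]

    def edges(self) -> list[tuple[int, int]]:
        """All (parent, child) pairs, in node order of the child."""
        return [
            (n.parent_id, n.node_id)
            for n in self._nodes.values()
            if n.parent_id != -1
        ]

    def edge_length(self, child_id: int) -> float:
        n = self._nodes[child_id]
        return float(np.linalg.norm(n.position - self._nodes[n.parent_id].position))

    def with_annotations(self, annotations: Mapping[int, str]) -> "NeuronTree":
        """Return a copy of this tree carrying the given surface labels."""
        return NeuronTree(self._nodes.values(), annotations)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "NeuronTree":
        """Return a rigidly transformed copy (positions -> R @ p + t)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_nodes = [
            NeuronNode(n.node_id, n.parent_id, R @ n.position + t, n.radius, n.structure_label)
            for n in self._nodes.values()
        ]
        return NeuronTree(new_nodes, dict(self.annotations))


@dataclass
class NeuronMetadata:
    """Per-neuron scalars that enter the feature vector as-is.

    ``ap_position`` is signed micrometres relative to the myomere 3/4
    boundary: negative values lie in the hindbrain, positive in the spinal
    cord (where the labeled cells are Rohon-Beard neurons).
    """

    neuron_id: str
    soma_area: float  # μm², measured at a single-micron z-slice
    ap_position: float  # μm, signed
    population: str | None = None  # "HB" | "RB"

    def __post_init__(self) -> None:
        if not (self.soma_area > 0):
            raise ValueError(f"{self.neuron_id}: soma_area must be positive")
        if not math.isfinite(self.ap_position):
            raise ValueError(f"{self.neuron_id}: ap_position must be finite")
        if self.population is not None and self.population not in ("HB", "RB"):
            raise ValueError(f"{self.neuron_id}: population must be HB or RB")


# ---------------------------------------------------------------------------
# SWC files
# ---------------------------------------------------------------------------

def read_swc(path: str | Path) -> NeuronTree:
    """Parse a 7-column whitespace-delimited SWC file into a validated tree.

    If several nodes carry SWC structure code 1 (soma), the node with
    ``parent_id == -1`` is the root; structure codes are otherwise advisory.
    """
    path = Path(path)
    nodes: list[NeuronNode] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCFormatError(
                f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}"
            )
        try:
            nid = int(parts[0])
            stype = int(parts[1])
            xyz = [float(parts[2]), float(parts[3]), float(parts[4])]
            radius = float(parts[5])
            parent = int(parts[6])
        except ValueError as exc:
            raise SWCFormatError(f"{path.name}:{lineno}: {exc}") from exc
        nodes.append(NeuronNode(nid, parent, np.array(xyz), radius, stype))
    if not nodes:
        raise SWCFormatError(f"{path.name}: no data lines")
    return NeuronTree(nodes)


def write_swc(tree: NeuronTree, path: str | Path) -> None:
    """Write a tree as standard SWC (read_swc ∘ write_swc is the identity)."""
    path = Path(path)
    lines = []
    for nid in tree.node_ids:
        n = tree.node(nid)
        r = float(DEFAULT_RADIUS if n.radius is None else n.radius)
        x, y, z = (float(v) for v in n.position)
        lines.append(
            f"{n.node_id} {n.structure_label} {x!r} {y!r} {z!r} {r!r} {n.parent_id}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sidecar annotations and metadata
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path, tree: NeuronTree) -> NeuronTree:
    """Attach surface labels from a two-column TSV (node_id, label).

    Nodes not listed remain ``"unlabeled"``.  Unknown labels or node ids not
    present in the tree raise ``ValueError``.
    """
    path = Path(path)
    annotations: dict[int, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"{path.name}:{lineno}: expected 2 columns")
        if parts[0] == "node_id":  # optional header
            continue
        try:
            nid = int(parts[0])
        except ValueError as exc:
            raise ValueError(f"{path.name}:{lineno}: bad node_id {parts[0]!r}") from exc
        label = parts[1]
        if label not in SURFACE_LABELS:
            raise ValueError(
                f"{path.name}:{lineno}: unknown label {label!r}; allowed: {SURFACE_LABELS}"
            )
        if nid not in tree:
            raise ValueError(f"{path.name}:{lineno}: node {nid} not in tree")
        annotations[nid] = label
    return tree.with_annotations(annotations)


def write_annotations(tree: NeuronTree, path: str | Path) -> None:
    lines = ["node_id\tlabel"]
    for nid in tree.node_ids:
        lab = tree.label(nid)
        if lab != "unlabeled":
            lines.append(f"{nid}\t{lab}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_metadata(path: str | Path) -> dict[str, NeuronMetadata]:
    """Load the per-neuron metadata CSV (neuron_id, soma_area_um2, ap_position_um, population)."""
    df = pd.read_csv(path, comment="#", dtype={"neuron_id": str})
    required = {"neuron_id", "soma_area_um2", "ap_position_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    out: dict[str, NeuronMetadata] = {}
    for row in df.itertuples(index=False):
        pop = getattr(row, "population", None)
        if pop is not None and (pd.isna(pop) or pop == ""):
            pop = None
        out[row.neuron_id] = NeuronMetadata(
            neuron_id=row.neuron_id,
            soma_area=float(row.soma_area_um2),
            ap_position=float(row.ap_position_um),
            population=pop,
        )
    return out


def write_metadata(meta: Iterable[NeuronMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "neuron_id": m.neuron_id,
                "soma_area_um2": m.soma_area,
                "ap_position_um": m.ap_position,
                "population": m.population,
            }
            for m in meta
        ]
    )
    df.to_csv(path, index=False)
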