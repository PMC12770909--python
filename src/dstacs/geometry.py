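"""Cortical-sheet geometry: meshes, outward normals, node areas, region labels.

All field metrics in this package are evaluated on a triangulated grey-matter
sheet.  The sheet carries, per node, an outward unit normal (the direction of
the principal dendritic axis of pyramidal neurones, which is the direction
most relevant for polarisation by weak electric fields) and a node area (one
third of every incident triangle, so that node areas sum exactly to the total
surface area).  Region labels partition the sheet into the two stimulation
targets (left and right primary motor cortex) and a surrounding belt of grey
matter; metrics are computed per named region set.

Coordinates are millimetres, areas mm².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CorticalSheet",
    "compute_vertex_normals",
    "compute_vertex_areas",
    "normal_component",
]

_DEGENERATE_AREA = 1e-12


def _triangle_geometry(node_coords: np.ndarray, triangles: np.ndarray):
    """Face normals (unnormalised cross products) and areas for each triangle."""
    a = node_coords[triangles[:, 0]]
    b = node_coords[triangles[:, 1]]
    c = node_coords[triangles[:, 2]]
    cross = np.cross(b - a, c - a)
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    return cross, areas


def compute_vertex_normals(node_coords: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Outward unit normal per node, as the angle-weighted mean of incident
    triangle normals.

    Angle weighting makes the result independent of how a smooth surface was
    triangulated (a node surrounded by many thin triangles is not biased
    toward them).  For a closed, consistently wound mesh the orientation is
    made outward, i.e. away from the mesh centroid.

    Parameters
    ----------
    node_coords : (N, 3) float array, mm
    triangles : (M, 3) int array of node indices

    Raises
    ------
    ValueError
        If a node belongs to no triangle (no normal can be defined there).
    """
    node_coords = np.asarray(node_coords, dtype=float)
    triangles = np.asarray(triangles, dtype=np.intp)
    n_nodes = node_coords.shape[0]
    if triangles.size and triangles.max() >= n_nodes:
        raise ValueError("triangle index out of range")

    cross, areas = _triangle_geometry(node_coords, triangles)
    degenerate = areas <= _DEGENERATE_AREA
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} degenerate (zero-area) triangles ignored",
            RuntimeWarning,
            stacklevel=2,
        )

    normals = np.zeros((n_nodes, 3))
    touched = np.zeros(n_nodes, dtype=bool)
    good = ~degenerate
    tri = triangles[good]
    face_unit = cross[good] / np.linalg.norm(cross[good], axis=1, keepdims=True)

    # interior angle at each corner of each (non-degenerate) triangle
    for corner in range(3):
        i = tri[:, corner]
        j = tri[:, (corner + 1) % 3]
        k = tri[:, (corner + 2) % 3]
        u = node_coords[j] - node_coords[i]
        v = node_coords[k] - node_coords[i]
        cosang = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(normals, i, face_unit * ang[:, None])
        touched[i] = True
    # degenerate triangles still anchor their nodes (they contribute no
    # direction, but the nodes are not isolated)
    touched[triangles[degenerate].ravel()] |= True

    if not touched.all():
        missing = np.flatnonzero(~touched)
        raise ValueError(f"isolated nodes with no incident triangle: {missing[:5].tolist()}...")

    lengths = np.linalg.norm(normals, axis=1)
    zero = lengths <= 0
    if zero.any():
        # nodes touched only by degenerate triangles: give them an arbitrary
        # but unit direction rather than NaN
        normals[zero] = (0.0, 0.0, 1.0)
        lengths[zero] = 1.0
    normals /= lengths[:, None]

    # orient outward for closed surfaces: flip globally if the majority points
    # toward the centroid
    centroid = node_coords.mean(axis=0)
    outward_score = np.einsum("ij,ij->i", normals, node_coords - centroid).sum()
    if outward_score < 0:
        normals = -normals
    return normals


def compute_vertex_areas(node_coords: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Barycentric node areas: each node owns one third of every incident
    triangle.  Node areas therefore sum exactly to the total surface area.
    """
    node_coords = np.asarray(node_coords, dtype=float)
    triangles = np.asarray(triangles, dtype=np.intp)
    _, tri_areas = _triangle_geometry(node_coords, triangles)
    areas = np.zeros(node_coords.shape[0])
    for corner in range(3):
        np.add.at(areas, triangles[:, corner], tri_areas / 3.0)
    return areas


def normal_component(field: np.ndarray, normals: np.ndarray) -> np.ndarray:
    """Signed projection of a per-node 3-vector field onto the outward unit
    normals: positive = outward, negative = inward.

    ``field`` may be ``(N, 3)`` or ``(T, N, 3)`` (time-resolved); the result
    has shape ``(N,)`` or ``(T, N)`` respectively.
    """
    field = np.asarray(field, dtype=float)
    normals = np.asarray(normals, dtype=float)
    if field.shape[-2] != normals.shape[0]:
        raise ValueError(
            f"field has {field.shape[-2]} nodes but normals have {normals.shape[0]}"
        )
    return np.einsum("...ij,ij->...i", field, normals)


@dataclass
class CorticalSheet:
    """A triangulated grey-matter sheet with per-node attributes.

    Attributes
    ----------
    node_coords : (N, 3) float, mm
    triangles : (M, 3) int
    normals : (N, 3) float, unit outward normals
    node_areas : (N,) float, mm²
    region_labels : (N,) int, one label per node (-1 = unlabelled)
    region_sets : mapping from region-set name to the set of labels it covers.
        The conventional names are ``"M1_left"``, ``"M1_right"`` and
        ``"surrounding"``.
    """

    node_coords: np.ndarray
    triangles: np.ndarray
    normals: np.ndarray
    node_areas: np.ndarray
    region_labels: np.ndarray
    region_sets: dict[str, frozenset[int]] = field(default_factory=dict)

    @classmethod
    def from_mesh(
        cls,
        node_coords: np.ndarray,
        triangles: np.ndarray,
        region_labels: np.ndarray | None = None,
        region_sets: dict[str, frozenset[int]] | None = None,
    ) -> "CorticalSheet":
        """Build a sheet from raw geometry, deriving normals and areas."""
        node_coords = np.asarray(node_coords, dtype=float)
        triangles = np.asarray(triangles, dtype=np.intp)
        if region_labels is None:
            region_labels = np.full(node_coords.shape[0], -1, dtype=int)
        region_labels = np.asarray(region_labels, dtype=int)
        if region_labels.shape[0] != node_coords.shape[0]:
            raise ValueError("region_labels must have one entry per node")
        sheet = cls(
            node_coords=node_coords,
            triangles=triangles,
            normals=compute_vertex_normals(node_coords, triangles),
            node_areas=compute_vertex_areas(node_coords, triangles),
            region_labels=region_labels,
            region_sets=dict(region_sets or {}),
        )
        sheet.validate()
        return sheet

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    def nodes_in(self, *region_set_names: str) -> np.ndarray:
        """Boolean node mask for the union of the named region sets."""
        labels: set[int] = set()
        for name in region_set_names:
            if name not in self.region_sets:
                raise KeyError(f"unknown region set {name!r}")
            labels |= set(self.region_sets[name])
        return np.isin(self.region_labels, sorted(labels))

    def validate(self) -> None:
        if self.triangles.size and self.triangles.max() >= self.n_nodes:
            raise ValueError("triangle index out of range")
        lengths = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(lengths, 1.0, atol=1e-9):
            raise ValueError("normals are not unit length")
        if (self.node_areas <= 0).any():
            raise ValueError("non-positive node area")
        # the three conventional region sets must not share labels
        names = [n for n in ("M1_left", "M1_right", "surrounding") if n in self.region_sets]
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if self.region_sets[a] & self.region_sets[b]:
                    raise ValueError(f"region sets {a!r} and {b!r} share labels")
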