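"""Triangle-mesh bookkeeping for cortical surface bundles.

A cortical hemisphere is represented as a single triangulated topology with
three coordinate layers (white, mid-gray, pial) and per-vertex retinotopic
scalars: polar angle (degrees from the upper vertical meridian, 0-180,
contralateral hemifield convention), eccentricity (degrees), and a visual-area
label.  All surface areas default to the mid-gray layer; geodesic distances
are graph shortest paths over mesh edges with Euclidean weights, which is
adequate downstream because only the *ratio* of two such distances is ever
consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

LAYERS = ("white", "midgray", "pial")
DEFAULT_LAYER = "midgray"
AREA_LABELS = ("V1", "V2", "none")


@dataclass
class VertexRegion:
    """A set of vertex indices on a mesh, with a free-text provenance tag."""

    vertex_ids: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = np.asarray(self.vertex_ids, dtype=np.intp)
        self.vertex_ids = np.unique(ids)

    def __len__(self) -> int:
        return len(self.vertex_ids)


@dataclass
class CorticalSurfaceBundle:
    """Shared-topology triangle mesh with retinotopic per-vertex scalars.

    Parameters
    ----------
    faces : (F, 3) int array
        Vertex-index triples; identical for all layers.
    coords : dict of layer name -> (N, 3) float array
        Vertex positions in mm for each of ``white``, ``midgray``, ``pial``.
    polar_angle : (N,) float array
        Degrees in [0, 180]: 0 = upper vertical meridian, 90 = horizontal,
        180 = lower vertical meridian.
    eccentricity : (N,) float array
        Degrees, finite and >= 0.
    area_label : (N,) str array
        One of ``V1``, ``V2``, ``none`` per vertex.
    hemisphere : {"left", "right"}
    """

    faces: np.ndarray
    coords: dict
    polar_angle: np.ndarray
    eccentricity: np.ndarray
    area_label: np.ndarray
    hemisphere: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.faces = np.asarray(self.faces, dtype=np.intp)
        self.coords = {k: np.asarray(v, dtype=float) for k, v in self.coords.items()}
        self.polar_angle = np.asarray(self.polar_angle, dtype=float)
        self.eccentricity = np.asarray(self.eccentricity, dtype=float)
        self.area_label = np.asarray(self.area_label, dtype=object)

    @property
    def vertex_count(self) -> int:
        return len(self.polar_angle)

    def layer_coords(self, layer: str = DEFAULT_LAYER) -> np.ndarray:
        if layer not in self.coords:
            raise KeyError(
                f"unknown surface layer {layer!r}; have {sorted(self.coords)}"
            )
        return self.coords[layer]

    def validate(self) -> None:
        n = self.vertex_count
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (F, 3) array")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError("face indices out of range")
        if (self.faces[:, 0] == self.faces[:, 1]).any() or (
            self.faces[:, 1] == self.faces[:, 2]
        ).any() or (self.faces[:, 0] == self.faces[:, 2]).any():
            raise ValueError("faces with repeated vertices")
        for layer, xyz in self.coords.items():
            if xyz.shape != (n, 3):
                raise ValueError(f"layer {layer!r} coords shape {xyz.shape} != ({n}, 3)")
        for name, arr in (("polar_angle", self.polar_angle),
                          ("eccentricity", self.eccentricity)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per vertex")
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite values")
        if (self.polar_angle < 0).any() or (self.polar_angle > 180).any():
            raise ValueError("polar_angle outside [0, 180]; clamp before building")
        if (self.eccentricity < 0).any():
            raise ValueError("negative eccentricity")
        bad = set(np.unique(self.area_label)) - set(AREA_LABELS)
        if bad:
            raise ValueError(f"unknown area labels {sorted(bad)}")
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")

    def label_region(self, label: str) -> VertexRegion:
        return VertexRegion(np.flatnonzero(self.area_label == label),
                            provenance=f"area_label == {label}")


def face_areas(bundle: CorticalSurfaceBundle, layer: str = DEFAULT_LAYER) -> np.ndarray:
    """Euclidean area in mm^2 of every triangle on the given layer."""
    xyz = bundle.layer_coords(layer)
    a = xyz[bundle.faces[:, 0]]
    b = xyz[bundle.faces[:, 1]]
    c = xyz[bundle.faces[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def vertex_areas(bundle: CorticalSurfaceBundle, layer: str = DEFAULT_LAYER) -> np.ndarray:
    """Per-vertex surface area: one third of each incident triangle's area.

    Barycentric lumping conserves total area exactly: the values sum to the
    sum of triangle areas on the layer.  Degenerate (zero-area) faces are
    rejected with a diagnostic naming the first offending face.
    """
    fa = face_areas(bundle, layer)
    degenerate = np.flatnonzero(fa <= 0.0)
    if degenerate.size:
        f = int(degenerate[0])
        raise ValueError(
            f"degenerate face {f} (vertices {tuple(bundle.faces[f])}) has zero "
            f"area on layer {layer!r}"
        )
    va = np.zeros(bundle.vertex_count)
    third = fa / 3.0
    for k in range(3):
        np.add.at(va, bundle.faces[:, k], third)
    return va


def region_area(per_vertex_area: np.ndarray, region: VertexRegion) -> float:
    """Total mm^2 of a vertex region (0.0 for an empty region)."""
    ids = region.vertex_ids
    if ids.size == 0:
        return 0.0
    if ids.min() < 0 or ids.max() >= len(per_vertex_area):
        raise IndexError("region contains out-of-range vertex indices")
    return float(per_vertex_area[ids].sum())


def _edge_graph(faces: np.ndarray, xyz: np.ndarray, n: int) -> coo_matrix:
    ii = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
    jj = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    # deduplicate: an interior edge appears in two faces, and COO duplicate
    # entries would be *summed* on conversion, corrupting the weights
    pairs = np.unique(np.sort(np.column_stack([ii, jj]), axis=1), axis=0)
    w = np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1)
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    ww = np.concatenate([w, w])
    return coo_matrix((ww, (rows, cols)), shape=(n, n)).tocsr()


def geodesic_distances(
    bundle: CorticalSurfaceBundle,
    sources: VertexRegion,
    layer: str = DEFAULT_LAYER,
    subset: VertexRegion | None = None,
) -> np.ndarray:
    """Graph-geodesic distance in mm from a source region to every vertex.

    Shortest path over mesh edges (Dijkstra) with Euclidean edge lengths on
    the chosen layer; distance is 0 on source vertices and +inf for vertices
    not edge-connected to any source.  If ``subset`` is given, paths are
    restricted to the subgraph induced by ``subset`` union ``sources`` and
    the returned array is still indexed by global vertex id (inf elsewhere).
    """
    if len(sources) == 0:
        raise ValueError("geodesic_distances requires a non-empty source region")
    n = bundle.vertex_count
    xyz = bundle.layer_coords(layer)
    if subset is None:
        graph = _edge_graph(bundle.faces, xyz, n)
        return dijkstra(graph, directed=False, indices=sources.vertex_ids,
                        min_only=True)
    keep = np.zeros(n, dtype=bool)
    keep[subset.vertex_ids] = True
    keep[sources.vertex_ids] = True
    face_keep = keep[bundle.faces].all(axis=1)
    graph = _edge_graph(bundle.faces[face_keep], xyz, n)
    out = dijkstra(graph, directed=False, indices=sources.vertex_ids,
                   min_only=True)
    out[~keep] = np.inf
    return out
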