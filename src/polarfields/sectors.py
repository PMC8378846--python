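"""Resampling coarse retinotopic sectors into a fine polar-angle x
eccentricity grid.

Hand-drawn (or synthetic) coarse sectors are bounded by two iso-polar-angle
contours and two iso-eccentricity contours.  Each sector is resampled
independently:

1. For each axis (tangential = polar angle, radial = eccentricity) compute
   the relative distance r = (d1 - d2) / (d1 + d2) per vertex, where d1 and
   d2 are geodesic distances in mm along the cortical surface from the two
   opposing boundary contours.  r is exactly -1 on the first boundary, +1 on
   the second, and varies smoothly between them.
2. Fit a monotone (isotonic) regression of the measured coordinate on r.
   The monotone fit denoises the retinotopic map while guaranteeing a
   bijective continuous relation between r and the coordinate.
3. Invert the fitted relation at the requested bin edges and assign every
   sector vertex to exactly one bin by its fitted coordinate.

Fine bins are the intersections of tangential and radial bins; within each
coarse sector they partition the sector's vertex set exactly, so fine-bin
areas sum to the sector area to floating tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .surface import (
    DEFAULT_LAYER,
    CorticalSurfaceBundle,
    VertexRegion,
    geodesic_distances,
)

log = logging.getLogger(__name__)

#: fine-grain eccentricity edges nested inside the coarse bands 1-2, 2-4, 4-7
DEFAULT_ECC_EDGES = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0)


@dataclass
class CoarseSector:
    """One hand-drawn sector: a vertex set plus its four boundary contours."""

    vertices: VertexRegion
    visual_area: str                      # "V1" or "V2"
    angular_band: tuple[float, float]     # degrees, e.g. (0, 90) = UVM-HM
    ecc_band: tuple[float, float]         # degrees, e.g. (1, 2)
    boundary_a: VertexRegion              # iso-angle contour at angular_band[0]
    boundary_b: VertexRegion              # iso-angle contour at angular_band[1]
    boundary_e1: VertexRegion             # iso-ecc contour at ecc_band[0]
    boundary_e2: VertexRegion             # iso-ecc contour at ecc_band[1]
    name: str = ""

    def __post_init__(self) -> None:
        for tag, b in (("A", self.boundary_a), ("B", self.boundary_b),
                       ("E1", self.boundary_e1), ("E2", self.boundary_e2)):
            if len(b) == 0:
                raise ValueError(f"sector {self.name!r}: boundary {tag} is empty")
            if not np.isin(b.vertex_ids, self.vertices.vertex_ids).all():
                raise ValueError(
                    f"sector {self.name!r}: boundary {tag} not a subset of the sector"
                )


@dataclass
class RelativeDistanceField:
    """Per-vertex relative distance r = (d1-d2)/(d1+d2) within a sector."""

    vertex_ids: np.ndarray
    r: np.ndarray
    d1: np.ndarray
    d2: np.ndarray


def relative_distance(
    bundle: CorticalSurfaceBundle,
    sector: CoarseSector,
    axis: str = "tangential",
    layer: str = DEFAULT_LAYER,
) -> RelativeDistanceField:
    """Relative geodesic distance between a sector's two opposing boundaries.

    ``axis`` selects the boundary pair: ``tangential`` uses the iso-angle
    contours (A, B), ``radial`` the iso-eccentricity contours (E1, E2).
    Distances are measured on the subgraph induced by the sector's vertices,
    so neighbouring sectors never shortcut each other's fields.
    """
    if axis == "tangential":
        src1, src2 = sector.boundary_a, sector.boundary_b
    elif axis == "radial":
        src1, src2 = sector.boundary_e1, sector.boundary_e2
    else:
        raise ValueError(f"axis must be 'tangential' or 'radial', got {axis!r}")
    ids = sector.vertices.vertex_ids
    d1 = geodesic_distances(bundle, src1, layer=layer, subset=sector.vertices)[ids]
    d2 = geodesic_distances(bundle, src2, layer=layer, subset=sector.vertices)[ids]
    total = d1 + d2
    if not np.isfinite(total).all():
        raise ValueError(
            f"sector {sector.name!r}: some vertices are not connected to both "
            f"{axis} boundaries"
        )
    if (total <= 0).any():
        raise ValueError(
            f"sector {sector.name!r}: {axis} boundaries intersect "
            "(a vertex has d1 = d2 = 0)"
        )
    return RelativeDistanceField(vertex_ids=ids, r=(d1 - d2) / total, d1=d1, d2=d2)


@dataclass
class MonotoneCoordinateMap:
    """Strictly monotone map r -> coordinate, invertible by interpolation.

    ``r_grid`` is strictly increasing; ``value_grid`` is strictly monotone
    (increasing or decreasing depending on the sector's orientation).
    """

    r_grid: np.ndarray
    value_grid: np.ndarray
    increasing: bool = True

    def predict(self, r) -> np.ndarray:
        return np.interp(np.asarray(r, dtype=float), self.r_grid, self.value_grid)

    def inverse(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.increasing:
            return np.interp(values, self.value_grid, self.r_grid)
        return np.interp(values, self.value_grid[::-1], self.r_grid[::-1])


def fit_monotone_map(r: np.ndarray, values: np.ndarray) -> MonotoneCoordinateMap:
    """Monotone least-squares fit of a retinotopic coordinate against r.

    Isotonic regression (pooled adjacent violators) with automatic
    orientation; the fitted step function is made strictly increasing by
    spreading tied plateaus linearly over an epsilon, which keeps the map
    bijective and hence invertible.  Requires at least 10 points and a
    non-degenerate coordinate range.
    """
    r = np.asarray(r, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(r) & np.isfinite(values)
    if ok.sum() < 10:
        raise ValueError("need at least 10 vertices with finite r and coordinate")
    r, values = r[ok], values[ok]
    if np.ptp(values) == 0:
        raise ValueError("degenerate sector: all coordinate values identical")
    iso = IsotonicRegression(increasing="auto", out_of_bounds="clip")
    fitted = iso.fit_transform(r, values)
    order = np.argsort(r, kind="stable")
    r_sorted = r[order]
    f_sorted = fitted[order]
    increasing = f_sorted[-1] >= f_sorted[0]
    if not increasing:
        f_sorted = -f_sorted
    # collapse duplicate r, then break plateaus by an epsilon ramp so the
    # grid is strictly increasing in both coordinates
    r_u, idx = np.unique(r_sorted, return_index=True)
    f_u = f_sorted[idx]
    f_u = np.maximum.accumulate(f_u)
    eps = max(np.ptp(f_u), 1.0) * 1e-9
    f_u = f_u + eps * np.arange(len(f_u))
    return MonotoneCoordinateMap(
        r_grid=r_u,
        value_grid=f_u if increasing else -f_u,
        increasing=increasing,
    )


def _band_edges(edges, band: tuple[float, float], what: str) -> np.ndarray:
    """Bin edges restricted to a coarse band; band endpoints must be edges."""
    edges = np.asarray(sorted(edges), dtype=float)
    lo, hi = band
    if not (np.isclose(edges, lo).any() and np.isclose(edges, hi).any()):
        raise ValueError(
            f"{what} bin edges {edges.tolist()} do not align with the coarse "
            f"band {band}; regenerate the fine grid with compatible edges"
        )
    inside = edges[(edges > lo - 1e-9) & (edges < hi + 1e-9)]
    if len(inside) < 2:
        raise ValueError(f"{what} bin edges fall outside the sector band {band}")
    return inside


def split_by_coordinate(
    sector: CoarseSector,
    field_vals: np.ndarray,
    mapping: MonotoneCoordinateMap,
    edges: np.ndarray,
) -> dict:
    """Assign each sector vertex to one bin by its fitted coordinate.

    Returns ``{(lo, hi): vertex-id array}`` over consecutive edge pairs;
    bins are half-open [lo, hi) except the last, which is closed, so the
    bins partition the sector's vertex set exactly.

    Vertices whose fitted value falls exactly on an interior edge lie on the
    iso-contour shared by two bins; they are alternated between the two so
    the shared row splits evenly rather than inflating one side (an unbiased
    deterministic tie-break; with noisy data ties are measure-zero).
    """
    fitted = mapping.predict(field_vals)
    # digitize against interior edges: values below edges[1] -> bin 0, etc.
    idx = np.digitize(fitted, edges[1:-1], right=False)
    tie_atol = max(np.ptp(edges) * 1e-6, 1e-2 * np.min(np.diff(edges)))
    for k, edge in enumerate(edges[1:-1]):
        on_edge = np.flatnonzero(np.abs(fitted - edge) <= tie_atol)
        idx[on_edge[::2]] = k       # digitize put every tie in bin k+1
        idx[on_edge[1::2]] = k + 1
    out = {}
    for k in range(len(edges) - 1):
        out[(float(edges[k]), float(edges[k + 1]))] = sector.vertices.vertex_ids[
            idx == k
        ]
    return out


@dataclass
class FineSectorGrid:
    """Fine polar-angle x eccentricity bins for one hemisphere.

    ``bins`` maps (visual_area, (ang_lo, ang_hi), (ecc_lo, ecc_hi)) to a
    vertex-id array.  Bins from one coarse sector partition that sector;
    bins from different sectors may share contour vertices, so consumers
    union vertex sets (never add areas) when assembling ROIs.
    """

    bins: dict
    angular_edges: tuple
    ecc_edges: tuple
    hemisphere: str

    def region(self, visual_area, ang_bin, ecc_bin) -> np.ndarray:
        return self.bins.get((visual_area, ang_bin, ecc_bin), np.empty(0, dtype=np.intp))

    def select(self, visual_areas, ang_lo, ang_hi, ecc_lo, ecc_hi) -> np.ndarray:
        """Union of all bins fully inside the given angular/ecc window."""
        parts = []
        for (va, ab, eb), ids in self.bins.items():
            if va not in visual_areas:
                continue
            if ab[0] >= ang_lo - 1e-9 and ab[1] <= ang_hi + 1e-9 and \
               eb[0] >= ecc_lo - 1e-9 and eb[1] <= ecc_hi + 1e-9:
                parts.append(ids)
        if not parts:
            return np.empty(0, dtype=np.intp)
        return np.unique(np.concatenate(parts))


def resample_sector(
    bundle: CorticalSurfaceBundle,
    sector: CoarseSector,
    angular_edges,
    ecc_edges=DEFAULT_ECC_EDGES,
    layer: str = DEFAULT_LAYER,
) -> dict:
    """Resample one coarse sector into fine angle x eccentricity bins.

    The tangential and radial axes are resampled independently with the same
    relative-distance + isotonic-fit procedure; fine bins are the
    intersections.  Polar angles outside [0, 180] (ipsilateral pRF centers)
    are clamped to the nearest vertical meridian and counted in the log.
    """
    ids = sector.vertices.vertex_ids
    angle = bundle.polar_angle[ids]
    n_ipsi = int(((angle < 0) | (angle > 180)).sum())
    if n_ipsi:
        log.info("sector %s: clamped %d ipsilateral polar angles into [0, 180]",
                 sector.name, n_ipsi)
        angle = np.clip(angle, 0.0, 180.0)

    a_edges = _band_edges(angular_edges, sector.angular_band, "angular")
    rf_t = relative_distance(bundle, sector, "tangential", layer=layer)
    map_t = fit_monotone_map(rf_t.r, angle)
    ang_bins = split_by_coordinate(sector, rf_t.r, map_t, a_edges)

    e_edges = _band_edges(ecc_edges, sector.ecc_band, "eccentricity")
    if len(e_edges) == 2:
        ecc_bins = {(float(e_edges[0]), float(e_edges[1])): ids}
    else:
        rf_r = relative_distance(bundle, sector, "radial", layer=layer)
        map_r = fit_monotone_map(rf_r.r, bundle.eccentricity[ids])
        ecc_bins = split_by_coordinate(sector, rf_r.r, map_r, e_edges)

    out = {}
    for ab, a_ids in ang_bins.items():
        for eb, e_ids in ecc_bins.items():
            out[(sector.visual_area, ab, eb)] = np.intersect1d(
                a_ids, e_ids, assume_unique=True
            )
    return out


def build_fine_grid(
    bundle: CorticalSurfaceBundle,
    sectors,
    angular_edges,
    ecc_edges=DEFAULT_ECC_EDGES,
    layer: str = DEFAULT_LAYER,
) -> FineSectorGrid:
    """Resample every coarse sector of a hemisphere into one fine grid.

    Coarse sectors are closed bands, so abutting sectors share their
    boundary contour.  Within each sector the fine bins partition the
    sector's vertex set exactly; across sectors the grid deduplicates: a
    vertex on a shared contour is claimed by the higher band (half-open
    [lo, hi) semantics), keeping the grid's bins globally disjoint so ROI
    and band areas are additive.
    """
    bins: dict = {}
    claimed = np.zeros(bundle.vertex_count, dtype=bool)
    order = sorted(
        range(len(sectors)),
        key=lambda i: (sectors[i].visual_area,
                       -sectors[i].angular_band[0],
                       -sectors[i].ecc_band[0]),
    )
    for i in order:
        sector = sectors[i]
        for key, ids in resample_sector(
            bundle, sector, angular_edges, ecc_edges, layer=layer
        ).items():
            ids = ids[~claimed[ids]]
            claimed[ids] = True
            if key in bins:
                bins[key] = np.unique(np.concatenate([bins[key], ids]))
            else:
                bins[key] = ids
    return FineSectorGrid(
        bins=bins,
        angular_edges=tuple(float(e) for e in sorted(angular_edges)),
        ecc_edges=tuple(float(e) for e in sorted(ecc_edges)),
        hemisphere=bundle.hemisphere,
    )


def angular_edges_for_width(width_deg: float, phase_deg: float = 0.0) -> tuple:
    """Angular bin edges over [0, 180] for a given fine-bin width.

    ``phase_deg`` shifts the edge lattice: 0 gives edges at 0, w, 2w, ...
    (the 10-degree grid); ``phase=width/2`` gives edges at w/2, 3w/2, ...
    plus the 0/180 endpoints (the wedge-centered 15-degree grid).  Edges must
    include 0, 90 and 180 or the coarse bands cannot be resampled; 90 is
    required to be on the lattice.
    """
    if width_deg <= 0 or width_deg > 90:
        raise ValueError("fine-bin width must be in (0, 90]")
    edges = np.arange(phase_deg, 180.0 + 1e-9, width_deg)
    edges = np.unique(np.concatenate([[0.0, 90.0, 180.0], edges]))
    if not np.isclose(edges, 90.0).any():
        raise ValueError("angular edges must include the horizontal meridian (90)")
    return tuple(float(e) for e in edges[(edges >= 0) & (edges <= 180 + 1e-9)])
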