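"""Wedge ROI assembly from fine sector grids.

ROIs are unions of fine polar-angle x eccentricity bins around the cardinal
meridians, in the hemifield convention (0 = UVM, 90 = HM, 180 = LVM per
hemisphere):

* ``HM``   - V1 bins within +/-theta of 90; each hemisphere contributes the
  contralateral wedge, so a bilateral ROI spans 4*theta of visual field.
* ``UVM`` / ``LVM`` - bins within theta of 0 (resp. 180); these ROIs straddle
  the V1/V2 border symmetrically by default (V1-only selectable).
* ``VM``   - the V1-only union of the UVM and LVM windows, the vertical
  counterpart of HM for horizontal-vertical comparisons.

Cumulative ROIs grow with theta; the incremental ROI at theta is the set
difference cumulative(theta) minus cumulative(theta - bin width), so the
incremental series is pairwise disjoint and unions back to the widest
cumulative ROI exactly.  All ROIs are restricted to an eccentricity range
(default 1-6 deg).  Areas are always summed over both hemispheres per
subject before any asymmetry is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sectors import FineSectorGrid
from .surface import DEFAULT_LAYER, CorticalSurfaceBundle, VertexRegion, vertex_areas

MERIDIANS = ("HM", "UVM", "LVM", "VM")


@dataclass(frozen=True)
class WedgeSpec:
    meridian: str
    half_width: float
    mode: str = "cumulative"
    ecc_range: tuple[float, float] = (1.0, 6.0)
    areas: str = "V1+V2"  # straddling option for UVM/LVM; HM and VM are V1-only

    def __post_init__(self) -> None:
        if self.meridian not in MERIDIANS:
            raise ValueError(f"meridian must be one of {MERIDIANS}")
        if not 0 < self.half_width <= 90:
            raise ValueError("half_width must be in (0, 90] degrees")
        if self.mode not in ("cumulative", "incremental"):
            raise ValueError("mode must be 'cumulative' or 'incremental'")
        if self.areas not in ("V1-only", "V1+V2"):
            raise ValueError("areas must be 'V1-only' or 'V1+V2'")


def _require_edge(grid: FineSectorGrid, value: float) -> None:
    edges = np.asarray(grid.angular_edges)
    if not np.isclose(edges, value).any():
        raise ValueError(
            f"angular value {value} deg is not an edge of the fine grid "
            f"{edges.tolist()}; widths must be multiples of the fine-bin width"
        )


def _cumulative_ids(grid: FineSectorGrid, spec: WedgeSpec) -> np.ndarray:
    lo_e, hi_e = spec.ecc_range
    w = spec.half_width
    if spec.meridian == "HM":
        _require_edge(grid, 90 - w)
        _require_edge(grid, 90 + w)
        return grid.select(("V1",), 90 - w, 90 + w, lo_e, hi_e)
    vas = ("V1",) if spec.areas == "V1-only" or spec.meridian == "VM" else ("V1", "V2")
    parts = []
    if spec.meridian in ("UVM", "VM"):
        _require_edge(grid, w)
        parts.append(grid.select(vas, 0.0, w, lo_e, hi_e))
    if spec.meridian in ("LVM", "VM"):
        _require_edge(grid, 180 - w)
        parts.append(grid.select(vas, 180 - w, 180.0, lo_e, hi_e))
    return np.unique(np.concatenate(parts)) if parts else np.empty(0, dtype=np.intp)


def assemble_wedge(grid: FineSectorGrid, spec: WedgeSpec) -> VertexRegion:
    """Vertex region of one wedge ROI in one hemisphere's fine grid."""
    ids = _cumulative_ids(grid, spec)
    if spec.mode == "incremental":
        bin_w = float(np.min(np.diff(grid.angular_edges)))
        inner_w = spec.half_width - bin_w
        if inner_w > 1e-9:
            inner = _cumulative_ids(
                grid,
                WedgeSpec(spec.meridian, inner_w, "cumulative",
                          spec.ecc_range, spec.areas),
            )
            ids = np.setdiff1d(ids, inner, assume_unique=True)
    return VertexRegion(ids, provenance=f"{spec.meridian}+-{spec.half_width}"
                                         f" {spec.mode} {spec.areas}")


def subject_area_table(
    subject_id: str,
    bundles: dict,
    grids: dict,
    half_widths=(10, 20, 30, 40, 50),
    modes=("cumulative", "incremental"),
    ecc_range=(1.0, 6.0),
    vma_areas: str = "V1+V2",
    layer: str = DEFAULT_LAYER,
) -> pd.DataFrame:
    """Bilateral wedge areas for one subject, long format.

    Returns rows (subject, meridian, half_width_deg, mode, ecc_lo, ecc_hi,
    layer, area_mm2) with the two hemispheres summed.  HM and VM ROIs are
    V1-only; UVM/LVM use ``vma_areas``.
    """
    va = {h: vertex_areas(b, layer) for h, b in bundles.items()}
    rows = []
    for mode in modes:
        for w in half_widths:
            for meridian in MERIDIANS:
                areas_opt = "V1-only" if meridian in ("HM", "VM") else vma_areas
                spec = WedgeSpec(meridian, float(w), mode, tuple(ecc_range),
                                 areas_opt)
                total = 0.0
                for h, grid in grids.items():
                    region = assemble_wedge(grid, spec)
                    total += float(va[h][region.vertex_ids].sum())
                rows.append({
                    "subject": subject_id, "meridian": meridian,
                    "half_width_deg": float(w), "mode": mode,
                    "ecc_lo": ecc_range[0], "ecc_hi": ecc_range[1],
                    "layer": layer, "area_mm2": total,
                })
    return pd.DataFrame(rows)


def behavior_matched_wedges(grids: dict, ecc_band=(4.0, 5.0),
                            width: float = 15.0) -> dict:
    """The 24 wedge ROIs matched to behavioral mapping positions.

    15-degree-wide V1 wedges centered at 0, 15, ..., 345 around the whole
    visual field, restricted to one eccentricity band (default 4-5 deg).
    Field angles in (0, 180) live in the left-hemisphere (right hemifield)
    map; angles in (180, 360) mirror into the right hemisphere.  The wedges
    at 0 and 180 straddle both hemispheres.  Requires a fine grid generated
    with half-width-aligned edges (e.g. 7.5, 22.5, ...).

    Returns ``{center_deg: {hemisphere: VertexRegion}}``.
    """
    half = width / 2.0
    out = {}
    for center in np.arange(0.0, 360.0, width):
        parts = {}
        if np.isclose(center, 0.0) or np.isclose(center, 180.0):
            lo, hi = (0.0, half) if center == 0.0 else (180.0 - half, 180.0)
            for h, grid in grids.items():
                _require_edge(grid, half if center == 0.0 else 180.0 - half)
                parts[h] = VertexRegion(grid.select(("V1",), lo, hi, *ecc_band))
        else:
            hemi, ang = ("left", center) if center < 180 else ("right", 360.0 - center)
            grid = grids[hemi]
            _require_edge(grid, ang - half)
            _require_edge(grid, ang + half)
            parts[hemi] = VertexRegion(
                grid.select(("V1",), ang - half, ang + half, *ecc_band)
            )
        out[float(center)] = parts
    return out


def behavior_matched_areas(bundles: dict, grids: dict, ecc_band=(4.0, 5.0),
                           width: float = 15.0,
                           layer: str = DEFAULT_LAYER) -> pd.DataFrame:
    """Areas of the behavior-matched wedges, folded across mirror positions.

    Mirror wedges (e.g. 15 and 345) have their summed area divided by two;
    the self-mirrored VM wedges (0, 180) are single-hemifield sums, and the
    HM value is the full sum of the 90 and 270 wedges — so HM and VM are not
    halved.  Returns columns center_deg (0..180) and area_mm2.
    """
    va = {h: vertex_areas(b, layer) for h, b in bundles.items()}
    wedges = behavior_matched_wedges(grids, ecc_band, width)
    raw = {
        c: sum(float(va[h][r.vertex_ids].sum()) for h, r in parts.items())
        for c, parts in wedges.items()
    }
    rows = []
    for c in np.arange(0.0, 180.0 + width / 2, width):
        c = float(c)
        if np.isclose(c, 0.0) or np.isclose(c, 180.0):
            area = raw[c]
        elif np.isclose(c, 90.0):
            area = raw[90.0] + raw[270.0]
        else:
            area = (raw[c] + raw[360.0 - c]) / 2.0
        rows.append({"center_deg": c, "area_mm2": area})
    return pd.DataFrame(rows)


def eccentricity_band_areas(
    subject_id: str,
    bundles: dict,
    grids: dict,
    half_width: float = 10.0,
    bands=((1, 2), (2, 3), (3, 4), (4, 5), (5, 6)),
    areas: str = "V1+V2",
    layer: str = DEFAULT_LAYER,
) -> pd.DataFrame:
    """Bilateral wedge area per 1-degree eccentricity band and meridian.

    Used for the eccentricity-resolved comparison against retinal density
    asymmetries: HM, UVM and LVM wedges of one half-width, split into
    non-overlapping eccentricity bands.
    """
    va = {h: vertex_areas(b, layer) for h, b in bundles.items()}
    rows = []
    for meridian in ("HM", "UVM", "LVM", "VM"):
        areas_opt = "V1-only" if meridian == "VM" else areas
        for lo, hi in bands:
            spec = WedgeSpec(meridian, half_width, "cumulative",
                             (float(lo), float(hi)), areas_opt)
            total = sum(
                float(va[h][assemble_wedge(g, spec).vertex_ids].sum())
                for h, g in grids.items()
            )
            rows.append({"subject": subject_id, "meridian": meridian,
                         "half_width_deg": half_width, "ecc_lo": float(lo),
                         "ecc_hi": float(hi), "layer": layer,
                         "area_mm2": total})
    return pd.DataFrame(rows)
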