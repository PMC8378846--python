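"""Synthetic retinotopic data with analytically known ground truth.

Three generators feed the pipeline's test and validation paths:

``generate_cortex``
    A flat model cortex per hemisphere whose areal magnification is the
    Horton-Hoyt radial falloff times a smooth angular modulation

        g(theta) = 1 - h*cos(2*theta) - v*cos(theta),

    theta measured from the upper vertical meridian in radians.  ``h`` boosts
    the horizontal meridian relative to both verticals (a horizontal-vertical
    asymmetry knob) and ``v`` boosts the lower vertical relative to the upper
    (a vertical-meridian asymmetry knob); g stays positive while |h|+|v| < 1.
    The cortical sheet is the image of the visual-field polar grid under

        U(rho)        = scale * ln((rho+e0)/(rho_min+e0))
        V(rho, theta) = scale * rho/(rho+e0) * G(theta),   G = integral of g,

    whose Jacobian per unit visual-field area is exactly m_HH(rho)*g(theta),
    so every wedge has the closed-form area

        A = radial_integral(e1, e2) * (G(theta2) - G(theta1)).

    Measurement noise is added to the per-vertex angle/eccentricity maps,
    including ipsilateral spill near the vertical meridians (pRF centers
    pushed outside [0, 180] and clamped back, emulating the contaminated
    vertical-meridian measurements seen in real retinotopy).

``generate_twin_cohort``
    Shared-latent pair measurements x_ij = mu + b_j + e_ij with
    var(b)/(var(b)+var(e)) equal to the requested pair correlation, plus a
    subject-metadata table with family structure, gender and age group.

``generate_density_profiles``
    Cone-like meridional density profiles: one common radial falloff scaled
    per meridian, so the meridional asymmetries reduce to closed-form
    scale-factor expressions independent of eccentricity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hortonhoyt import HortonHoytModel
from .retina import DensityProfile, MeridianQuartet
from .sectors import CoarseSector
from .surface import CorticalSurfaceBundle, VertexRegion

DEFAULT_SEED = 20210803

#: coarse-band eccentricity knots (deg): bands 1-2, 2-4, 4-7
COARSE_ECC_KNOTS = (1.0, 2.0, 4.0, 7.0)


@dataclass
class CortexGenParams:
    """Knobs of the synthetic cortex.

    h, v : angular modulation amplitudes (|h| + |v| < 1).
    ecc_range : eccentricity span of the model maps, deg.
    mesh_step : target cortical edge length, mm (~0.3 gives ~30k
        vertices per hemisphere).
    angle_noise_sd : per-vertex polar-angle measurement noise, deg.
    ecc_noise_sd : eccentricity measurement noise, deg.
    ipsi_spill_prob : probability that a vertex within 10 deg of a vertical
        meridian reports an ipsilateral (out-of-range) polar angle.
    fold_amplitude : sinusoidal folding amplitude, mm (0 = flat sheet).
    thickness : cortical thickness, mm; white/pial sit half a thickness
        below/above the mid-gray sheet along the vertex normal.
    """

    h: float = 0.3
    v: float = 0.2
    ecc_range: tuple[float, float] = (1.0, 7.0)
    mesh_step: float = 0.3
    angle_noise_sd: float = 10.0
    ecc_noise_sd: float = 0.25
    ipsi_spill_prob: float = 0.1
    fold_amplitude: float = 0.0
    thickness: float = 2.0
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if abs(self.h) + abs(self.v) >= 1.0:
            raise ValueError("need |h| + |v| < 1 to keep magnification positive")
        if self.mesh_step <= 0:
            raise ValueError("mesh_step must be positive")
        lo, hi = self.ecc_range
        if not 0 <= lo < hi:
            raise ValueError("ecc_range must satisfy 0 <= lo < hi")
        if not 0 <= self.ipsi_spill_prob <= 1:
            raise ValueError("ipsi_spill_prob must be a probability")
        if self.angle_noise_sd < 0 or self.ecc_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass
class GroundTruth:
    """Closed-form areas and true maps of a generated cortex."""

    h: float
    v: float
    ecc_range: tuple[float, float]
    model: HortonHoytModel = field(default_factory=HortonHoytModel)
    true_angle: dict = field(default_factory=dict)  # hemi -> per-vertex deg
    true_ecc: dict = field(default_factory=dict)

    def g(self, theta_deg) -> np.ndarray:
        t = np.deg2rad(np.asarray(theta_deg, dtype=float))
        return 1.0 - self.h * np.cos(2 * t) - self.v * np.cos(t)

    def G(self, theta_deg) -> np.ndarray:
        """Integral of g from the UVM, in radians."""
        t = np.deg2rad(np.asarray(theta_deg, dtype=float))
        return t - 0.5 * self.h * np.sin(2 * t) - self.v * np.sin(t)

    def wedge_area(self, ang_lo: float, ang_hi: float,
                   ecc_lo: float, ecc_hi: float) -> float:
        """True cortical mm^2 of one wedge in one hemisphere's V1 (or one
        V2 quarterfield strip): additive in both the angular and the radial
        argument."""
        if ang_lo >= ang_hi:
            raise ValueError("need ang_lo < ang_hi")
        return float(
            self.model.radial_integral(ecc_lo, ecc_hi)
            * (self.G(ang_hi) - self.G(ang_lo))
        )

    def true_hva(self, half_width_deg: float,
                 ecc_lo: float = 1.0, ecc_hi: float = 6.0) -> float:
        """Closed-form HVA (percent) for +/-theta cumulative V1 wedges."""
        w = half_width_deg
        a_h = self.wedge_area(90 - w, 90 + w, ecc_lo, ecc_hi)
        a_v = self.wedge_area(0, w, ecc_lo, ecc_hi) + self.wedge_area(
            180 - w, 180, ecc_lo, ecc_hi
        )
        return 100.0 * (a_h - a_v) / ((a_h + a_v) / 2.0)

    def true_vma(self, half_width_deg: float,
                 ecc_lo: float = 1.0, ecc_hi: float = 6.0) -> float:
        """Closed-form VMA (percent): lower minus upper vertical wedge."""
        w = half_width_deg
        a_l = self.wedge_area(180 - w, 180, ecc_lo, ecc_hi)
        a_u = self.wedge_area(0, w, ecc_lo, ecc_hi)
        return 100.0 * (a_l - a_u) / ((a_l + a_u) / 2.0)


@dataclass
class SyntheticCortex:
    bundles: dict                 # hemisphere -> CorticalSurfaceBundle
    sectors: dict                 # hemisphere -> list[CoarseSector]
    ground_truth: GroundTruth
    params: CortexGenParams


def _patch_grid(params: CortexGenParams, truth: GroundTruth,
                theta_lo: float, theta_hi: float, orientation: float,
                y_origin_fn):
    """Vertex grid of one quarter/half-field patch in the flat (U, V) plane.

    ``orientation`` is +1 when cortical V grows with theta, -1 when it is
    mirrored (V2 ventral).  ``y_origin_fn(s)`` gives the patch's V offset as
    a function of the radial scale s(rho).  Returns (theta_deg, ecc, x, y)
    flattened row-major plus the grid shape.
    """
    model = truth.model
    e0 = model.e0
    ecc_lo, ecc_hi = params.ecc_range

    # radial rows: mandatory coarse-band knots, uniform in U between them
    knots = sorted({ecc_lo, ecc_hi} | {k for k in COARSE_ECC_KNOTS
                                       if ecc_lo < k < ecc_hi})
    def U(rho):
        return model.scale * np.log((rho + e0) / (ecc_lo + e0))
    rows = [np.array([knots[0]])]
    for a, b in zip(knots[:-1], knots[1:]):
        nseg = max(1, int(np.ceil((U(b) - U(a)) / params.mesh_step)))
        u = np.linspace(U(a), U(b), nseg + 1)[1:]
        rows.append((ecc_lo + e0) * np.exp(u / model.scale) - e0)
    ecc_rows = np.concatenate(rows)
    # snap the mandatory knots exactly (exp/log round trip drifts slightly)
    for k in knots:
        ecc_rows[np.argmin(np.abs(ecc_rows - k))] = k

    # angular columns: uniform in theta, spacing set by the outer-row arc
    s_max = model.scale * ecc_hi / (ecc_hi + e0)
    arc = s_max * abs(truth.G(theta_hi) - truth.G(theta_lo))
    ncol = max(2, int(np.ceil(arc / params.mesh_step)))
    # keep the horizontal meridian on the lattice for half-field patches
    if np.isclose(theta_lo, 0) and np.isclose(theta_hi, 180) and ncol % 2:
        ncol += 1
    theta_cols = np.linspace(theta_lo, theta_hi, ncol + 1)

    tt, ee = np.meshgrid(theta_cols, ecc_rows)            # (nr, nc)
    s = model.scale * ee / (ee + e0)
    x = U(ee)
    y = y_origin_fn(s) + orientation * s * (truth.G(tt) - truth.G(theta_lo))
    return tt.ravel(), ee.ravel(), x.ravel(), y.ravel(), tt.shape


def _grid_faces(shape, offset: int) -> np.ndarray:
    nr, nc = shape
    i, j = np.meshgrid(np.arange(nr - 1), np.arange(nc - 1), indexing="ij")
    v00 = offset + i * nc + j
    v01 = v00 + 1
    v10 = v00 + nc
    v11 = v10 + 1
    tri1 = np.stack([v00, v10, v01], axis=-1).reshape(-1, 3)
    tri2 = np.stack([v01, v10, v11], axis=-1).reshape(-1, 3)
    return np.vstack([tri1, tri2])


def _vertex_normals(coords: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a, b, c = coords[faces[:, 0]], coords[faces[:, 1]], coords[faces[:, 2]]
    fn = np.cross(b - a, c - a)
    vn = np.zeros_like(coords)
    for k in range(3):
        np.add.at(vn, faces[:, k], fn)
    norm = np.linalg.norm(vn, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return vn / norm


def _coarse_sectors(true_angle, true_ecc, ids, area, patch_band, params,
                    hemisphere) -> list:
    """Coarse sectors of one visual-area patch, bounded by iso-contours of
    the true (noise-free) maps, emulating hand-drawn annotations.

    ``ids`` are the global vertex ids of the patch; ``true_angle`` and
    ``true_ecc`` are the patch-local coordinate arrays in the same order.
    Sectors are closed bands, so abutting sectors share their boundary
    contour — downstream consumers union vertex sets rather than adding
    areas across sectors.
    """
    ecc_lo, ecc_hi = params.ecc_range
    knots = sorted({ecc_lo, ecc_hi} | {k for k in COARSE_ECC_KNOTS
                                       if ecc_lo < k < ecc_hi})
    if patch_band[1] - patch_band[0] > 90:
        ang_bands = [(0.0, 90.0), (90.0, 180.0)]
    else:
        ang_bands = [patch_band]
    sectors = []
    for a_lo, a_hi in ang_bands:
        in_ang = (true_angle >= a_lo - 1e-9) & (true_angle <= a_hi + 1e-9)
        for e_lo, e_hi in zip(knots[:-1], knots[1:]):
            in_ecc = (true_ecc >= e_lo - 1e-9) & (true_ecc <= e_hi + 1e-9)
            sel = in_ang & in_ecc
            sub_ids = ids[sel]
            sel_a = true_angle[sel]
            sel_e = true_ecc[sel]
            name = f"{hemisphere}-{area}-ang{a_lo:g}-{a_hi:g}-ecc{e_lo:g}-{e_hi:g}"
            sectors.append(CoarseSector(
                vertices=VertexRegion(sub_ids, provenance=name),
                visual_area=area,
                angular_band=(a_lo, a_hi),
                ecc_band=(e_lo, e_hi),
                boundary_a=VertexRegion(sub_ids[np.isclose(sel_a, a_lo)]),
                boundary_b=VertexRegion(sub_ids[np.isclose(sel_a, a_hi)]),
                boundary_e1=VertexRegion(sub_ids[np.isclose(sel_e, e_lo)]),
                boundary_e2=VertexRegion(sub_ids[np.isclose(sel_e, e_hi)]),
                name=name,
            ))
    return sectors


def _measured_maps(true_angle, true_ecc, params, rng):
    """True maps plus Gaussian measurement noise and ipsilateral spill."""
    angle = true_angle + (
        rng.normal(0.0, params.angle_noise_sd, true_angle.shape)
        if params.angle_noise_sd > 0 else 0.0
    )
    if params.ipsi_spill_prob > 0:
        near_uvm = true_angle <= 10.0
        near_lvm = true_angle >= 170.0
        spill = rng.random(true_angle.shape) < params.ipsi_spill_prob
        mag = np.abs(rng.normal(0.0, 10.0, true_angle.shape))
        angle = np.where(near_uvm & spill, -mag, angle)
        angle = np.where(near_lvm & spill, 180.0 + mag, angle)
    angle = np.clip(angle, 0.0, 180.0)
    ecc = true_ecc + (
        rng.normal(0.0, params.ecc_noise_sd, true_ecc.shape)
        if params.ecc_noise_sd > 0 else 0.0
    )
    return angle, np.maximum(ecc, 0.0)


def generate_cortex(params: CortexGenParams | None = None) -> SyntheticCortex:
    """Build a two-hemisphere synthetic retinotopic cortex.

    Each hemisphere is one flat sheet holding three patches: V1 covering the
    full contralateral hemifield (polar angle 0-180 from the UVM) flanked by
    a ventral V2 strip mirrored across the UVM border and a dorsal V2 strip
    mirrored across the LVM border, each covering its quarterfield.  Coarse
    sectors (six per visual area per hemisphere) are labeled from the true
    coordinates; the measured per-vertex maps carry Gaussian noise and
    ipsilateral spill.
    """
    params = params or CortexGenParams()
    params.validate()
    truth = GroundTruth(h=params.h, v=params.v, ecc_range=params.ecc_range)
    rng = np.random.default_rng(params.seed)
    G90 = float(truth.G(90.0))
    G180 = float(truth.G(180.0))

    # (angular band, area, orientation, V offset as a function of s(rho))
    patches = (
        ((0.0, 180.0), "V1", +1.0, lambda s: -s * G90),
        ((0.0, 90.0), "V2", -1.0, lambda s: -s * G90),
        ((90.0, 180.0), "V2", -1.0, lambda s: 2.0 * s * (G180 - G90)),
    )

    bundles, sectors = {}, {}
    for hemisphere in ("left", "right"):
        tru_angle, tru_ecc, xs, ys, labels, faces = [], [], [], [], [], []
        sector_list = []
        offset = 0
        for band, area, orient, yfn in patches:
            t, e, x, y, shape = _patch_grid(params, truth, band[0], band[1],
                                            orient, yfn)
            faces.append(_grid_faces(shape, offset))
            ids = np.arange(offset, offset + t.size, dtype=np.intp)
            sector_list.extend(
                _coarse_sectors(t, e, ids, area, band, params, hemisphere)
            )
            tru_angle.append(t)
            tru_ecc.append(e)
            xs.append(x)
            ys.append(y)
            labels.append(np.full(t.size, area, dtype=object))
            offset += t.size

        tru_angle = np.concatenate(tru_angle)
        tru_ecc = np.concatenate(tru_ecc)
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        faces = np.vstack(faces)
        sign = 1.0 if hemisphere == "left" else -1.0
        z = params.fold_amplitude * np.sin(2 * np.pi * x / 25.0) \
            if params.fold_amplitude else np.zeros_like(x)
        mid = np.column_stack([sign * x, y, z])
        normals = _vertex_normals(mid, faces)
        half = params.thickness / 2.0
        coords = {
            "midgray": mid,
            "white": mid - half * normals,
            "pial": mid + half * normals,
        }
        angle, ecc = _measured_maps(tru_angle, tru_ecc, params, rng)
        bundle = CorticalSurfaceBundle(
            faces=faces,
            coords=coords,
            polar_angle=angle,
            eccentricity=ecc,
            area_label=np.concatenate(labels),
            hemisphere=hemisphere,
            meta={"generator": "polarfields.synth", "seed": params.seed,
                  "h": params.h, "v": params.v},
        )
        bundle.validate()
        bundles[hemisphere] = bundle
        sectors[hemisphere] = sector_list
        truth.true_angle[hemisphere] = tru_angle
        truth.true_ecc[hemisphere] = tru_ecc
    return SyntheticCortex(bundles, sectors, truth, params)


def generate_twin_cohort(
    n_mz: int = 38,
    n_dz: int = 33,
    n_singletons: int = 20,
    rho_mz: float = 0.6,
    rho_dz: float = 0.2,
    mu: float = 0.0,
    sigma: float = 1.0,
    seed: int = DEFAULT_SEED,
):
    """Shared-latent twin cohort: pair matrices plus a metadata table.

    Measurements follow x_ij = mu + b_j + e_ij with var(b) = rho*sigma^2 and
    var(e) = (1-rho)*sigma^2, so the population intraclass correlation of a
    pair class equals its rho.  Singleton subjects (no co-twin) are added so
    unrelated-pair matching has material to work with.  Genders and age
    groups are assigned per family (twins always match).

    Returns ``(matrices, meta)`` where matrices maps 'MZ'/'DZ' to a 2 x n
    array and meta is a DataFrame with columns subject_id, gender, age_group,
    family_id, zygosity, measurement.
    """
    for name, rho in (("rho_mz", rho_mz), ("rho_dz", rho_dz)):
        if not 0 <= rho < 1:
            raise ValueError(f"{name} must be in [0, 1)")
    if min(n_mz, n_dz) < 2:
        raise ValueError("need at least 2 pairs per twin class")
    rng = np.random.default_rng(seed)
    age_groups = ("22-25", "26-30", "31-35", "36+")
    genders = ("M", "F")

    matrices = {}
    rows = []
    fam = 0
    for cls, n_pairs, rho in (("MZ", n_mz, rho_mz), ("DZ", n_dz, rho_dz)):
        b = rng.normal(0.0, np.sqrt(rho) * sigma, n_pairs)
        e = rng.normal(0.0, np.sqrt(1.0 - rho) * sigma, (2, n_pairs))
        x = mu + b[None, :] + e
        matrices[cls] = x
        for j in range(n_pairs):
            fam += 1
            g = genders[rng.integers(2)]
            a = age_groups[rng.integers(len(age_groups))]
            for i in range(2):
                rows.append({
                    "subject_id": f"{cls}{j:04d}{'ab'[i]}",
                    "gender": g, "age_group": a,
                    "family_id": f"fam{fam:04d}", "zygosity": cls,
                    "measurement": x[i, j],
                })
    for k in range(n_singletons):
        fam += 1
        rows.append({
            "subject_id": f"S{k:04d}",
            "gender": genders[rng.integers(2)],
            "age_group": age_groups[rng.integers(len(age_groups))],
            "family_id": f"fam{fam:04d}", "zygosity": "none",
            "measurement": mu + rng.normal(0.0, sigma),
        })
    return matrices, pd.DataFrame(rows)


def default_radial_falloff(ecc):
    """Cone-like density falloff in counts/deg^2: steep foveal peak with an
    inverse-square shoulder."""
    ecc = np.asarray(ecc, dtype=float)
    return 14000.0 / (1.0 + ecc / 0.65) ** 2 + 1000.0 / (1.0 + ecc / 8.0)


def generate_density_profiles(
    meridian_scales: dict | None = None,
    radial_falloff=default_radial_falloff,
    noise_sd: float = 0.0,
    ecc_max: float = 8.0,
    step: float = 0.1,
    seed: int = DEFAULT_SEED,
) -> MeridianQuartet:
    """Meridional density profiles sharing one radial falloff.

    density(rho, m) = scale_m * f(rho) * (1 + noise); with zero noise every
    meridional asymmetry reduces to a scale-factor expression independent of
    eccentricity.  Profiles are sampled on 0..ecc_max at ``step`` deg in the
    retinal frame.  Negative noisy densities are truncated at zero.
    """
    scales = dict(nasal=1.2, temporal=1.2, superior=1.0, inferior=1.0)
    if meridian_scales:
        scales.update(meridian_scales)
    if any(s <= 0 for s in scales.values()):
        raise ValueError("meridian scales must be positive")
    rng = np.random.default_rng(seed)
    ecc = np.round(np.arange(0.0, ecc_max + step / 2, step), 10)
    f = radial_falloff(ecc)
    profiles = {}
    for m in ("nasal", "temporal", "superior", "inferior"):
        d = scales[m] * f
        if noise_sd > 0:
            d = d * (1.0 + rng.normal(0.0, noise_sd, d.shape))
            if (d < 0).any():
                import warnings

                warnings.warn("negative densities truncated at zero")
                d = np.maximum(d, 0.0)
        profiles[m] = DensityProfile(meridian=m, frame="retinal",
                                     eccentricity=ecc, density=d)
    return MeridianQuartet(**profiles)
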