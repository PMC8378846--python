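"""Meridional asymmetries of retinal density profiles.

Cone and midget-RGC densities are sampled along the four cardinal meridians
as density-vs-eccentricity profiles.  The meridional asymmetries are

    HVA = 100 * (mean(nasal, temporal) - mean(superior, inferior))
              / mean(nasal, temporal, superior, inferior)
    VMA = 100 * (superior - inferior) / mean(superior, inferior)

evaluated at matched eccentricities.  The ``frame`` field distinguishes
retinal coordinates (superior = superior retina) from visual-field
coordinates: the vertical flip of the eye's optics means superior retina
sees the *lower* visual field, so converting frames swaps superior and
inferior (and maps nasal/temporal onto the left/right hemifield).  Keeping
the frame explicit prevents silently mixing retinal profiles with cortical
(visual-field) wedge measures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

MERIDIANS = ("nasal", "temporal", "superior", "inferior")
FRAMES = ("retinal", "visual-field")


@dataclass
class DensityProfile:
    """Density (counts/deg^2) versus eccentricity (deg) along one meridian."""

    meridian: str
    frame: str
    eccentricity: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.eccentricity = np.asarray(self.eccentricity, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.meridian not in MERIDIANS:
            raise ValueError(f"unknown meridian {self.meridian!r}")
        if self.frame not in FRAMES:
            raise ValueError(f"unknown frame {self.frame!r}")
        if self.eccentricity.shape != self.density.shape:
            raise ValueError("eccentricity and density must align")
        if (self.eccentricity < 0).any():
            raise ValueError("negative eccentricity")
        if (np.diff(self.eccentricity) <= 0).any():
            raise ValueError("eccentricities must be strictly increasing")
        if (self.density < 0).any():
            raise ValueError("negative density")


def regrid_profile(p: DensityProfile, grid) -> DensityProfile:
    """Piecewise-linear resampling onto a new eccentricity grid.

    Exact at the original knots; extrapolation beyond the sampled support is
    refused rather than guessed.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.min() < p.eccentricity[0] - 1e-12 or grid.max() > p.eccentricity[-1] + 1e-12:
        raise ValueError(
            f"regrid outside sampled support [{p.eccentricity[0]}, "
            f"{p.eccentricity[-1]}] requested"
        )
    return replace(p, eccentricity=grid,
                   density=np.interp(grid, p.eccentricity, p.density))


@dataclass
class MeridianQuartet:
    """One profile per cardinal meridian, on a common grid and frame."""

    nasal: DensityProfile
    temporal: DensityProfile
    superior: DensityProfile
    inferior: DensityProfile

    def __post_init__(self) -> None:
        frames = {p.frame for p in self.profiles()}
        if len(frames) != 1:
            raise ValueError(f"profiles mix frames {sorted(frames)}")
        e0 = self.nasal.eccentricity
        for p in self.profiles():
            if p.eccentricity.shape != e0.shape or not np.allclose(p.eccentricity, e0):
                raise ValueError("profiles must share one eccentricity grid; regrid first")

    def profiles(self):
        return (self.nasal, self.temporal, self.superior, self.inferior)

    @property
    def frame(self) -> str:
        return self.nasal.frame

    @property
    def eccentricity(self) -> np.ndarray:
        return self.nasal.eccentricity

    def to_frame(self, frame: str) -> "MeridianQuartet":
        """Convert retinal <-> visual-field: swap superior and inferior.

        Applying the conversion twice is the identity.  Nasal/temporal keep
        their labels (their hemifield identity additionally depends on the
        eye, which a density quartet does not carry).
        """
        if frame not in FRAMES:
            raise ValueError(f"unknown frame {frame!r}")
        if frame == self.frame:
            return self
        def flip(p, new_meridian):
            return replace(p, frame=frame, meridian=new_meridian)
        return MeridianQuartet(
            nasal=replace(self.nasal, frame=frame),
            temporal=replace(self.temporal, frame=frame),
            superior=flip(self.inferior, "superior"),
            inferior=flip(self.superior, "inferior"),
        )


def _asym(n, t, s, i):
    n, t, s, i = (np.asarray(x, dtype=float) for x in (n, t, s, i))
    denom_h = (n + t + s + i) / 4.0
    denom_v = (s + i) / 2.0
    if np.any(denom_h == 0) or np.any(denom_v == 0):
        raise ZeroDivisionError("asymmetry undefined: zero mean density")
    hva = 100.0 * ((n + t) / 2.0 - (s + i) / 2.0) / denom_h
    vma = 100.0 * (s - i) / denom_v
    return hva, vma


def asymmetry_at_eccentricity(q: MeridianQuartet, ecc: float):
    """(HVA, VMA) in percent at one eccentricity (linear interpolation)."""
    vals = [regrid_profile(p, [ecc]).density[0] for p in q.profiles()]
    hva, vma = _asym(*vals)
    return float(hva), float(vma)


def asymmetry_curve(q: MeridianQuartet, bin_edges=(1, 2, 3, 4, 5, 6)):
    """Band-wise HVA/VMA plus second-degree polynomial trend fits.

    Each band's value is the asymmetry of the band-mean densities (matching
    how cortical band areas enter the same comparison).  Returns a DataFrame
    with columns ecc_center, hva_pct, vma_pct, plus a dict of quadratic
    coefficients (ascending order) for each curve.
    """
    import pandas as pd

    from .stats import fit_quadratic_trend

    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (q.eccentricity >= lo) & (q.eccentricity <= hi)
        if not sel.any():
            raise ValueError(f"no density samples in band [{lo}, {hi}]")
        means = [p.density[sel].mean() for p in q.profiles()]
        hva, vma = _asym(*means)
        rows.append({"ecc_center": (lo + hi) / 2.0,
                     "hva_pct": float(hva), "vma_pct": float(vma)})
    table = pd.DataFrame(rows)
    fits = {}
    if len(table) >= 3:
        fits["hva"] = fit_quadratic_trend(table["ecc_center"], table["hva_pct"])
        fits["vma"] = fit_quadratic_trend(table["ecc_center"], table["vma_pct"])
    return table, fits
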