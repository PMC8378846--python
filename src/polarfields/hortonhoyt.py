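"""Areal cortical magnification model of Horton & Hoyt and its wedge areas.

The model gives the V1 surface area devoted to a unit area of visual field as

    m(rho) = (scale / (rho + e0))^2   [mm^2 / deg^2],

with scale = 17.3 mm and e0 = 0.75 deg.  It depends only on eccentricity rho,
so its predicted wedge areas are independent of meridian and serve both as
the reference curve for measured asymmetries and as the radial backbone of
the synthetic cortex generator.

Predicted wedge areas integrate m over a visual-field wedge using the polar
area element rho drho dtheta (theta in radians):

    A = W_rad * scale^2 * [ln((e2+e0)/(e1+e0)) + e0*(1/(e2+e0) - 1/(e1+e0))]

where W_rad is the total angular width of the wedge in radians (summed over
all constituent visual-field wedges, e.g. 4*theta for a pair of +/-theta
wedges represented in both hemispheres).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class HortonHoytModel:
    scale: float = 17.3  # mm
    e0: float = 0.75     # deg

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.e0 <= 0:
            raise ValueError("scale and e0 must be positive")

    def magnification(self, ecc) -> np.ndarray:
        """Areal magnification in mm^2/deg^2 at eccentricity ``ecc`` (deg)."""
        ecc = np.asarray(ecc, dtype=float)
        if (ecc < 0).any():
            raise ValueError("eccentricity must be non-negative")
        return (self.scale / (ecc + self.e0)) ** 2

    def radial_integral(self, ecc_lo: float, ecc_hi: float) -> float:
        """Integral of m(rho) * rho drho over [ecc_lo, ecc_hi], in mm^2/rad.

        This is the predicted area per radian of visual-field angle.
        """
        if ecc_lo < 0 or ecc_lo >= ecc_hi:
            raise ValueError("need 0 <= ecc_lo < ecc_hi")
        e0 = self.e0
        term = np.log((ecc_hi + e0) / (ecc_lo + e0)) + e0 * (
            1.0 / (ecc_hi + e0) - 1.0 / (ecc_lo + e0)
        )
        return self.scale**2 * term

    def predicted_area(
        self, ecc_lo: float, ecc_hi: float, total_angular_width_deg: float
    ) -> float:
        """Predicted cortical area in mm^2 of a visual-field wedge.

        ``total_angular_width_deg`` is the summed angular extent of all
        constituent wedges (0 < width <= 360).
        """
        if not 0 <= total_angular_width_deg <= 360:
            raise ValueError("total angular width must be in [0, 360] degrees")
        return np.deg2rad(total_angular_width_deg) * self.radial_integral(ecc_lo, ecc_hi)


def predicted_area_table(
    half_widths_deg,
    ecc_lo: float = 1.0,
    ecc_hi: float = 6.0,
    model: HortonHoytModel | None = None,
):
    """Predicted areas for dual +/-theta cumulative wedges, both hemifields.

    A cumulative wedge of half-width theta around a meridian spans 2*theta of
    angle in each hemifield, hence 4*theta in total for a bilateral ROI.
    Returns a pandas DataFrame with columns half_width_deg, area_mm2,
    area_cm2.
    """
    import pandas as pd

    model = model or HortonHoytModel()
    rows = []
    for hw in half_widths_deg:
        a = model.predicted_area(ecc_lo, ecc_hi, 4.0 * hw)
        rows.append({"half_width_deg": hw, "area_mm2": a, "area_cm2": a / 100.0})
    return pd.DataFrame(rows)
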