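"""Asymmetry statistics: the percent-difference index, group profiles with
subject-level bootstrap CIs, polynomial trends, and correlations.

The asymmetry between two matched measures a1, a2 (areas or densities) is

    Delta(a1, a2) = 100 * (a1 - a2) / mean(a1, a2),

a signed percent difference that is antisymmetric under swapping and
invariant to a common positive rescaling; it is bounded by +/-200.  Group
profiles aggregate per-subject asymmetries (never asymmetries of group-mean
areas) with a percentile bootstrap over subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class BootstrapConfig:
    """Subject-level percentile bootstrap settings.

    Defaults give the 68% CI (16th/84th percentiles) of the median across
    subjects.
    """

    n_boot: int = 1000
    seed: int = 0
    statistic: str = "median"
    ci_percentiles: tuple[float, float] = (16.0, 84.0)

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        lo, hi = self.ci_percentiles
        if not (0 < lo < hi < 100):
            raise ValueError("ci_percentiles must be ordered within (0, 100)")
        if self.statistic not in ("median", "mean"):
            raise ValueError("statistic must be 'median' or 'mean'")

    @property
    def stat_fn(self):
        return np.median if self.statistic == "median" else np.mean


def percent_asymmetry(a1, a2):
    """Delta(a1, a2) = 100 * (a1 - a2) / mean(a1, a2), elementwise."""
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    if (a1 < 0).any() or (a2 < 0).any():
        raise ValueError("asymmetry inputs must be non-negative")
    total = a1 + a2
    if (total == 0).any():
        raise ZeroDivisionError("asymmetry undefined when both inputs are zero")
    out = 100.0 * (a1 - a2) / (total / 2.0)
    return float(out) if out.ndim == 0 else out


def bootstrap_statistic(values, cfg: BootstrapConfig = BootstrapConfig()):
    """Statistic of ``values`` with a percentile bootstrap CI over subjects.

    Resamples the subjects with replacement (same n) ``cfg.n_boot`` times;
    reproducible for a fixed ``cfg.seed``.  Returns (estimate, ci_lo, ci_hi).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 subjects to bootstrap")
    rng = np.random.default_rng(cfg.seed)
    stat = cfg.stat_fn
    idx = rng.integers(0, values.size, size=(cfg.n_boot, values.size))
    boots = stat(values[idx], axis=1)
    lo, hi = np.percentile(boots, cfg.ci_percentiles)
    return float(stat(values)), float(lo), float(hi)


def hva_vma_profiles(area_table: pd.DataFrame,
                     cfg: BootstrapConfig = BootstrapConfig()) -> pd.DataFrame:
    """HVA and VMA versus wedge width from a long-format area table.

    ``area_table`` needs columns subject, meridian (HM/UVM/LVM/VM),
    half_width_deg, mode (cumulative/incremental), area_mm2; areas are
    already summed over hemispheres.  Per subject and width,
    HVA = Delta(HM, VM) and VMA = Delta(LVM, UVM); the group profile is the
    configured statistic with its percentile-bootstrap CI and the fraction of
    subjects with positive asymmetry.  Subjects missing a required meridian
    at some width are dropped from that point with a warning.
    """
    import warnings

    required = {"subject", "meridian", "half_width_deg", "mode", "area_mm2"}
    missing = required - set(area_table.columns)
    if missing:
        raise ValueError(f"area table missing columns {sorted(missing)}")

    wide = area_table.pivot_table(
        index=["subject", "half_width_deg", "mode"],
        columns="meridian", values="area_mm2", aggfunc="sum",
    )
    rows = []
    for (width, mode), grp in wide.groupby(level=["half_width_deg", "mode"]):
        for kind, top, bottom in (("HVA", "HM", "VM"), ("VMA", "LVM", "UVM")):
            if top not in grp.columns or bottom not in grp.columns:
                continue
            pair = grp[[top, bottom]].dropna()
            n_dropped = len(grp) - len(pair)
            if n_dropped:
                warnings.warn(
                    f"{kind} at width {width} ({mode}): dropped {n_dropped} "
                    "subjects missing a meridian ROI"
                )
            if len(pair) == 0:
                continue
            deltas = percent_asymmetry(pair[top].to_numpy(),
                                       pair[bottom].to_numpy())
            deltas = np.atleast_1d(deltas)
            if deltas.size >= 2:
                est, lo, hi = bootstrap_statistic(deltas, cfg)
            else:
                est = float(deltas[0])
                lo = hi = est
            rows.append({
                "kind": kind, "mode": mode, "half_width_deg": width,
                "estimate_pct": est, "ci_lo": lo, "ci_hi": hi,
                "n_subjects": int(deltas.size),
                "frac_positive": float((deltas > 0).mean()),
            })
    return pd.DataFrame(rows)


def fit_quadratic_trend(x, y) -> np.ndarray:
    """Least-squares second-degree polynomial fit; coefficients ascending.

    Requires at least 3 distinct x values; a rank-deficient design is an
    error rather than a silently truncated fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("quadratic fit needs >= 3 distinct x values")
    design = np.vander(x, 3, increasing=True)
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient design for quadratic fit")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def pearson_correlation(v1, v2) -> float:
    """Pearson r of two matched vectors (length >= 3, nonzero variance)."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(sps.pearsonr(v1, v2).statistic)
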