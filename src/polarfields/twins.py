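"""Intraclass correlation for pair-structured measurements.

For a 2 x n matrix X of pair measurements (x_ij = member i of pair j) the
one-way ANOVA mean squares are

    MSr = 2/(n-1) * sum_j (pairmean_j - grandmean)^2     (between pairs)
    MSw = 1/n * sum_i sum_j (x_ij - pairmean_j)^2        (within pairs)

and the intraclass correlation estimate is

    r_ICC = (MSr - MSw) / (MSr + MSw),

which is 1 exactly for concordant pairs (MSw = 0, MSr > 0), always lies in
[-1, 1], is invariant to relabeling pair members and to affine rescaling of
the measurements, and converges to the population pair correlation for
bivariate-normal pairs.  Bootstrap CIs resample pairs (never individual
subjects), preserving the within-pair dependence under study.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats import BootstrapConfig


def icc(x) -> float:
    """One-way ANOVA intraclass correlation of a 2 x n pair matrix."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] != 2:
        raise ValueError("pair matrix must be 2 x n")
    n = x.shape[1]
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if not np.isfinite(x).all():
        raise ValueError("pair matrix contains non-finite values")
    pair_means = x.mean(axis=0)
    grand = x.mean()
    ms_r = 2.0 / (n - 1) * ((pair_means - grand) ** 2).sum()
    ms_w = ((x - pair_means) ** 2).sum() / n
    if ms_r + ms_w == 0:
        raise ValueError("ICC undefined: zero total variance")
    return float((ms_r - ms_w) / (ms_r + ms_w))


def icc_with_ci(x, cfg: BootstrapConfig = BootstrapConfig(n_boot=10_000)):
    """ICC estimate with a percentile bootstrap CI over pairs.

    Returns a dict with estimate, ci_lo, ci_hi, n_pairs, n_boot and a
    ``ci_stable`` flag (False when fewer than 3 pairs support the CI).
    """
    x = np.asarray(x, dtype=float)
    est = icc(x)
    n = x.shape[1]
    rng = np.random.default_rng(cfg.seed)
    boots = np.empty(cfg.n_boot)
    for b in range(cfg.n_boot):
        cols = rng.integers(0, n, n)
        xb = x[:, cols]
        pm = xb.mean(axis=0)
        g = xb.mean()
        ms_r = 2.0 / (n - 1) * ((pm - g) ** 2).sum()
        ms_w = ((xb - pm) ** 2).sum() / n
        boots[b] = (ms_r - ms_w) / (ms_r + ms_w) if ms_r + ms_w > 0 else 0.0
    lo, hi = np.percentile(boots, cfg.ci_percentiles)
    stable = n >= 3
    if not stable:
        warnings.warn("bootstrap CI unstable with fewer than 3 pairs")
    return {"estimate": est, "ci_lo": float(lo), "ci_hi": float(hi),
            "n_pairs": int(n), "n_boot": cfg.n_boot, "ci_stable": stable}


def match_unrelated_pairs(meta: pd.DataFrame) -> pd.DataFrame:
    """All unordered subject pairs that are unrelated and demographically matched.

    ``meta`` needs columns subject_id, gender, age_group, family_id (twins
    and other relatives share a family_id).  A pair qualifies when the two
    subjects come from different families, share a gender and share an age
    group.  Subjects missing gender or age group are excluded with a warning.
    Returns a DataFrame with columns subject_a, subject_b.
    """
    required = {"subject_id", "gender", "age_group", "family_id"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns {sorted(missing)}")
    usable = meta.dropna(subset=["gender", "age_group"])
    if len(usable) < len(meta):
        warnings.warn(
            f"excluded {len(meta) - len(usable)} subjects with missing "
            "gender or age group"
        )
    usable = usable.reset_index(drop=True)
    sid = usable["subject_id"].to_numpy()
    gender = usable["gender"].to_numpy()
    age = usable["age_group"].to_numpy()
    fam = usable["family_id"].to_numpy()
    ii, jj = np.triu_indices(len(usable), k=1)
    ok = (gender[ii] == gender[jj]) & (age[ii] == age[jj]) & (fam[ii] != fam[jj])
    return pd.DataFrame({"subject_a": sid[ii[ok]], "subject_b": sid[jj[ok]]})


def pairs_to_matrix(pairs: pd.DataFrame, measurements: pd.Series) -> np.ndarray:
    """2 x n matrix of a per-subject measurement over a pair list."""
    a = measurements.loc[pairs["subject_a"]].to_numpy(dtype=float)
    b = measurements.loc[pairs["subject_b"]].to_numpy(dtype=float)
    return np.vstack([a, b])


def icc_by_width(pair_tables: dict,
                 cfg: BootstrapConfig = BootstrapConfig(n_boot=10_000)) -> pd.DataFrame:
    """ICC profile across wedge widths (or any keyed family of pair matrices).

    ``pair_tables`` maps (kind, half_width_deg, pair_class) -> 2 x n matrix.
    Returns one row per key with the estimate and its percentile-bootstrap CI
    (same seed -> identical endpoints).
    """
    rows = []
    for (kind, width, cls), x in sorted(pair_tables.items()):
        res = icc_with_ci(x, cfg)
        rows.append({"kind": kind, "half_width_deg": width, "class": cls,
                     **res})
    return pd.DataFrame(rows)
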