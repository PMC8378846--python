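"""End-to-end orchestration: config, staged computation, output tables and a
run manifest.

A run either reads cortical inputs from disk (bundle directory per subject)
or simulates a cohort with the synthetic generator, then resamples sectors,
assembles wedge ROIs, computes asymmetry profiles, magnification predictions
and — when pair/density data are present — twin ICC profiles and retinal
asymmetries.  Outputs are deterministic functions of the config plus seed;
every table is TSV with a '#' metadata preamble, and a JSON manifest
(config snapshot, seeds, row counts, warnings) is written atomically at the
end of the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .hortonhoyt import HortonHoytModel, predicted_area_table
from .io import write_table
from .retina import asymmetry_curve
from .rois import eccentricity_band_areas, subject_area_table
from .sectors import angular_edges_for_width, build_fine_grid
from .stats import BootstrapConfig, hva_vma_profiles, percent_asymmetry
from .synth import (
    CortexGenParams,
    generate_cortex,
    generate_density_profiles,
    generate_twin_cohort,
)
from .twins import icc_with_ci, match_unrelated_pairs, pairs_to_matrix

log = logging.getLogger(__name__)


@dataclass
class SimulateBlock:
    """Synthetic-cohort settings for a simulation-driven run."""

    n_subjects: int = 5
    h: float = 0.3
    v: float = 0.2
    subject_h_sd: float = 0.05
    subject_v_sd: float = 0.05
    mesh_step: float = 1.0
    angle_noise_sd: float = 10.0
    ecc_noise_sd: float = 0.25
    ipsi_spill_prob: float = 0.1
    twins: dict = field(default_factory=lambda: dict(
        n_mz=38, n_dz=33, n_singletons=20, rho_mz=0.6, rho_dz=0.2))
    density_scales: dict = field(default_factory=lambda: dict(
        nasal=1.2, temporal=1.2, superior=1.0, inferior=0.9))
    density_noise_sd: float = 0.02


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    out_dir: str = "polarfields_out"
    seed: int = 20210803
    widths: tuple = (10, 20, 30, 40, 50)
    fine_bin_width: float = 10.0
    ecc_range: tuple = (1.0, 6.0)
    layer: str = "midgray"
    n_boot: int = 1000
    statistic: str = "median"
    simulate: SimulateBlock | None = field(default_factory=SimulateBlock)
    input_dirs: tuple = ()  # per-subject bundle directories (with sectors JSON)

    def validate(self) -> None:
        for w in self.widths:
            if abs(w / self.fine_bin_width - round(w / self.fine_bin_width)) > 1e-9:
                raise ValueError(
                    f"wedge width {w} is not a multiple of the fine-bin width "
                    f"{self.fine_bin_width}"
                )
        lo, hi = self.ecc_range
        if not 0 <= lo < hi:
            raise ValueError("ecc_range must satisfy 0 <= lo < hi")
        if self.simulate is None and not self.input_dirs:
            raise ValueError("config needs either a simulate block or input_dirs")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        cfg = cls(**{k: v for k, v in d.items() if k in
                     {f.name for f in dataclasses.fields(cls)} - {"simulate"}})
        if sim is not None:
            known = {f.name for f in dataclasses.fields(SimulateBlock)}
            cfg.simulate = SimulateBlock(**{k: v for k, v in sim.items() if k in known})
        elif d.get("input_dirs"):
            cfg.simulate = None
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _simulated_subjects(cfg: PipelineConfig):
    """Yield (subject_id, bundles, sectors, truth) for the simulated cohort."""
    sim = cfg.simulate
    rng = np.random.default_rng(cfg.seed)
    for i in range(sim.n_subjects):
        h = float(np.clip(rng.normal(sim.h, sim.subject_h_sd), -0.9, 0.9))
        v = float(np.clip(rng.normal(sim.v, sim.subject_v_sd), -0.9, 0.9))
        if abs(h) + abs(v) >= 1.0:
            v = np.sign(v) * (0.99 - abs(h))
        params = CortexGenParams(
            h=h, v=v, mesh_step=sim.mesh_step,
            angle_noise_sd=sim.angle_noise_sd, ecc_noise_sd=sim.ecc_noise_sd,
            ipsi_spill_prob=sim.ipsi_spill_prob,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cortex = generate_cortex(params)
        yield f"sim{i:03d}", cortex.bundles, cortex.sectors, cortex.ground_truth


def _loaded_subjects(cfg: PipelineConfig):
    from .io import read_bundle, read_sectors_json

    for d in cfg.input_dirs:
        d = Path(d)
        bundles, sectors = {}, {}
        for hemi in ("left", "right"):
            bundles[hemi] = read_bundle(d, hemi)
            sectors[hemi] = read_sectors_json(d / f"{hemi}.sectors.json")
        yield d.name, bundles, sectors, None


def run(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns {table name: DataFrame} and writes TSVs.

    Stages: cortex (simulate or load) -> fine-grid resampling -> wedge areas
    -> asymmetry profiles; plus magnification predictions, twin ICC and
    retinal asymmetries.  Any stage error aborts with the stage and offending
    entity in the message; the partial manifest is still written.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    caught: list[str] = []
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "tables": {},
        "warnings": caught,
    }
    tables: dict[str, pd.DataFrame] = {}
    meta = {"seed": config.seed, "version": __version__}
    stage = "setup"
    try:
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")

            stage = "cortex"
            subjects = (_simulated_subjects(config) if config.simulate
                        else _loaded_subjects(config))
            edges = angular_edges_for_width(config.fine_bin_width)

            stage = "areas"
            area_rows, band_rows = [], []
            for sid, bundles, sectors, _truth in subjects:
                grids = {
                    h: build_fine_grid(bundles[h], sectors[h], edges,
                                       layer=config.layer)
                    for h in bundles
                }
                area_rows.append(subject_area_table(
                    sid, bundles, grids, half_widths=config.widths,
                    ecc_range=config.ecc_range, layer=config.layer,
                ))
                band_rows.append(eccentricity_band_areas(
                    sid, bundles, grids, half_width=config.fine_bin_width,
                    layer=config.layer,
                ))
            tables["areas"] = pd.concat(area_rows, ignore_index=True)
            tables["ecc_band_areas"] = pd.concat(band_rows, ignore_index=True)

            stage = "asymmetry"
            boot = BootstrapConfig(n_boot=config.n_boot, seed=config.seed,
                                   statistic=config.statistic)
            tables["asymmetry"] = hva_vma_profiles(tables["areas"], boot)

            stage = "hh_predictions"
            tables["hh_predictions"] = predicted_area_table(
                config.widths, *config.ecc_range, model=HortonHoytModel()
            )

            if config.simulate is not None:
                stage = "icc"
                tw = config.simulate.twins
                matrices, meta_df = generate_twin_cohort(
                    seed=config.seed, **tw)
                meas = meta_df.set_index("subject_id")["measurement"]
                unrel = match_unrelated_pairs(meta_df)
                icc_rows = []
                for cls, mat in [("MZ", matrices["MZ"]), ("DZ", matrices["DZ"]),
                                 ("UNREL", pairs_to_matrix(unrel, meas))]:
                    res = icc_with_ci(mat, BootstrapConfig(
                        n_boot=config.n_boot, seed=config.seed))
                    icc_rows.append({"class": cls, **res})
                tables["icc"] = pd.DataFrame(icc_rows)

                stage = "retina"
                quartet = generate_density_profiles(
                    meridian_scales=config.simulate.density_scales,
                    noise_sd=config.simulate.density_noise_sd,
                    seed=config.seed,
                )
                curve, fits = asymmetry_curve(quartet)
                for kind, coef in fits.items():
                    curve[f"{kind}_fit_c0"], curve[f"{kind}_fit_c1"], \
                        curve[f"{kind}_fit_c2"] = coef
                tables["retina"] = curve

            stage = "write"
            for name, df in tables.items():
                write_table(df, out / f"{name}.tsv", meta)
                manifest["tables"][name] = len(df)
            caught.extend(str(w.message) for w in wrec)
    except Exception as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        _write_manifest(out, manifest, t0)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    _write_manifest(out, manifest, t0)
    return tables


def _write_manifest(out: Path, manifest: dict, t0: float) -> None:
    manifest["elapsed_s"] = round(time.time() - t0, 3)
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, default=str))
    os.replace(tmp, out / "manifest.json")
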