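"""Readers and writers for surface bundles, sector labels and result tables.

Meshes travel as GIfTI surface files (one per layer) or FreeSurfer binary
geometry; per-vertex retinotopic scalars as GIfTI functional files or a CSV
with columns vertex_id, polar_angle_deg, eccentricity_deg, area_label.
Coarse sectors are a JSON document listing vertex ids per sector with
metadata.  Result tables are tab-separated with a one-line header and a
'#'-prefixed metadata preamble.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .sectors import CoarseSector
from .surface import LAYERS, CorticalSurfaceBundle, VertexRegion

SCALAR_COLUMNS = ("vertex_id", "polar_angle_deg", "eccentricity_deg", "area_label")


# ---------------------------------------------------------------- surfaces

def write_surface_gifti(path, coords: np.ndarray, faces: np.ndarray) -> None:
    img = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"),
        nib.gifti.GiftiDataArray(faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"),
    ])
    nib.save(img, str(path))


def read_surface(path):
    """(coords, faces) from GIfTI (.gii) or FreeSurfer binary geometry."""
    path = str(path)
    if path.endswith(".gii"):
        img = nib.load(path)
        coords = faces = None
        for da in img.darrays:
            if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                coords = np.asarray(da.data, dtype=float)
            elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                faces = np.asarray(da.data, dtype=np.intp)
        if coords is None or faces is None:
            raise ValueError(f"{path}: GIfTI surface lacks pointset/triangle arrays")
        return coords, faces
    try:
        coords, faces = nib.freesurfer.read_geometry(path)
    except Exception as exc:
        raise ValueError(f"unrecognized surface format: {path}") from exc
    return np.asarray(coords, dtype=float), np.asarray(faces, dtype=np.intp)


def write_scalars_csv(path, bundle: CorticalSurfaceBundle) -> None:
    pd.DataFrame({
        "vertex_id": np.arange(bundle.vertex_count),
        "polar_angle_deg": bundle.polar_angle,
        "eccentricity_deg": bundle.eccentricity,
        "area_label": bundle.area_label,
    }).to_csv(path, index=False)


def read_scalars_csv(path, n_vertices: int) -> dict:
    df = pd.read_csv(path)
    missing_cols = set(SCALAR_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    present = set(df["vertex_id"].astype(int))
    missing = sorted(set(range(n_vertices)) - present)
    if missing:
        raise ValueError(
            f"{path}: scalar map missing vertices {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    df = df.sort_values("vertex_id")
    return {
        "polar_angle": df["polar_angle_deg"].to_numpy(dtype=float),
        "eccentricity": df["eccentricity_deg"].to_numpy(dtype=float),
        "area_label": df["area_label"].to_numpy(dtype=object),
    }


def write_bundle(directory, bundle: CorticalSurfaceBundle) -> None:
    """One hemisphere: three .surf.gii layer files plus a scalar CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    h = bundle.hemisphere
    for layer in LAYERS:
        write_surface_gifti(directory / f"{h}.{layer}.surf.gii",
                            bundle.coords[layer], bundle.faces)
    write_scalars_csv(directory / f"{h}.scalars.csv", bundle)


def read_bundle(directory, hemisphere: str) -> CorticalSurfaceBundle:
    directory = Path(directory)
    coords = {}
    faces_ref = None
    for layer in LAYERS:
        coords[layer], faces = read_surface(directory / f"{hemisphere}.{layer}.surf.gii")
        if faces_ref is None:
            faces_ref = faces
        elif faces.shape != faces_ref.shape or (faces != faces_ref).any():
            raise ValueError(
                f"{hemisphere}.{layer}: topology differs between surface layers"
            )
    scalars = read_scalars_csv(directory / f"{hemisphere}.scalars.csv",
                               len(coords["midgray"]))
    bundle = CorticalSurfaceBundle(
        faces=faces_ref, coords=coords, hemisphere=hemisphere, **scalars
    )
    bundle.validate()
    return bundle


# ----------------------------------------------------------------- sectors

def write_sectors_json(path, sectors: list) -> None:
    doc = []
    for s in sectors:
        doc.append({
            "name": s.name,
            "visual_area": s.visual_area,
            "angular_band": list(s.angular_band),
            "ecc_band": list(s.ecc_band),
            "vertices": s.vertices.vertex_ids.tolist(),
            "boundary_a": s.boundary_a.vertex_ids.tolist(),
            "boundary_b": s.boundary_b.vertex_ids.tolist(),
            "boundary_e1": s.boundary_e1.vertex_ids.tolist(),
            "boundary_e2": s.boundary_e2.vertex_ids.tolist(),
        })
    Path(path).write_text(json.dumps(doc))


def read_sectors_json(path) -> list:
    doc = json.loads(Path(path).read_text())
    out = []
    for d in doc:
        out.append(CoarseSector(
            vertices=VertexRegion(np.asarray(d["vertices"], dtype=np.intp),
                                  provenance=d.get("name", "")),
            visual_area=d["visual_area"],
            angular_band=tuple(d["angular_band"]),
            ecc_band=tuple(d["ecc_band"]),
            boundary_a=VertexRegion(np.asarray(d["boundary_a"], dtype=np.intp)),
            boundary_b=VertexRegion(np.asarray(d["boundary_b"], dtype=np.intp)),
            boundary_e1=VertexRegion(np.asarray(d["boundary_e1"], dtype=np.intp)),
            boundary_e2=VertexRegion(np.asarray(d["boundary_e2"], dtype=np.intp)),
            name=d.get("name", ""),
        ))
    return out


# ------------------------------------------------------------------ tables

def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """TSV with a '#'-prefixed metadata preamble, written atomically."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)
    os.replace(tmp, path)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ------------------------------------------------------------------ retina

def read_density_csv(path):
    """Meridian quartet from a CSV with columns meridian, frame,
    eccentricity_deg, density_per_deg2."""
    from .retina import DensityProfile, MeridianQuartet

    df = pd.read_csv(path)
    required = {"meridian", "frame", "eccentricity_deg", "density_per_deg2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    profiles = {}
    for m, grp in df.groupby("meridian"):
        grp = grp.sort_values("eccentricity_deg")
        frames = grp["frame"].unique()
        if len(frames) != 1:
            raise ValueError(f"{path}: meridian {m} mixes frames")
        profiles[m] = DensityProfile(
            meridian=m, frame=frames[0],
            eccentricity=grp["eccentricity_deg"].to_numpy(dtype=float),
            density=grp["density_per_deg2"].to_numpy(dtype=float),
        )
    return MeridianQuartet(**profiles)


def write_density_csv(path, quartet) -> None:
    rows = []
    for p in quartet.profiles():
        for e, d in zip(p.eccentricity, p.density):
            rows.append({"meridian": p.meridian, "frame": p.frame,
                         "eccentricity_deg": e, "density_per_deg2": d})
    pd.DataFrame(rows).to_csv(path, index=False)
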