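"""Readers and writers for velocity fields, geometries, pathlines and results.

Image volumes travel as NIfTI with a JSON sidecar carrying the timing and
velocity-encoding metadata NIfTI has no standard slot for (cycle length,
frame times, VENC).  Pathlines are written as a long-format CSV
(``pathline_id, frame, t_ms, x_mm, y_mm, z_mm, vx, vy, vz``) or a compact
``.npz`` archive.  Result tables are CSV (flow components) and JSON (MBF),
with units spelled out in the headers/keys.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    COMPONENTS,
    ComponentResult,
    LVGeometry,
    MBFResult,
    OrificeDisk,
    PathlineSet,
    VelocityField4D,
)

__all__ = [
    "read_field",
    "write_field",
    "read_geometry",
    "write_geometry",
    "read_pathlines_csv",
    "write_pathlines_csv",
    "read_pathlines_npz",
    "write_pathlines_npz",
    "write_results",
    "read_component_result",
    "read_mbf_result",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_field(field: VelocityField4D, path) -> Path:
    """Write a velocity field as NIfTI (X, Y, Z, T, 3) plus JSON sidecar.

    Velocities are stored in m/s; the sidecar records the VENC in cm/s (the
    console unit) together with frame times and cycle length in ms.
    """
    path = Path(path)
    # (T, X, Y, Z, 3) -> (X, Y, Z, T, 3)
    data = np.moveaxis(field.velocities, 0, 3)
    affine = np.eye(4)
    affine[:3, :3] = np.diag([field.spacing] * 3)
    affine[:3, 3] = field.origin_mm
    img = nib.Nifti1Image(data.astype(np.float64), affine)
    img.header.set_zooms((field.spacing,) * 3 + (1.0, 1.0))
    nib.save(img, str(path))
    sidecar = {
        "frame_times_ms": [float(t) for t in field.frame_times],
        "cycle_length_ms": float(field.cycle_length),
        "venc_cm_per_s": float(field.venc * 100.0),
        "velocity_units": "m/s",
        "periodic": bool(field.periodic),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_field(path) -> VelocityField4D:
    """Read a velocity field written by :func:`write_field`.

    Raises
    ------
    FileNotFoundError
        If the image or its JSON sidecar is missing.
    ValueError
        If timing metadata is absent (the missing key is named), frame
        times are not strictly increasing, or the stored velocity unit is
        not convertible.
    """
    path = Path(path)
    img = nib.load(str(path))
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(
            f"timing sidecar {sidecar_file} not found; velocity fields need "
            "frame_times_ms / cycle_length_ms / venc_cm_per_s metadata"
        )
    meta = json.loads(sidecar_file.read_text())
    for key in ("frame_times_ms", "cycle_length_ms", "venc_cm_per_s"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_file} is missing required field {key!r}")
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 5 or data.shape[-1] != 3:
        raise ValueError(
            f"{path} must hold a (X, Y, Z, T, 3) velocity volume; got {data.shape}"
        )
    units = meta.get("velocity_units", "m/s")
    if units == "cm/s":
        data = data / 100.0
    elif units != "m/s":
        raise ValueError(f"unsupported velocity unit {units!r}")
    affine = img.affine
    spacing = float(affine[0, 0])
    return VelocityField4D(
        velocities=np.moveaxis(data, 3, 0),
        spacing=spacing,
        frame_times=np.asarray(meta["frame_times_ms"], dtype=float),
        cycle_length=float(meta["cycle_length_ms"]),
        venc=float(meta["venc_cm_per_s"]) / 100.0,
        origin_mm=affine[:3, 3].copy(),
        periodic=bool(meta.get("periodic", False)),
    )


def write_geometry(geom: LVGeometry, path) -> Path:
    """Write LV geometry: one NIfTI label volume plus a JSON sidecar.

    The label volume encodes the three masks bitwise (1 = ED, 2 = ES prev,
    4 = ES next); orifice disks and frame indices go to the sidecar.
    """
    path = Path(path)
    labels = (
        geom.ed_mask.astype(np.uint8)
        + 2 * geom.es_mask_prev.astype(np.uint8)
        + 4 * geom.es_mask_next.astype(np.uint8)
    )
    affine = np.eye(4)
    affine[:3, :3] = np.diag([geom.spacing] * 3)
    affine[:3, 3] = geom.origin_mm
    nib.save(nib.Nifti1Image(labels, affine), str(path))
    sidecar = {
        "orifices": [
            {
                "name": o.name,
                "center_mm": [float(c) for c in o.center_mm],
                "normal": [float(c) for c in o.normal],
                "radius_mm": float(o.radius_mm),
            }
            for o in geom.orifices
        ],
        "ed_frame": geom.ed_frame,
        "es_frame_prev": geom.es_frame_prev,
        "es_frame_next": geom.es_frame_next,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_geometry(path) -> LVGeometry:
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.uint8)
    meta = json.loads(_sidecar_path(path).read_text())
    orifices = [
        OrificeDisk(
            name=o["name"],
            center_mm=tuple(o["center_mm"]),
            normal=tuple(o["normal"]),
            radius_mm=o["radius_mm"],
        )
        for o in meta["orifices"]
    ]
    return LVGeometry(
        ed_mask=(labels & 1) > 0,
        es_mask_prev=(labels & 2) > 0,
        es_mask_next=(labels & 4) > 0,
        orifices=orifices,
        spacing=float(img.affine[0, 0]),
        origin_mm=img.affine[:3, 3].copy(),
        ed_frame=meta.get("ed_frame", 0),
        es_frame_prev=meta.get("es_frame_prev"),
        es_frame_next=meta.get("es_frame_next"),
    )


def write_pathlines_csv(pathlines: PathlineSet, path) -> Path:
    """Long-format CSV, one row per pathline per timeframe."""
    path = Path(path)
    n, k, _ = pathlines.positions.shape
    ids = np.repeat(np.arange(n), k)
    frames = np.tile(np.arange(k), n)
    pos = pathlines.positions.reshape(-1, 3)
    vel = pathlines.velocities.reshape(-1, 3)
    df = pd.DataFrame(
        {
            "pathline_id": ids,
            "frame": frames,
            "t_ms": np.tile(pathlines.times_ms, n),
            "x_mm": pos[:, 0],
            "y_mm": pos[:, 1],
            "z_mm": pos[:, 2],
            "vx_m_per_s": vel[:, 0],
            "vy_m_per_s": vel[:, 1],
            "vz_m_per_s": vel[:, 2],
        }
    )
    df.to_csv(path, index=False)
    meta = pd.DataFrame(
        {
            "pathline_id": np.arange(n),
            "volume_mm3": pathlines.volumes_mm3,
            "qc_status": pathlines.qc_status,
            "component": [c if c is not None else "" for c in pathlines.components],
            "inflow_phase": [
                p if p is not None else "" for p in pathlines.inflow_phase
            ],
        }
    )
    meta.to_csv(path.with_suffix(".meta.csv"), index=False)
    return path


def read_pathlines_csv(path) -> PathlineSet:
    path = Path(path)
    df = pd.read_csv(path)
    n = int(df["pathline_id"].max()) + 1
    k = int(df["frame"].max()) + 1
    order = np.lexsort((df["frame"].to_numpy(), df["pathline_id"].to_numpy()))
    pos = df[["x_mm", "y_mm", "z_mm"]].to_numpy()[order].reshape(n, k, 3)
    vel = df[["vx_m_per_s", "vy_m_per_s", "vz_m_per_s"]].to_numpy()[order].reshape(
        n, k, 3
    )
    times = df["t_ms"].to_numpy()[order][:k]
    meta_path = path.with_suffix(".meta.csv")
    if meta_path.exists():
        meta = pd.read_csv(meta_path, keep_default_na=False)
        volumes = meta["volume_mm3"].to_numpy()
        qc = meta["qc_status"].to_numpy(dtype=object)
        comp = np.array(
            [c if c != "" else None for c in meta["component"]], dtype=object
        )
        phase = np.array(
            [p if p != "" else None for p in meta["inflow_phase"]], dtype=object
        )
    else:
        volumes = np.ones(n)
        qc = np.full(n, "valid", dtype=object)
        comp = phase = None
    return PathlineSet(pos, vel, times, volumes, qc, comp, phase)


def write_pathlines_npz(pathlines: PathlineSet, path) -> Path:
    """Compact binary archive of a pathline set."""
    path = Path(path)
    np.savez_compressed(
        path,
        positions=pathlines.positions,
        velocities=pathlines.velocities,
        times_ms=pathlines.times_ms,
        volumes_mm3=pathlines.volumes_mm3,
        qc_status=pathlines.qc_status.astype(str),
        components=np.array(
            [c if c is not None else "" for c in pathlines.components]
        ),
        inflow_phase=np.array(
            [p if p is not None else "" for p in pathlines.inflow_phase]
        ),
    )
    return path


def read_pathlines_npz(path) -> PathlineSet:
    with np.load(path, allow_pickle=False) as z:
        comp = np.array([c if c != "" else None for c in z["components"]], dtype=object)
        phase = np.array(
            [p if p != "" else None for p in z["inflow_phase"]], dtype=object
        )
        return PathlineSet(
            z["positions"],
            z["velocities"],
            z["times_ms"],
            z["volumes_mm3"],
            z["qc_status"].astype(object),
            comp,
            phase,
        )


def write_results(result, path) -> Path:
    """Write a :class:`ComponentResult` (CSV) or :class:`MBFResult` (JSON).

    Column order and key order are deterministic so outputs diff cleanly.
    """
    path = Path(path)
    if isinstance(result, ComponentResult):
        rows = []
        for comp in COMPONENTS:
            rows.append(
                {
                    "component": comp,
                    "volume_ml": result.volumes.get(comp, 0.0),
                    "ke_ed_uJ_per_ml": result.ke_per_ml_at_ed.get(comp, np.nan),
                }
            )
        df = pd.DataFrame(rows, columns=["component", "volume_ml", "ke_ed_uJ_per_ml"])
        df.to_csv(path, index=False)
        extra = {
            "edv_ml": result.edv,
            "inflow_ml": result.inflow,
            "ejected_ml": result.ejected,
            "direct_flow_split_ml": result.direct_flow_split,
            "mid_diastole_frame": result.mid_diastole_frame,
        }
        path.with_suffix(".json").write_text(json.dumps(extra, indent=1))
        return path
    if isinstance(result, MBFResult):
        payload = {
            "global_mbf": float(result.global_mbf),
            "regional_mbf": [float(v) for v in result.regional_mbf],
            "septal_mbf": [float(v) for v in result.septal_mbf],
            "pn": None if result.pn is None else float(result.pn),
            "tn": None if result.tn is None else float(result.tn),
            "per_pair_mbf": [float(v) for v in result.per_pair_mbf],
            "units": "ml/g/min",
        }
        path.write_text(json.dumps(payload, indent=1))
        return path
    raise TypeError(f"cannot write result of type {type(result).__name__}")


def read_component_result(path) -> ComponentResult:
    path = Path(path)
    df = pd.read_csv(path)
    extra = json.loads(path.with_suffix(".json").read_text())
    volumes = dict(zip(df["component"], df["volume_ml"]))
    ke_ed = {
        c: k
        for c, k in zip(df["component"], df["ke_ed_uJ_per_ml"])
        if np.isfinite(k)
    }
    return ComponentResult(
        volumes=volumes,
        ke_timeseries={},
        ke_per_ml_at_ed=ke_ed,
        direct_flow_split=extra["direct_flow_split_ml"],
        edv=extra["edv_ml"],
        inflow=extra["inflow_ml"],
        ejected=extra["ejected_ml"],
        mid_diastole_frame=extra.get("mid_diastole_frame"),
    )


def read_mbf_result(path) -> MBFResult:
    payload = json.loads(Path(path).read_text())
    return MBFResult(
        global_mbf=payload["global_mbf"],
        regional_mbf=np.asarray(payload["regional_mbf"], dtype=float),
        septal_mbf=np.asarray(payload["septal_mbf"], dtype=float),
        per_pair_mbf=np.asarray(payload["per_pair_mbf"], dtype=float),
        pn=payload.get("pn"),
        tn=payload.get("tn"),
    )
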