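"""Product serialization: HDF5 scan archives, TIFF rasters, CSV tables.

Rasters are single-band TIFFs with a JSON sidecar carrying the planar-km
affine transform; scan archives hold per-sweep dBZ/flag arrays plus the
simulator's ground-truth mask groups.
"""
from __future__ import annotations

import datetime as dt
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .grids import Grid
from .scans import PolarGeometry, PolarScan, Sweep


def save_scan_archive(path, scans: list[PolarScan]) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        geo = scans[0].geometry
        f.attrs["station_id"] = scans[0].station_id
        f.attrs["gate_depth_m"] = geo.gate_depth_m
        f.attrs["azimuth_step_deg"] = geo.azimuth_step_deg
        f.attrs["max_range_km"] = geo.max_range_km
        f.create_dataset(
            "timestamps", data=[s.timestamp.isoformat().encode() for s in scans]
        )
        f.create_dataset(
            "elevation_angles", data=[sw.elevation_deg for sw in scans[0].sweeps]
        )
        for i, scan in enumerate(scans):
            g = f.create_group(f"scans/{i:04d}")
            g.create_dataset("dbz", data=np.stack([sw.dbz for sw in scan.sweeps]),
                             compression="gzip", compression_opts=1)
            g.create_dataset("flags", data=np.stack([sw.flags for sw in scan.sweeps]),
                             compression="gzip", compression_opts=1)
            if scan.minutes_after_sunset is not None:
                g.attrs["minutes_after_sunset"] = scan.minutes_after_sunset
            for name, mask in scan.truth.items():
                g.create_dataset(f"truth/{name}", data=np.asarray(mask, dtype=bool),
                                 compression="gzip", compression_opts=1)


def load_scan_archive(path) -> list[PolarScan]:
    with h5py.File(path, "r") as f:
        geo = PolarGeometry(
            gate_depth_m=float(f.attrs["gate_depth_m"]),
            azimuth_step_deg=float(f.attrs["azimuth_step_deg"]),
            max_range_km=float(f.attrs["max_range_km"]),
        )
        station = f.attrs["station_id"]
        timestamps = [dt.datetime.fromisoformat(t.decode()) for t in f["timestamps"][()]]
        elevations = list(f["elevation_angles"][()])
        scans = []
        for i, ts in enumerate(timestamps):
            g = f[f"scans/{i:04d}"]
            dbz = g["dbz"][()]
            flags = g["flags"][()]
            sweeps = [
                Sweep(elevation_deg=float(el), dbz=dbz[j], flags=flags[j])
                for j, el in enumerate(elevations)
            ]
            truth = {}
            if "truth" in g:
                truth = {k: g[f"truth/{k}"][()] for k in g["truth"]}
            scans.append(
                PolarScan(
                    station_id=str(station),
                    timestamp=ts,
                    geometry=geo,
                    sweeps=sweeps,
                    minutes_after_sunset=float(g.attrs["minutes_after_sunset"])
                    if "minutes_after_sunset" in g.attrs
                    else None,
                    truth=truth,
                )
            )
    return scans


def save_raster(path, values: np.ndarray, grid: Grid, meta: dict | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    sidecar = {
        "pixel_km": grid.pixel_km,
        "x0_km": grid.x0_km,
        "y0_km": grid.y0_km,
        "nx": grid.nx,
        "ny": grid.ny,
        "nodata": "NaN",
    }
    if meta:
        sidecar.update(meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_raster(path) -> tuple[np.ndarray, Grid]:
    path = Path(path)
    values = tifffile.imread(path)
    side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = Grid(
        nx=side["nx"], ny=side["ny"], pixel_km=side["pixel_km"],
        x0_km=side["x0_km"], y0_km=side["y0_km"],
    )
    return np.asarray(values, dtype=float), grid


def save_table(path, table: pd.DataFrame, registry: dict[str, str] | None = None) -> None:
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.6g")
    if registry is not None:
        path.with_suffix(".columns.json").write_text(json.dumps(registry, indent=1))


def config_hash(config) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def write_provenance(path, config, seed: int, extra: dict | None = None) -> None:
    import xgboost

    prov = {
        "config_hash": config_hash(config),
        "seed": seed,
        "written": dt.datetime.now().isoformat(timespec="seconds"),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "xgboost": xgboost.__version__,
        },
    }
    if extra:
        prov.update(extra)
    Path(path).write_text(json.dumps(prov, indent=1))
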