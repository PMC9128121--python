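"""Readers and writers for the pipeline's file formats.

Tabular data are CSV; the covariate stack is written either as a single
CF-style NetCDF file (via xarray's scipy backend) or as one TIFF per
layer/day with a JSON grid-spec sidecar; both dialects are readable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .covariates import CovariateStack, GridSpec
from .preprocess import PathRealization
from .synthetic import ArgosObservation, TruePath

OBS_COLUMNS = [
    "animal_id",
    "class",
    "timestamp",
    "x_m",
    "y_m",
    "smaj_m",
    "smin_m",
    "orient_rad",
    "duty_cycle_id",
]


def observations_to_frame(obs: list[ArgosObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [o.animal_id for o in obs],
            "class": [o.class_label for o in obs],
            "timestamp": [pd.Timestamp(o.timestamp).isoformat() for o in obs],
            "x_m": [o.x for o in obs],
            "y_m": [o.y for o in obs],
            "smaj_m": [o.semi_major for o in obs],
            "smin_m": [o.semi_minor for o in obs],
            "orient_rad": [o.orientation for o in obs],
            "duty_cycle_id": [o.duty_cycle_id for o in obs],
        }
    )


def frame_to_observations(df: pd.DataFrame) -> list[ArgosObservation]:
    return [
        ArgosObservation(
            animal_id=str(r["animal_id"]),
            class_label=str(r["class"]),
            timestamp=np.datetime64(pd.Timestamp(r["timestamp"])),
            x=float(r["x_m"]),
            y=float(r["y_m"]),
            semi_major=float(r["smaj_m"]),
            semi_minor=float(r["smin_m"]),
            orientation=float(r["orient_rad"]),
            duty_cycle_id=int(r["duty_cycle_id"]),
        )
        for r in df.to_dict("records")
    ]


def write_observations(obs: list[ArgosObservation], path) -> None:
    observations_to_frame(obs).to_csv(path, index=False)


def read_observations(path) -> list[ArgosObservation]:
    return frame_to_observations(pd.read_csv(path))


def paths_to_frame(paths: list) -> pd.DataFrame:
    frames = []
    for p in paths:
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": p.animal_id,
                    "class": p.class_label,
                    "timestamp": [pd.Timestamp(t).isoformat() for t in p.times],
                    "x_m": p.xy[:, 0],
                    "y_m": p.xy[:, 1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_paths(paths: list, path) -> None:
    paths_to_frame(paths).to_csv(path, index=False)


def read_realizations(path, dataset_index: int) -> list[PathRealization]:
    df = pd.read_csv(path)
    out = []
    for aid, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("timestamp")
        out.append(
            PathRealization(
                animal_id=str(aid),
                class_label=str(grp["class"].iloc[0]),
                dataset_index=dataset_index,
                times=np.array([np.datetime64(pd.Timestamp(t)) for t in grp.timestamp]),
                xy=grp[["x_m", "y_m"]].to_numpy(float),
            )
        )
    return out


def read_true_paths(path) -> list[TruePath]:
    df = pd.read_csv(path)
    out = []
    for aid, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("timestamp")
        xy = grp[["x_m", "y_m"]].to_numpy(float)
        d = np.diff(xy, axis=0)
        out.append(
            TruePath(
                animal_id=str(aid),
                class_label=str(grp["class"].iloc[0]),
                times=np.array([np.datetime64(pd.Timestamp(t)) for t in grp.timestamp]),
                xy=xy,
                bearings=np.arctan2(d[:, 1], d[:, 0]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# covariate stack
# ---------------------------------------------------------------------------


def stack_to_dataset(stack: CovariateStack) -> xr.Dataset:
    xs, ys = stack.grid.cell_centers()
    return xr.Dataset(
        data_vars={
            "depth": (("y", "x"), stack.depth, {"units": "m"}),
            "land_mask": (("y", "x"), stack.land_mask.astype(np.int8)),
            "ice_conc": (("time", "y", "x"), stack.ice_conc, {"units": "percent"}),
        },
        coords={"x": xs, "y": ys, "time": stack.dates.astype("datetime64[s]")},
        attrs={
            "x0": stack.grid.x0,
            "y0": stack.grid.y0,
            "cell_size": stack.grid.cell_size,
            "Conventions": "CF-1.8",
        },
    )


def write_stack_netcdf(stack: CovariateStack, path) -> None:
    stack_to_dataset(stack).to_netcdf(path, engine="scipy")


def read_stack_netcdf(path) -> CovariateStack:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    grid = GridSpec(
        x0=float(ds.attrs["x0"]),
        y0=float(ds.attrs["y0"]),
        cell_size=float(ds.attrs["cell_size"]),
        nrows=ds.sizes["y"],
        ncols=ds.sizes["x"],
    )
    return CovariateStack(
        grid=grid,
        depth=ds["depth"].values,
        ice_conc=ds["ice_conc"].values,
        land_mask=ds["land_mask"].values.astype(bool),
        dates=ds["time"].values.astype("datetime64[D]"),
    )


def write_stack_tiffs(stack: CovariateStack, out_dir) -> None:
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out_dir / "depth.tif", stack.depth.astype(np.float32))
    tifffile.imwrite(out_dir / "land_mask.tif", stack.land_mask.astype(np.uint8))
    for d in range(stack.n_days):
        tifffile.imwrite(
            out_dir / f"ice_conc_{d:04d}.tif", stack.ice_conc[d].astype(np.float32)
        )
    meta = {
        "x0": stack.grid.x0,
        "y0": stack.grid.y0,
        "cell_size": stack.grid.cell_size,
        "nrows": stack.grid.nrows,
        "ncols": stack.grid.ncols,
        "dates": [str(d) for d in stack.dates],
    }
    (out_dir / "gridspec.json").write_text(json.dumps(meta, indent=1))


def read_stack_tiffs(in_dir) -> CovariateStack:
    import tifffile

    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "gridspec.json").read_text())
    grid = GridSpec(
        x0=meta["x0"],
        y0=meta["y0"],
        cell_size=meta["cell_size"],
        nrows=meta["nrows"],
        ncols=meta["ncols"],
    )
    dates = np.array(meta["dates"], dtype="datetime64[D]")
    ice = np.stack(
        [
            tifffile.imread(in_dir / f"ice_conc_{d:04d}.tif").astype(float)
            for d in range(dates.size)
        ]
    )
    return CovariateStack(
        grid=grid,
        depth=tifffile.imread(in_dir / "depth.tif").astype(float),
        ice_conc=ice,
        land_mask=tifffile.imread(in_dir / "land_mask.tif").astype(bool),
        dates=dates,
    )


def read_stack(path) -> CovariateStack:
    """Read either stack dialect: a NetCDF file or a TIFF directory."""
    p = Path(path)
    if p.is_dir():
        return read_stack_tiffs(p)
    return read_stack_netcdf(p)
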