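"""Reading and writing the package's simple text and image formats.

Point sets and trajectories travel as CSV, grids as CSV or binary PNG masks,
run metadata as YAML.  These helpers keep the column conventions in one
place.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .indices import ColonyPointSet
from .rates import AreaSeries


def write_points_csv(points: ColonyPointSet, path) -> None:
    pd.DataFrame(points.points, columns=["x", "y"]).to_csv(path, index=False)


def read_points_csv(path, bounds=None, seeds=None) -> ColonyPointSet:
    df = pd.read_csv(path)
    pts = df[["x", "y"]].to_numpy(dtype=float)
    if bounds is None:
        pad = 0.5
        bounds = (
            pts[:, 0].min() - pad,
            pts[:, 0].max() + pad,
            pts[:, 1].min() - pad,
            pts[:, 1].max() + pad,
        )
    return ColonyPointSet(points=pts, bounds=bounds, seeds=seeds)


def write_area_series_csv(series: AreaSeries, path) -> None:
    pd.DataFrame(
        {
            "time": series.times,
            "area": series.areas,
            "time_units": series.time_units,
            "area_units": series.area_units,
        }
    ).to_csv(path, index=False)


def read_area_series_csv(path) -> AreaSeries:
    df = pd.read_csv(path)
    return AreaSeries(
        times=df["time"].to_numpy(float),
        areas=df["area"].to_numpy(float),
        time_units=str(df["time_units"].iloc[0]) if "time_units" in df else "min",
        area_units=str(df["area_units"].iloc[0]) if "area_units" in df else "mm2",
    )


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG (cell pixels = 255)."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, dtype=np.uint8) * 255))


def read_mask_png(path) -> np.ndarray:
    """Read a PNG as a binary mask (any nonzero channel value = 1)."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img.max(axis=2)
    return (img > 0).astype(np.uint8)


def write_trajectory_csv(result, path) -> None:
    pd.DataFrame(
        result.trajectory, columns=["t_step", "nu", "free_packets"]
    ).to_csv(path, index=False)


def write_manifest(path, **fields) -> None:
    """Write a YAML run manifest (command, config, seeds, outputs)."""
    with open(path, "w") as fh:
        yaml.safe_dump(fields, fh, sort_keys=False)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
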