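"""File formats: per-year burn rasters, land-cover raster, and CSV tables.

Raster layout: one single-band TIFF per year named ``burn_<year>.tif``
(values 0/1) plus ``landcover.tif`` holding integer class codes, with a
JSON sidecar ``landcover_classes.json`` mapping codes to labels and
recording the cell size and year range.  Tabular alternative: a CSV with
columns point_id, x, y, class, fire_years (semicolon-separated).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .censoring import FireHistoryGrid, intervals_from_fire_years, observations_to_frame
from .model import IntervalObservation

__all__ = [
    "write_grid_rasters",
    "read_grid_rasters",
    "write_points_csv",
    "read_points_csv",
    "write_observations_csv",
    "read_observations_csv",
]


def write_grid_rasters(grid: FireHistoryGrid, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = grid.land_cover.astype(str)
    codes = {lab: i for i, lab in enumerate(sorted(np.unique(labels)))}
    lc = np.vectorize(codes.get)(labels).astype(np.uint16)
    tifffile.imwrite(out / "landcover.tif", lc)
    y0, y1 = grid.years
    for i, year in enumerate(range(y0, y1 + 1)):
        tifffile.imwrite(out / f"burn_{year}.tif", grid.burn_mask[i].astype(np.uint8))
    meta = {
        "years": [y0, y1],
        "cell_size_m": grid.cell_size,
        "classes": {str(v): k for k, v in codes.items()},
    }
    (out / "landcover_classes.json").write_text(json.dumps(meta, indent=2))
    return out


def read_grid_rasters(in_dir: str | Path) -> FireHistoryGrid:
    src = Path(in_dir)
    meta = json.loads((src / "landcover_classes.json").read_text())
    y0, y1 = meta["years"]
    lc_codes = tifffile.imread(src / "landcover.tif")
    codes = {int(k): v for k, v in meta["classes"].items()}
    labels = np.vectorize(codes.get)(lc_codes)
    masks = np.stack(
        [tifffile.imread(src / f"burn_{year}.tif").astype(bool) for year in range(y0, y1 + 1)]
    )
    return FireHistoryGrid(masks, labels, (y0, y1), float(meta["cell_size_m"]))


def write_points_csv(
    path: str | Path,
    fire_years_per_point: Sequence[Sequence[int]],
    classes: Sequence[str],
    xy: Sequence[tuple[float, float]] | None = None,
) -> None:
    rows = []
    for i, (fy, cls) in enumerate(zip(fire_years_per_point, classes)):
        x, y = xy[i] if xy is not None else (float("nan"), float("nan"))
        rows.append(dict(point_id=i, x=x, y=y, **{"class": cls}, fire_years=";".join(map(str, fy))))
    pd.DataFrame(rows).to_csv(path, index=False)


def read_points_csv(path: str | Path, record: tuple[int, int]) -> list[IntervalObservation]:
    """Interval observations from a tabular per-point fire-year list."""
    df = pd.read_csv(path, dtype={"fire_years": str}, keep_default_na=False)
    out: list[IntervalObservation] = []
    for _, row in df.iterrows():
        fy = [int(v) for v in str(row.fire_years).split(";") if v.strip()]
        out.extend(intervals_from_fire_years(fy, record, str(row["class"])))
    return out


def write_observations_csv(path: str | Path, sample: Iterable[IntervalObservation]) -> None:
    df = observations_to_frame(sample)
    df.insert(0, "point_id", range(len(df)))
    df.to_csv(path, index=False)


def read_observations_csv(path: str | Path) -> list[IntervalObservation]:
    from .censoring import frame_to_observations

    return frame_to_observations(pd.read_csv(path))
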