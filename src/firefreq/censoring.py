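"""Point-grid sampling of censored fire intervals from a burned-area stack.

A regular point grid (default 500 m spacing) is laid over the landscape.
Each point's per-year burn record is converted into interval observations:
complete intervals between consecutive fires, one left-censored observation
for the fire-free period running into the start of the record, and one
right-censored observation for the open period after the last fire.  Points
that never burned yield a single right-censored observation spanning the
whole record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import CensorStatus, IntervalObservation

__all__ = ["FireHistoryGrid", "point_grid_indices", "intervals_from_fire_years", "extract_intervals"]

# classes never able to carry fire; points on them are excluded
UNBURNABLE_LABELS = frozenset({"sand", "water", ""})


@dataclass
class FireHistoryGrid:
    """Annual burn masks plus a land-cover map on one shared grid.

    burn_mask   -- boolean array of shape (n_years, rows, cols)
    land_cover  -- object/str array of shape (rows, cols); labels in
                   UNBURNABLE_LABELS mark cells excluded from sampling
    years       -- (first_year, last_year) inclusive; contiguous
    cell_size   -- cell edge length in meters
    """

    burn_mask: np.ndarray
    land_cover: np.ndarray
    years: tuple[int, int]
    cell_size: float

    def __post_init__(self) -> None:
        self.burn_mask = np.asarray(self.burn_mask, dtype=bool)
        self.land_cover = np.asarray(self.land_cover)
        y0, y1 = self.years
        n = y1 - y0 + 1
        if n < 2:
            raise ValueError("record must span at least 2 years")
        if self.burn_mask.ndim != 3 or self.burn_mask.shape[0] != n:
            raise ValueError(
                f"burn_mask must have shape (n_years={n}, rows, cols), got {self.burn_mask.shape}"
            )
        if self.land_cover.shape != self.burn_mask.shape[1:]:
            raise ValueError("land_cover and burn_mask grids disagree")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.land_cover.shape


def point_grid_indices(shape: tuple[int, int], cell_size: float, spacing_m: float) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of a regular point grid with the given spacing.

    The stride is spacing_m / cell_size rounded to the nearest whole cell
    (minimum 1); the first point sits at half a stride from the edge so the
    grid is centered in the extent.
    """
    if spacing_m < cell_size:
        raise ValueError("spacing must be at least one cell")
    rows, cols = shape
    step = max(1, int(round(spacing_m / cell_size)))
    if step > rows or step > cols:
        raise ValueError("spacing exceeds the landscape extent")
    r = np.arange(step // 2, rows, step)
    c = np.arange(step // 2, cols, step)
    rr, cc = np.meshgrid(r, c, indexing="ij")
    return rr.ravel(), cc.ravel()


def intervals_from_fire_years(
    fire_years: Sequence[int],
    record: tuple[int, int],
    class_label: str = "",
) -> list[IntervalObservation]:
    """Censored interval observations for one point.

    For fire years y1 < ... < yk within the inclusive record [Y0, Y1]:

    * complete intervals y_{j+1} - y_j for consecutive fires;
    * one left-censored observation of open length y1 - Y0 + 1 (the previous
      fire predates the record: the interval ending at y1 is at least that
      long);
    * one right-censored observation of length Y1 - yk (the next fire was
      not observed).

    A point with no fires yields a single right-censored observation of
    length N (the record length).  Censored lengths of 0 are retained; they
    carry no likelihood information.
    """
    y0, y1 = record
    ys = sorted(set(int(y) for y in fire_years))
    if ys and (ys[0] < y0 or ys[-1] > y1):
        raise ValueError(f"fire years {ys} outside record {record}")
    n = y1 - y0 + 1
    if not ys:
        return [IntervalObservation(n, CensorStatus.RIGHT_CENSORED, class_label)]
    obs = [IntervalObservation(ys[0] - y0 + 1, CensorStatus.LEFT_CENSORED, class_label)]
    obs += [
        IntervalObservation(b - a, CensorStatus.COMPLETE, class_label)
        for a, b in zip(ys, ys[1:])
    ]
    obs.append(IntervalObservation(y1 - ys[-1], CensorStatus.RIGHT_CENSORED, class_label))
    return obs


def extract_intervals(
    grid: FireHistoryGrid,
    spacing_m: float = 500.0,
    drop_uninformative: bool = False,
) -> list[IntervalObservation]:
    """Sample a regular point grid and extract censored interval observations.

    Points on unburnable land cover (sand, water) are excluded.  With
    ``drop_uninformative`` set, censored observations of length 0 (and
    left-censored of length 1, whose likelihood contribution is also exactly
    zero) are removed from the output.
    """
    rr, cc = point_grid_indices(grid.shape, grid.cell_size, spacing_m)
    y0, y1 = grid.years
    year_idx = np.arange(y0, y1 + 1)
    out: list[IntervalObservation] = []
    for r, c in zip(rr, cc):
        label = str(grid.land_cover[r, c])
        if label in UNBURNABLE_LABELS:
            continue
        burned = grid.burn_mask[:, r, c]
        fire_years = year_idx[burned]
        out.extend(intervals_from_fire_years(fire_years, grid.years, label))
    if drop_uninformative:
        out = [
            o
            for o in out
            if not (
                (o.status == CensorStatus.RIGHT_CENSORED and o.length == 0)
                or (o.status == CensorStatus.LEFT_CENSORED and o.length <= 1)
            )
        ]
    if not out:
        raise ValueError("no sampled points fell on burnable land cover")
    return out


def observations_to_frame(sample: Iterable[IntervalObservation]) -> pd.DataFrame:
    """Tabular view (class, length, status) of an observation list."""
    return pd.DataFrame(
        [(o.class_label, o.length, o.status.value) for o in sample],
        columns=["class", "length", "status"],
    )


def frame_to_observations(df: pd.DataFrame) -> list[IntervalObservation]:
    """Inverse of :func:`observations_to_frame`."""
    return [
        IntervalObservation(int(row.length), CensorStatus(row.status), str(row["class"]))
        for _, row in df.iterrows()
    ]
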