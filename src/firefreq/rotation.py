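"""Fire rotation period and annual percentage of area burned.

FRP = N * S / sum_y A_y, the time needed to burn a cumulative area equal to
the burnable study area, where N is the number of record years, S the area
susceptible to burn and A_y the area burned in year y.  APAB = 100 / FRP is
the mean percent of the burnable area burned per year.  FRP * APAB = 100 by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .censoring import UNBURNABLE_LABELS, FireHistoryGrid

__all__ = ["RotationSummary", "rotation_from_areas", "fire_rotation", "burn_count_map"]


@dataclass
class RotationSummary:
    class_label: str
    susceptible_area_ha: float
    years: int
    annual_burned_ha: tuple[float, ...]
    frp: float
    apab: float
    no_fire: bool = False


def rotation_from_areas(
    annual_burned_ha,
    susceptible_area_ha: float,
    class_label: str = "all",
) -> RotationSummary:
    """FRP/APAB from a per-year burned-area series (hectares)."""
    burned = tuple(float(a) for a in annual_burned_ha)
    n = len(burned)
    if n < 1:
        raise ValueError("need at least one year of burned area")
    if susceptible_area_ha <= 0:
        raise ValueError("susceptible area must be positive")
    total = sum(burned)
    if total == 0:
        return RotationSummary(class_label, susceptible_area_ha, n, burned, math.inf, 0.0, no_fire=True)
    frp = n * susceptible_area_ha / total
    return RotationSummary(class_label, susceptible_area_ha, n, burned, frp, 100.0 / frp)


def fire_rotation(grid: FireHistoryGrid, class_filter: str | None = None) -> RotationSummary:
    """FRP/APAB for a fire-history grid, optionally for one land-cover class.

    The susceptible area excludes unburnable cells (sand, water).  Cell
    areas derive from the grid cell size; the result is invariant to a
    uniform rescaling of the cell size because area units cancel.
    """
    cell_ha = (grid.cell_size**2) / 10_000.0
    labels = grid.land_cover.astype(str)
    if class_filter is None:
        mask = ~np.isin(labels, list(UNBURNABLE_LABELS))
        label = "all"
    else:
        mask = labels == class_filter
        label = class_filter
    s_cells = int(mask.sum())
    if s_cells == 0:
        raise ValueError(f"no burnable cells for class filter {class_filter!r}")
    annual = [float(np.sum(grid.burn_mask[i][mask])) * cell_ha for i in range(grid.n_years)]
    return rotation_from_areas(annual, s_cells * cell_ha, label)


def rotation_table(grid: FireHistoryGrid) -> pd.DataFrame:
    """Per-class (plus overall) FRP/APAB table."""
    labels = sorted(set(np.unique(grid.land_cover.astype(str))) - set(UNBURNABLE_LABELS))
    rows = []
    for lab in ["all", *labels]:
        r = fire_rotation(grid, None if lab == "all" else lab)
        rows.append(
            dict(
                class_label=r.class_label,
                susceptible_area_ha=r.susceptible_area_ha,
                years=r.years,
                total_burned_ha=sum(r.annual_burned_ha),
                frp=r.frp,
                apab=r.apab,
            )
        )
    return pd.DataFrame(rows)


def burn_count_map(grid: FireHistoryGrid) -> np.ndarray:
    """Number of times each cell burned over the record (times-burned map)."""
    return grid.burn_mask.sum(axis=0).astype(int)
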