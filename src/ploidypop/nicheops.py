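"""Presence-raster post-processing: thresholding, merging, area accounting.

Climate-niche models output per-cell normalized vote fractions; cells with
votes strictly above 0.6 count as predicted presence.  Two subspecies
models merge into four classes per cell (A-only, B-only, co-occurring,
absent), class areas are cell counts times a uniform nominal cell area
(km^2), and scenarios compare through percent habitat loss against a
reference (negative loss = gain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "PresenceGrid",
    "AreaSummary",
    "threshold_votes",
    "merge_models",
    "area_summary",
    "percent_loss",
    "overlap_share_percent",
    "read_ascii_grid",
    "write_ascii_grid",
]

CLASS_ABSENT, CLASS_A_ONLY, CLASS_B_ONLY, CLASS_BOTH = 0, 1, 2, 3


@dataclass
class PresenceGrid:
    """A vote or presence raster with uniform cell area.

    ``values`` holds vote fractions in [0, 1] (float) or presence flags
    (bool); ``nodata`` masks cells outside the modelled extent.
    """

    values: np.ndarray
    cell_area: float  # km^2 per cell
    nodata: np.ndarray | None = None
    scenario: str = "contemporary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.cell_area <= 0:
            raise ValueError("cell area must be positive")
        if self.nodata is None:
            self.nodata = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata = np.asarray(self.nodata, dtype=bool)
            if self.nodata.shape != self.values.shape:
                raise ValueError("nodata mask shape mismatch")
        # float grids hold vote fractions; bool = presence; int = classes
        if np.issubdtype(self.values.dtype, np.floating):
            vals = self.values[~self.nodata]
            if vals.size and (vals.min() < 0 or vals.max() > 1):
                raise ValueError("vote fractions must lie in [0, 1]")


@dataclass
class AreaSummary:
    """Class areas (km^2) for one scenario, plus optional percent loss."""

    areas: dict[str, float]  # a_only, b_only, co_occurring, total
    scenario: str = "contemporary"
    percent_loss_vs_reference: dict[str, float] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for cls, a in self.areas.items():
            rows.append(
                {
                    "class": cls,
                    "area_km2": a,
                    "percent_loss": self.percent_loss_vs_reference.get(cls, np.nan),
                }
            )
        return pd.DataFrame(rows)


def threshold_votes(grid: PresenceGrid, cutoff: float = 0.6) -> PresenceGrid:
    """Presence iff vote > cutoff, strictly; no-data cells preserved."""
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must lie in [0, 1]")
    presence = (grid.values.astype(float) > cutoff) & ~grid.nodata
    return PresenceGrid(presence, grid.cell_area, grid.nodata.copy(), grid.scenario)


def merge_models(grid_a: PresenceGrid, grid_b: PresenceGrid) -> PresenceGrid:
    """Merge two boolean presence grids into a 4-class grid.

    Per cell: 3 = co-occurring, 1 = A-only, 2 = B-only, 0 = absent.
    """
    if grid_a.values.dtype != bool or grid_b.values.dtype != bool:
        raise ValueError("merge_models expects thresholded boolean grids")
    if grid_a.values.shape != grid_b.values.shape:
        raise ValueError("grids must share shape")
    if not np.array_equal(grid_a.nodata, grid_b.nodata):
        raise ValueError("grids must share the no-data mask")
    a, b = grid_a.values, grid_b.values
    classes = np.zeros(a.shape, dtype=np.int8)
    classes[a & ~b] = CLASS_A_ONLY
    classes[~a & b] = CLASS_B_ONLY
    classes[a & b] = CLASS_BOTH
    return PresenceGrid(classes, grid_a.cell_area, grid_a.nodata.copy(), grid_a.scenario)


def area_summary(class_grid: PresenceGrid, labels: tuple[str, str] = ("a_only", "b_only")) -> AreaSummary:
    """Class areas from a merged class grid: cell counts x cell area."""
    v = class_grid.values
    ok = ~class_grid.nodata
    ca = class_grid.cell_area
    a_only = float((ok & (v == CLASS_A_ONLY)).sum() * ca)
    b_only = float((ok & (v == CLASS_B_ONLY)).sum() * ca)
    both = float((ok & (v == CLASS_BOTH)).sum() * ca)
    areas = {
        labels[0]: a_only,
        labels[1]: b_only,
        "co_occurring": both,
        "total": a_only + b_only + both,
    }
    return AreaSummary(areas, class_grid.scenario)


def percent_loss(area_reference: float, area_scenario: float) -> float:
    """Percent habitat loss versus the reference, half-up to 2 decimals.

    Negative values indicate gain.
    """
    if area_reference <= 0:
        raise ValueError("reference area must be positive")
    pct = 100.0 * (area_reference - area_scenario) / area_reference
    return float(Decimal(repr(pct)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def overlap_share_percent(co_occurring: float, total: float) -> int:
    """Co-occurring share of the total suitable range, nearest whole percent."""
    if total <= 0:
        raise ValueError("total area must be positive")
    return int(
        Decimal(repr(100.0 * co_occurring / total)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )


def scenario_loss_table(
    summaries: dict[str, AreaSummary], reference: str = "contemporary"
) -> pd.DataFrame:
    """Area table across scenarios with percent loss versus the reference."""
    if reference not in summaries:
        raise ValueError(f"reference scenario {reference!r} missing")
    ref = summaries[reference]
    rows = []
    for cls in ref.areas:
        row: dict[str, object] = {"class": cls, reference: ref.areas[cls]}
        for name, summ in summaries.items():
            if name == reference:
                continue
            row[name] = summ.areas[cls]
            row[f"loss_{name}"] = percent_loss(ref.areas[cls], summ.areas[cls])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (6-line header + whitespace-separated rows)

def write_ascii_grid(grid: PresenceGrid, path: str, nodata_value: float = -9999.0) -> None:
    vals = grid.values.astype(float).copy()
    vals[grid.nodata] = nodata_value
    rows, cols = vals.shape
    cellsize = float(np.sqrt(grid.cell_area))
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cellsize}\n")
        fh.write(f"NODATA_value {nodata_value}\n")
        for r in range(rows):
            fh.write(" ".join(f"{x:g}" for x in vals[r]) + "\n")


def read_ascii_grid(path: str, scenario: str = "contemporary") -> PresenceGrid:
    header: dict[str, float] = {}
    data_rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
            else:
                data_rows.append([float(x) for x in parts])
    vals = np.array(data_rows)
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid body does not match header dimensions")
    nodata_value = header.get("nodata_value", -9999.0)
    nodata = vals == nodata_value
    vals = np.where(nodata, 0.0, vals)
    cellsize = header.get("cellsize", 1.0)
    return PresenceGrid(vals, cellsize**2, nodata, scenario)
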