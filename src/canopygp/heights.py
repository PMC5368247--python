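"""Per-plot canopy height extraction from DSM pairs.

Plant height above ground is obtained by differencing two digital surface
models — a canopy-date DSM and a bare-ground DSM taken early in the season —
and summarising the central block of each plot window by upper percentiles
(50th/75th/90th/99th by default).  The central block keeps the statistic away
from plot margins, where the surface model is contaminated by neighbouring
plots.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .geometry import PixelWindow, central_block, plot_window
from .layout import FieldLayout
from .raster import Raster, RasterAlignmentError

__all__ = [
    "DEFAULT_PERCENTILES",
    "difference_dsm",
    "plot_percentile_height",
    "extract_plot_heights",
    "write_height_table",
    "read_height_table",
]

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILES = (50, 75, 90, 99)

#: HeightTable column schema: one row per (plot, source[, percentile]).
HEIGHT_COLUMNS = ["plot_id", "source", "percentile", "height_m"]


def difference_dsm(canopy: Raster, ground: Raster) -> Raster:
    """Per-pixel canopy-minus-ground height raster.

    Both rasters must share shape, resolution and origin.  A pixel is masked
    in the output iff it is masked in either input.  Negative differences are
    retained — they are real features of noisy ground models and clamping
    them would bias low percentiles upward.
    """
    if not canopy.same_grid(ground):
        raise RasterAlignmentError(
            "canopy and ground rasters are not on the same grid: "
            f"canopy [{canopy.geometry_summary()}] vs ground [{ground.geometry_summary()}]"
        )
    mask = canopy.mask & ground.mask
    values = np.where(mask, canopy.values - ground.values, np.nan)
    return Raster(values, resolution=canopy.resolution, origin=canopy.origin, mask=mask)


def plot_percentile_height(height: Raster, block: PixelWindow, p: float) -> float:
    """Percentile *p* of the unmasked pixels in *block* of the height raster.

    Uses linear interpolation between order statistics: with sorted values
    v(0..n-1), rank h = (n-1) p/100 and the result interpolates between
    v(floor h) and v(floor h + 1).  Returns NaN for a fully masked block.
    """
    if not 0 <= p <= 100:
        raise ValueError(f"percentile must be in [0, 100], got {p}")
    sub_vals = height.values[block.row_start : block.row_stop, block.col_start : block.col_stop]
    sub_mask = height.mask[block.row_start : block.row_stop, block.col_start : block.col_stop]
    if sub_vals.shape != block.shape:
        raise IndexError(f"block {block} extends outside raster {height.geometry_summary()}")
    vals = sub_vals[sub_mask]
    if vals.size == 0:
        return float("nan")
    return float(np.percentile(vals, p, method="linear"))


def extract_plot_heights(
    canopy: Raster,
    ground: Raster,
    layout: FieldLayout,
    percentiles: Iterable[float] = DEFAULT_PERCENTILES,
    *,
    min_valid_fraction: float = 0.5,
    clamp_negative: bool = False,
) -> pd.DataFrame:
    """Batch driver: central-block percentile heights for every plot.

    Returns a height table with one ``source='UAV'`` row per
    (plot, percentile).  Plots whose central block has fewer than
    *min_valid_fraction* unmasked pixels get NaN heights and a warning.
    Raises with plot context if a plot rectangle falls outside the rasters.
    """
    percentiles = sorted(set(float(p) for p in percentiles))
    diff = difference_dsm(canopy, ground)
    if clamp_negative:
        diff = Raster(
            np.where(diff.mask, np.clip(diff.values, 0.0, None), np.nan),
            resolution=diff.resolution,
            origin=diff.origin,
            mask=diff.mask,
        )
    rows = []
    for plot in layout:
        window = plot_window(plot.rect, diff, plot_id=plot.plot_id)
        block = central_block(window)
        sub_mask = diff.mask[block.row_start : block.row_stop, block.col_start : block.col_stop]
        valid_frac = float(sub_mask.mean())
        usable = valid_frac >= min_valid_fraction and sub_mask.any()
        if not usable:
            logger.warning(
                "plot %s: only %.0f%% of central-block pixels valid; height set missing",
                plot.plot_id,
                100 * valid_frac,
            )
        for p in percentiles:
            value = plot_percentile_height(diff, block, p) if usable else float("nan")
            rows.append((plot.plot_id, "UAV", p, value))
    return pd.DataFrame(rows, columns=HEIGHT_COLUMNS)


def write_height_table(table: pd.DataFrame, path: str | Path, *, header_comment: str | None = None) -> None:
    """Write a height table as CSV, optionally with a provenance comment line."""
    _check_height_table(table)
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_csv(fh, index=False)


def read_height_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"plot_id": str, "source": str})
    _check_height_table(df)
    return df


def _check_height_table(df: pd.DataFrame) -> None:
    missing = [c for c in HEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"height table missing column(s): {missing}")
    dup = df.duplicated(subset=["plot_id", "source", "percentile"])
    if dup.any():
        raise ValueError("height table has duplicate (plot_id, source, percentile) rows")
    uav = df["source"] == "UAV"
    if uav.any() and df.loc[uav, "percentile"].isna().any():
        raise ValueError("UAV rows must carry a percentile")
    if (~uav).any() and df.loc[~uav, "percentile"].notna().any():
        raise ValueError("ruler rows must not carry a percentile")
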