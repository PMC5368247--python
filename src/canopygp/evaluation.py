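"""Accuracy metrics and field diagnostics for UAV-vs-ruler plant heights.

Three groups of tools live here:

* plain metrics — Pearson correlation and root mean square difference (RMSD)
  between paired UAV and ruler heights;
* the replicate-selection rule — per accession and treatment, keep the
  replication with the lower (or higher, or the mean) UAV height; the paired
  ruler height follows the chosen replication.  Because overlap from taller
  neighbouring plots inflates UAV heights one-sidedly, the lower replicate is
  typically the less contaminated one;
* the adjacency-overlap diagnostic — per plot, r1 = tallest-neighbour ruler
  height over own ruler height (8-neighbourhood) and r2 = own UAV height over
  own ruler height.  Plots with r1 well above 1 sit next to much taller
  material and tend to show inflated r2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import FieldLayout

__all__ = [
    "pearson_r",
    "rmsd",
    "select_replicates",
    "adjacency_ratios",
    "compare_dependent_correlations",
]

logger = logging.getLogger(__name__)

REPLICATE_MODES = ("lower", "higher", "mean")


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"expected equal-length 1-D vectors, got {x.shape} and {y.shape}")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson_r(x, y) -> float:
    """Sample Pearson correlation of two paired vectors.

    Missing values are removed pairwise.  At least 3 complete pairs and
    nonzero variance in both vectors are required; a degenerate input raises
    rather than returning a silent 0.
    """
    x, y = _paired(x, y)
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs for a correlation, got {x.size}")
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined: zero variance in an input vector")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def rmsd(ph_uav, ph_r) -> float:
    """Root mean square difference sqrt(mean((PH_UAV - PH_R)^2)), in metres."""
    x = np.asarray(ph_uav, dtype=float)
    y = np.asarray(ph_r, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError(f"expected equal-length non-empty vectors, got {x.shape} and {y.shape}")
    keep = np.isfinite(x) & np.isfinite(y)
    if not keep.any():
        raise ValueError("no complete pairs")
    d = x[keep] - y[keep]
    return float(np.sqrt(np.mean(d * d)))


def _plot_level_table(height_table: pd.DataFrame, percentile: float) -> pd.DataFrame:
    """Wide per-plot table with columns ph_uav (at *percentile*) and ph_r."""
    uav = height_table[
        (height_table["source"] == "UAV") & (height_table["percentile"] == percentile)
    ][["plot_id", "height_m"]].rename(columns={"height_m": "ph_uav"})
    ruler = height_table[height_table["source"] == "ruler"][["plot_id", "height_m"]].rename(
        columns={"height_m": "ph_r"}
    )
    return uav.merge(ruler, on="plot_id", how="outer")


def select_replicates(
    height_table: pd.DataFrame,
    layout: FieldLayout,
    mode: str = "lower",
    percentile: float = 50,
) -> pd.DataFrame:
    """Collapse the two replications per accession x treatment into one value.

    mode='lower' keeps the replication with the lower UAV height (ties go to
    replication 1), 'higher' the other, 'mean' averages both.  The paired
    ruler height always follows the same replication (or is averaged).

    Returns a frame with columns accession_id, treatment, mode,
    selected_replication (NaN for mean), ph_uav, ph_r.  Accessions without
    exactly two complete replications in a treatment are dropped with a
    warning.
    """
    if mode not in REPLICATE_MODES:
        raise ValueError(f"mode must be one of {REPLICATE_MODES}, got {mode!r}")
    plot_heights = _plot_level_table(height_table, percentile)
    meta = layout.to_frame()[["plot_id", "accession_id", "treatment", "replication"]]
    df = meta.merge(plot_heights, on="plot_id", how="left")
    out = []
    for (acc, trt), grp in df.groupby(["accession_id", "treatment"], sort=True):
        grp = grp.dropna(subset=["ph_uav", "ph_r"]).sort_values("replication")
        if len(grp) != 2:
            logger.warning(
                "accession %s / treatment %s: %d complete replication(s), expected 2; dropped",
                acc,
                trt,
                len(grp),
            )
            continue
        u = grp["ph_uav"].to_numpy()
        r = grp["ph_r"].to_numpy()
        reps = grp["replication"].to_numpy()
        if mode == "mean":
            out.append((acc, trt, mode, np.nan, u.mean(), r.mean()))
        else:
            # ties select the first (lowest replication number) entry
            if mode == "lower":
                idx = 0 if u[0] <= u[1] else 1
            else:
                idx = 0 if u[0] >= u[1] else 1
            out.append((acc, trt, mode, int(reps[idx]), float(u[idx]), float(r[idx])))
    return pd.DataFrame(
        out,
        columns=["accession_id", "treatment", "mode", "selected_replication", "ph_uav", "ph_r"],
    )


def adjacency_ratios(
    layout: FieldLayout,
    height_table: pd.DataFrame,
    percentile: float = 50,
) -> pd.DataFrame:
    """Per-plot overlap diagnostic ratios.

    r1 = max ruler height among the (up to 8) grid neighbours / own ruler
    height; r2 = own UAV height / own ruler height.  Border plots use the
    neighbours they have; a plot with no neighbour, or no neighbour with a
    ruler height, gets NaN r1 and is flagged in the log.
    """
    plot_heights = _plot_level_table(height_table, percentile).set_index("plot_id")
    rows = []
    for plot in layout:
        own = plot_heights["ph_r"].get(plot.plot_id, np.nan)
        own_uav = plot_heights["ph_uav"].get(plot.plot_id, np.nan)
        nbrs = layout.neighbors(plot.plot_id)
        nbr_heights = [
            plot_heights["ph_r"].get(q.plot_id, np.nan) for q in nbrs
        ]
        nbr_heights = [h for h in nbr_heights if np.isfinite(h)]
        if not nbr_heights or not np.isfinite(own) or own <= 0:
            logger.warning("plot %s: adjacency ratio r1 undefined", plot.plot_id)
            r1 = np.nan
        else:
            r1 = max(nbr_heights) / own
        r2 = own_uav / own if np.isfinite(own) and own > 0 else np.nan
        rows.append((plot.plot_id, r1, r2, len(nbr_heights)))
    return pd.DataFrame(rows, columns=["plot_id", "r1", "r2", "n_neighbors"])


def compare_dependent_correlations(
    x1,
    x2,
    y,
    n_boot: int = 10_000,
    seed: int | None = None,
    max_retries: int = 100,
) -> float:
    """One-sided paired-bootstrap p-value for H1: corr(x1, y) > corr(x2, y).

    All three vectors are observed on the same units, so the two
    correlations are dependent; a paired bootstrap over units resamples the
    correlation difference directly.  The p-value is the bootstrap
    probability that the difference is <= 0 (ties at exactly 0 count half),
    so swapping x1 and x2 maps p to 1 - p.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (x1.shape == x2.shape == y.shape) or x1.ndim != 1:
        raise ValueError("x1, x2, y must be equal-length 1-D vectors")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000 for a stable tail estimate")
    n = x1.size
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(max_retries):
            idx = rng.integers(0, n, size=n)
            xb1, xb2, yb = x1[idx], x2[idx], y[idx]
            if xb1.std() > 0 and xb2.std() > 0 and yb.std() > 0:
                break
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        diffs[b] = pearson_r(xb1, yb) - pearson_r(xb2, yb)
    return float(np.mean(diffs < 0) + 0.5 * np.mean(diffs == 0))
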