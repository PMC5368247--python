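"""Synthetic field trial, genome and DSM scene generator.

The undeposited field experiment this package analyses is emulated end to
end: a germplasm panel with an additive genetic architecture, a replicated
two-treatment field layout (172 accessions x 2 fertilization levels x 2
replications = 688 plots of 5 plants by default), a bare-ground surface
model, a canopy surface model in which each plant is a radially decaying
crown whose footprint grows with plant height (so tall plants overhang
neighbouring plots — the contamination mechanism the diagnostics target),
and a 2-plants-per-plot ruler campaign.

Every operation is a pure function of (config, seed): randomness flows
through named child streams of a single ``numpy`` seed sequence.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .layout import FieldLayout, PlotRecord
from .raster import Raster

__all__ = [
    "SimulationConfig",
    "CAMERA_PROFILES",
    "SceneTruth",
    "SimulatedExperiment",
    "simulate_genotypes",
    "simulate_phenotypes",
    "build_layout",
    "render_scene",
    "simulate_ruler",
    "simulate_experiment",
]

#: DSM noise presets (m).  The two cameras of the original campaign differ
#: here only through their height-error level; the near-infrared unit
#: produced the cleaner surface model.
CAMERA_PROFILES = {"nirgb": 0.05, "rgb": 0.09}

_STREAMS = {
    "genotypes": 0,
    "effects": 1,
    "layout": 2,
    "environment": 3,
    "scene": 4,
    "ruler": 5,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the simulated experiment, with field-realistic defaults.

    Lengths in metres.  The default geometry reproduces the reference trial:
    5 plants per plot at 0.3 m spacing in 0.72 m x 1.8 m plots, 13 mm/px
    rasters, 172 accessions of which 151 are genotyped.
    """

    seed: int = 0
    n_accessions: int = 172
    n_genotyped: int = 151
    n_markers: int = 2000
    n_qtl: int = 100
    n_subpopulations: int = 8
    fst: float = 0.3
    h2: float = 0.5
    mean_height_m: float = 2.0
    genetic_sd_m: float = 0.5
    low_fertilization_factor: float = 0.8
    plants_per_plot: int = 5
    plant_spacing_m: float = 0.3
    row_spacing_m: float = 0.72
    plot_width_m: float = 0.72
    plot_length_m: float = 1.8
    resolution_m: float = 0.013
    canopy_cover: float = 0.75
    spill_coefficient: float = 0.35
    dsm_noise_sd_m: float = CAMERA_PROFILES["nirgb"]
    ruler_noise_sd_m: float = 0.02
    plants_sampled_for_ruler: int = 2
    plant_noise_sd_m: float = 0.08
    field_margin_m: float = 1.0
    min_height_m: float = 0.2
    treatments: tuple[str, ...] = ("normal", "low")
    n_replications: int = 2

    def __post_init__(self) -> None:
        positive = [
            "n_accessions", "n_markers", "plants_per_plot", "plant_spacing_m",
            "row_spacing_m", "plot_width_m", "plot_length_m", "resolution_m",
            "mean_height_m", "n_replications",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"SimulationConfig.{name} must be positive")
        if not 0 < self.h2 < 1:
            raise ValueError(f"h2 must be in (0, 1), got {self.h2}")
        if not 0 < self.canopy_cover <= 1:
            raise ValueError(f"canopy_cover must be in (0, 1], got {self.canopy_cover}")
        if self.spill_coefficient < 0:
            raise ValueError("spill_coefficient must be >= 0")
        if not 0 < self.low_fertilization_factor <= 1:
            raise ValueError("low_fertilization_factor must be in (0, 1]")
        if self.plants_sampled_for_ruler > self.plants_per_plot:
            raise ValueError(
                f"cannot sample {self.plants_sampled_for_ruler} of "
                f"{self.plants_per_plot} plants for ruler measurement"
            )
        if not 0 < self.n_genotyped <= self.n_accessions:
            raise ValueError("n_genotyped must be in (0, n_accessions]")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if not 0 <= self.fst < 1:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if self.n_subpopulations < 1:
            raise ValueError("n_subpopulations must be >= 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Named deterministic child stream of the config seed."""
        child = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))[_STREAMS[stream]]
        return np.random.default_rng(child)

    def accession_ids(self) -> list[str]:
        return [f"ACC{i:03d}" for i in range(1, self.n_accessions + 1)]

    def genotyped_ids(self) -> list[str]:
        """The genotyped subset: a seeded draw of n_genotyped accessions."""
        rng = self.rng("genotypes")
        ids = self.accession_ids()
        chosen = rng.choice(self.n_accessions, size=self.n_genotyped, replace=False)
        return [ids[i] for i in sorted(chosen)]

    def crown_base_radius(self) -> float:
        """Crown footprint radius at zero spill.

        Chosen so the crown footprints of a plot's plants tile the plot area
        when they do not overlap; sparseness is modelled separately by
        per-pixel canopy dropout (``canopy_cover``), not by shrinking crowns.
        """
        plot_area = self.plot_width_m * self.plot_length_m
        return math.sqrt(plot_area / (self.plants_per_plot * math.pi))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["treatments"] = list(self.treatments)
        return d


@dataclass
class SceneTruth:
    """Generator-side ground truth for recovery tests.

    ``plants`` has one row per plant (plot_id, plant_index, x_m, y_m,
    height_m); ``plots`` one row per plot with the true max/mean plant
    height and ``block_max_m``, the analytic noise-free maximum of the
    rendered surface over the plot's central block considering the plot's
    own plants only.
    """

    plants: pd.DataFrame
    plots: pd.DataFrame
    genetic_values: pd.Series


@dataclass
class SimulatedExperiment:
    """Bundle of everything one simulated campaign produces."""

    config: SimulationConfig
    layout: FieldLayout
    genotypes: GenotypeMatrix
    truth: SceneTruth
    ground: Raster
    canopy: Raster
    ruler: pd.DataFrame


# ---------------------------------------------------------------------------
# genotypes and genetic architecture

def _simulate_panel_dosages(config: SimulationConfig) -> np.ndarray:
    """Dosages for the full phenotyped panel (genotyped subset is a view)."""
    rng = config.rng("genotypes")
    # consume the subset draw first so panel dosages and subset choice share
    # one stream deterministically
    rng.choice(config.n_accessions, size=config.n_genotyped, replace=False)
    freqs = rng.uniform(0.05, 0.5, size=config.n_markers)
    if config.fst > 0 and config.n_subpopulations > 1:
        # Balding-Nichols: subpopulation frequencies drift around the
        # ancestral frequency with divergence Fst
        shape = (1 - config.fst) / config.fst
        sub_freqs = rng.beta(
            freqs * shape, (1 - freqs) * shape, size=(config.n_subpopulations, config.n_markers)
        )
        assignment = rng.permuted(
            np.arange(config.n_accessions) % config.n_subpopulations
        )
        p_acc = sub_freqs[assignment]
    else:
        p_acc = np.broadcast_to(freqs, (config.n_accessions, config.n_markers))
    return rng.binomial(2, p_acc).astype(float)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """0/1/2 dosage matrix for the genotyped subset of the panel.

    Ancestral alternate-allele frequencies are uniform on (0.05, 0.5).  The
    panel carries population structure in the Balding-Nichols sense: each
    accession belongs to one of ``n_subpopulations`` groups whose marker
    frequencies have drifted from the ancestral value with divergence
    ``fst`` (germplasm core collections are strongly structured, and that
    structure is what gives genomic prediction its accuracy at panel sizes
    of a few hundred).  ``fst=0`` recovers an unstructured panel in linkage
    equilibrium.  Dosages are binomial(2, p) per accession and marker.
    """
    dosages = _simulate_panel_dosages(config)
    ids = config.accession_ids()
    marker_ids = [f"M{j:05d}" for j in range(1, config.n_markers + 1)]
    full = GenotypeMatrix(ids, marker_ids, dosages)
    return full.subset(config.genotyped_ids())


def _genetic_values(config: SimulationConfig) -> pd.Series:
    """Additive genetic values (m) for all accessions, sd = genetic_sd_m."""
    dosages = _simulate_panel_dosages(config)
    rng = config.rng("effects")
    qtl = rng.choice(config.n_markers, size=config.n_qtl, replace=False)
    effects = rng.normal(size=config.n_qtl)
    g = (dosages[:, qtl] - dosages[:, qtl].mean(axis=0)) @ effects
    sd = g.std()
    if sd > 0:
        g = g * (config.genetic_sd_m / sd)
    return pd.Series(g, index=config.accession_ids())


def simulate_phenotypes(
    genotypes: GenotypeMatrix,  # noqa: ARG001 - panel regenerated from config for the full 172
    layout: FieldLayout,
    config: SimulationConfig,
) -> tuple[pd.Series, pd.DataFrame]:
    """Genetic values per accession and true heights/positions per plant.

    Plant height is additive: mean_height x treatment factor + genetic value
    + plot effect + within-plot plant noise, truncated below at
    ``min_height_m``.  The plot-effect variance is chosen so that the
    plot-mean phenotype has heritability ``h2`` within a treatment:
    sigma_env^2 = sigma_g^2 (1 - h2) / h2, with the within-plot noise
    contribution (sigma_plant^2 / n_plants) counted against it.
    """
    g = _genetic_values(config)
    var_env = config.genetic_sd_m**2 * (1 - config.h2) / config.h2
    var_plant_mean = config.plant_noise_sd_m**2 / config.plants_per_plot
    plot_sd = math.sqrt(max(var_env - var_plant_mean, 1e-12))
    rng = config.rng("environment")
    rows = []
    for plot in layout:
        factor = 1.0 if plot.treatment == "normal" else config.low_fertilization_factor
        base = config.mean_height_m * factor + g[plot.accession_id]
        plot_effect = rng.normal(0.0, plot_sd)
        for k in range(config.plants_per_plot):
            x, y = _plant_position(plot, k, config)
            h = base + plot_effect + rng.normal(0.0, config.plant_noise_sd_m)
            rows.append((plot.plot_id, k, x, y, max(h, config.min_height_m)))
    plants = pd.DataFrame(rows, columns=["plot_id", "plant_index", "x_m", "y_m", "height_m"])
    return g, plants


def _plant_position(plot: PlotRecord, k: int, config: SimulationConfig) -> tuple[float, float]:
    """Field coordinates of plant *k*: single row along the plot's long axis."""
    x = plot.x_m + plot.width_m / 2
    row_extent = (config.plants_per_plot - 1) * config.plant_spacing_m
    lead = (plot.height_m - row_extent) / 2
    y = plot.y_m - lead - k * config.plant_spacing_m
    return x, y


# ---------------------------------------------------------------------------
# layout

def _block_shape(n: int) -> tuple[int, int]:
    """Rows x cols for one treatment-replication block of n plots.

    Prefers an exact divisor of n close to sqrt(n); otherwise a ragged
    near-square grid whose last row is only partially filled (e.g. 172 ->
    13 rows x 14 cols with 10 trailing cells empty, leaving alley-like gaps
    between stacked blocks).
    """
    target = math.sqrt(n)
    divisors = [d for d in range(1, n + 1) if n % d == 0]
    cols = min((d for d in divisors if d >= target), default=None)
    if cols is not None and cols <= 1.5 * target:
        return n // cols, cols
    cols = math.ceil(target)
    return math.ceil(n / cols), cols


def build_layout(config: SimulationConfig) -> FieldLayout:
    """Replicated two-treatment field layout on one contiguous grid.

    Each treatment x replication forms a block of all accessions in an
    independently randomized (seeded) order; blocks are stacked north to
    south.  With defaults: 4 blocks of 4 x 43 plots = 688 plots on a
    16 x 43 grid.
    """
    rng = config.rng("layout")
    ids = config.accession_ids()
    block_rows, block_cols = _block_shape(config.n_accessions)
    n_blocks = len(config.treatments) * config.n_replications
    total_rows = block_rows * n_blocks
    field_top = total_rows * config.plot_length_m
    plots = []
    block = 0
    for treatment in config.treatments:
        for rep in range(1, config.n_replications + 1):
            order = rng.permutation(config.n_accessions)
            for slot, acc_idx in enumerate(order):
                grid_row = block * block_rows + slot // block_cols
                grid_col = slot % block_cols
                plots.append(
                    PlotRecord(
                        plot_id=f"P{len(plots) + 1:04d}",
                        accession_id=ids[acc_idx],
                        treatment=treatment,
                        replication=rep,
                        grid_row=grid_row,
                        grid_col=grid_col,
                        x_m=grid_col * config.plot_width_m,
                        y_m=field_top - grid_row * config.plot_length_m,
                        width_m=config.plot_width_m,
                        height_m=config.plot_length_m,
                    )
                )
            block += 1
    return FieldLayout(plots)


# ---------------------------------------------------------------------------
# scene rendering

def _crown_bump(
    h: float, r: float, dist: np.ndarray, plateau_fraction: float = 0.6
) -> np.ndarray:
    """Height contribution of one crown at distances *dist* from its stem.

    Flat top of the full plant height out to ``plateau_fraction * r``, then
    linear decay to zero at the footprint radius r.
    """
    r_flat = plateau_fraction * r
    out = h * np.clip((r - dist) / max(r - r_flat, 1e-9), 0.0, 1.0)
    return out


def render_scene(
    layout: FieldLayout,
    plants: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[Raster, Raster]:
    """Ground and canopy DSM rasters for the whole field.

    The ground surface is a gentle planar gradient plus independent pixel
    noise (the two flight dates get independent noise draws).  The canopy
    surface adds, per plant, a flat-topped conical crown of that plant's
    height with footprint radius ``base_radius + spill_coefficient x
    height`` — taller plants overhang farther, contaminating neighbouring
    plots' margins.  Sparse canopies reconstruct poorly in photogrammetry:
    a seeded fraction ``1 - canopy_cover`` of pixels drop through the crown
    surface to bare ground, and pixels no crown reaches show bare ground.
    """
    res = config.resolution_m
    margin = config.field_margin_m
    frame = layout.to_frame()
    x_max = float((frame["x_m"] + frame["width_m"]).max()) + margin
    y_max = float(frame["y_m"].max()) + margin
    x_min = float(frame["x_m"].min()) - margin
    y_min = float((frame["y_m"] - frame["height_m"]).min()) - margin
    ncols = math.ceil((x_max - x_min) / res)
    nrows = math.ceil((y_max - y_min) / res)
    if nrows < 3 or ncols < 3:
        raise ValueError("raster extent degenerate for this layout")
    origin = (x_min, y_max)
    rng = config.rng("scene")
    # pixel-centre coordinates
    xs = x_min + (np.arange(ncols) + 0.5) * res
    ys = y_max - (np.arange(nrows) + 0.5) * res
    # smooth terrain: a tilted plane, ~0.2 m drop across the field
    terrain = 60.0 + 0.004 * (xs[None, :] - x_min) + 0.002 * (y_max - ys[:, None])
    ground_vals = terrain + rng.normal(0.0, config.dsm_noise_sd_m, size=(nrows, ncols))

    surface = np.zeros((nrows, ncols))
    base_r = config.crown_base_radius()
    for px, py, h in plants[["x_m", "y_m", "height_m"]].itertuples(index=False):
        r = base_r + config.spill_coefficient * h
        c0 = max(int((px - r - x_min) / res), 0)
        c1 = min(int((px + r - x_min) / res) + 2, ncols)
        r0 = max(int((y_max - (py + r)) / res), 0)
        r1 = min(int((y_max - (py - r)) / res) + 2, nrows)
        if c0 >= c1 or r0 >= r1:
            continue
        dist = np.hypot(xs[None, c0:c1] - px, ys[r0:r1, None] - py)
        bump = _crown_bump(h, r, dist)
        np.maximum(surface[r0:r1, c0:c1], bump, out=surface[r0:r1, c0:c1])
    if config.canopy_cover < 1:
        dropout = rng.random((nrows, ncols)) >= config.canopy_cover
        surface[dropout] = 0.0
    canopy_vals = terrain + surface + rng.normal(0.0, config.dsm_noise_sd_m, size=(nrows, ncols))

    ground = Raster(ground_vals, resolution=res, origin=origin)
    canopy = Raster(canopy_vals, resolution=res, origin=origin)
    return ground, canopy


def _block_rect(plot: PlotRecord) -> tuple[float, float, float, float]:
    """Field rectangle of the central third of a plot (x0, x1, y0, y1)."""
    bx0 = plot.x_m + plot.width_m / 3
    bx1 = plot.x_m + 2 * plot.width_m / 3
    by1 = plot.y_m - plot.height_m / 3
    by0 = plot.y_m - 2 * plot.height_m / 3
    return bx0, bx1, by0, by1


def _truth_tables(
    layout: FieldLayout, plants: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Per-plot true heights plus the analytic central-block surface maximum."""
    base_r = config.crown_base_radius()
    rows = []
    for plot in layout:
        sub = plants[plants["plot_id"] == plot.plot_id]
        bx0, bx1, by0, by1 = _block_rect(plot)
        block_max = 0.0
        for px, py, h in sub[["x_m", "y_m", "height_m"]].itertuples(index=False):
            dx = max(bx0 - px, 0.0, px - bx1)
            dy = max(by0 - py, 0.0, py - by1)
            dist = math.hypot(dx, dy)
            r = base_r + config.spill_coefficient * h
            block_max = max(block_max, float(_crown_bump(h, r, np.asarray(dist))))
        rows.append(
            (
                plot.plot_id,
                float(sub["height_m"].max()),
                float(sub["height_m"].mean()),
                block_max,
            )
        )
    return pd.DataFrame(rows, columns=["plot_id", "max_height_m", "mean_height_m", "block_max_m"])


# ---------------------------------------------------------------------------
# ruler campaign

def simulate_ruler(
    plants: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ruler measurements: sample plants per plot, add noise, average.

    Returns ``(height_table, plant_measurements)``: the first has one
    ``source='ruler'`` row per plot (the plot value is the mean of the
    sampled plants), the second one row per measured plant.
    """
    rng = config.rng("ruler")
    k = config.plants_sampled_for_ruler
    meas_rows = []
    plot_rows = []
    for plot_id, sub in plants.groupby("plot_id", sort=True):
        chosen = rng.choice(len(sub), size=k, replace=False)
        heights = sub["height_m"].to_numpy()[chosen] + rng.normal(0.0, config.ruler_noise_sd_m, k)
        for idx, h in zip(sub["plant_index"].to_numpy()[chosen], heights):
            meas_rows.append((plot_id, int(idx), float(h)))
        plot_rows.append((plot_id, "ruler", np.nan, float(heights.mean())))
    table = pd.DataFrame(plot_rows, columns=["plot_id", "source", "percentile", "height_m"])
    measurements = pd.DataFrame(meas_rows, columns=["plot_id", "plant_index", "height_m"])
    return table, measurements


# ---------------------------------------------------------------------------
# one-call campaign

def simulate_experiment(config: SimulationConfig | None = None, **overrides) -> SimulatedExperiment:
    """Run the whole generator: layout, genome, scene, ruler campaign."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    layout = build_layout(config)
    genotypes = simulate_genotypes(config)
    g, plants = simulate_phenotypes(genotypes, layout, config)
    ground, canopy = render_scene(layout, plants, config)
    ruler, _ = simulate_ruler(plants, config)
    truth = SceneTruth(plants=plants, plots=_truth_tables(layout, plants, config), genetic_values=g)
    return SimulatedExperiment(
        config=config,
        layout=layout,
        genotypes=genotypes,
        truth=truth,
        ground=ground,
        canopy=canopy,
        ruler=ruler,
    )
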