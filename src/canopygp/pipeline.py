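"""Stage orchestration: simulate / extract / evaluate / predict with file I/O.

Each stage reads and writes plain files (CSV, ASCII-grid or TIFF rasters,
VCF, YAML) so stages can be re-run independently or driven from the CLI.
Every CSV a stage writes starts with a provenance comment carrying the
package version, the seed and a hash of the resolved configuration; two runs
with identical configs produce identical files.  A stage that fails moves
whatever it had already written into a ``quarantine/`` subdirectory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    REPLICATE_MODES,
    adjacency_ratios,
    compare_dependent_correlations,
    pearson_r,
    rmsd,
    select_replicates,
)
from .gblup import genomic_relationship_matrix, loocv
from .genotypes import read_genotypes, write_vcf
from .heights import DEFAULT_PERCENTILES, extract_plot_heights, read_height_table, write_height_table
from .layout import FieldLayout
from .raster import read_raster, write_raster
from .simulate import SimulationConfig, simulate_experiment

__all__ = ["RunConfig", "run_simulate", "run_extract", "run_evaluate", "run_predict", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run."""

    outdir: Path = Path("canopygp_run")
    seed: int = 0
    ground_path: Path | None = None
    canopy_path: Path | None = None
    layout_path: Path | None = None
    genotypes_path: Path | None = None
    heights_path: Path | None = None
    ruler_path: Path | None = None
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES
    replicate_mode: str = "lower"
    eval_percentile: float = 50
    n_boot: int = 10_000
    min_maf: float = 0.01
    raster_format: str = "tif"
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("outdir", "ground_path", "canopy_path", "layout_path",
                    "genotypes_path", "heights_path", "ruler_path"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        if "percentiles" in raw:
            raw["percentiles"] = tuple(raw["percentiles"])
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        d["percentiles"] = list(self.percentiles)
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> str:
        return f"canopygp v{__version__} config={self.config_hash()} seed={self.seed}"

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {config.provenance()}\n")
        df.to_csv(fh, index=False)


class _Stage:
    """Context manager quarantining partial outputs on failure."""

    def __init__(self, config: RunConfig, name: str):
        self.outdir = Path(config.outdir)
        self.name = name
        self.written: list[Path] = []

    def __enter__(self) -> "_Stage":
        self.outdir.mkdir(parents=True, exist_ok=True)
        return self

    def track(self, path: Path) -> Path:
        self.written.append(path)
        return path

    def __exit__(self, exc_type, exc, tb) -> bool:
        if exc_type is not None:
            qdir = self.outdir / "quarantine"
            qdir.mkdir(exist_ok=True)
            for p in self.written:
                if p.exists():
                    p.rename(qdir / p.name)
            logger.error("stage %s failed; partial outputs moved to %s", self.name, qdir)
        return False


def run_simulate(config: RunConfig) -> dict[str, Path]:
    """Generate a synthetic campaign and write all its files."""
    with _Stage(config, "simulate") as stage:
        out = Path(config.outdir)
        sim = simulate_experiment(config.sim_config())
        suffix = "." + config.raster_format.lstrip(".")
        paths = {
            "ground": out / f"ground{suffix}",
            "canopy": out / f"canopy{suffix}",
            "layout": out / "layout.csv",
            "genotypes": out / "genotypes.vcf",
            "ruler": out / "ruler.csv",
            "truth": out / "truth.csv",
            "config": out / "config_resolved.yaml",
        }
        write_raster(sim.ground, stage.track(paths["ground"]))
        write_raster(sim.canopy, stage.track(paths["canopy"]))
        stage.track(paths["layout"])
        with open(paths["layout"], "w") as fh:
            fh.write(f"# {config.provenance()}\n")
            sim.layout.to_frame().to_csv(fh, index=False)
        write_vcf(sim.genotypes, stage.track(paths["genotypes"]))
        write_height_table(sim.ruler, stage.track(paths["ruler"]), header_comment=config.provenance())
        _write_csv(sim.truth.plots, stage.track(paths["truth"]), config)
        with open(stage.track(paths["config"]), "w") as fh:
            fh.write(f"# {config.provenance()}\n")
            yaml.safe_dump(
                {"run": config.resolved(), "simulation": sim.config.to_dict()}, fh, sort_keys=True
            )
        return paths


def _input(config: RunConfig, explicit: Path | None, default_name: str) -> Path:
    path = explicit if explicit is not None else Path(config.outdir) / default_name
    if not path.exists():
        raise FileNotFoundError(f"required input not found: {path}")
    return path


def run_extract(config: RunConfig) -> Path:
    """Extract per-plot UAV heights from the DSM pair and write heights.csv."""
    with _Stage(config, "extract") as stage:
        suffix = "." + config.raster_format.lstrip(".")
        ground = read_raster(_input(config, config.ground_path, f"ground{suffix}"))
        canopy = read_raster(_input(config, config.canopy_path, f"canopy{suffix}"))
        layout = FieldLayout.read_csv(_input(config, config.layout_path, "layout.csv"))
        table = extract_plot_heights(canopy, ground, layout, config.percentiles)
        out = stage.track(Path(config.outdir) / "heights.csv")
        write_height_table(table, out, header_comment=config.provenance())
        return out


def _combined_height_table(config: RunConfig) -> pd.DataFrame:
    uav = read_height_table(_input(config, config.heights_path, "heights.csv"))
    ruler = read_height_table(_input(config, config.ruler_path, "ruler.csv"))
    return pd.concat([uav, ruler], ignore_index=True)


def run_evaluate(config: RunConfig) -> dict[str, Path]:
    """Accuracy metrics, replicate-selection comparison, adjacency diagnostics."""
    with _Stage(config, "evaluate") as stage:
        out = Path(config.outdir)
        layout = FieldLayout.read_csv(_input(config, config.layout_path, "layout.csv"))
        table = _combined_height_table(config)

        metric_rows = []
        selections: dict[tuple[float, str], pd.DataFrame] = {}
        for p in config.percentiles:
            for mode in REPLICATE_MODES:
                sel = select_replicates(table, layout, mode=mode, percentile=p)
                if len(sel) < 3:
                    raise ValueError(
                        f"fewer than 3 complete accession pairs at percentile {p}"
                    )
                selections[(p, mode)] = sel
                metric_rows.append(
                    (
                        p,
                        mode,
                        pearson_r(sel["ph_uav"], sel["ph_r"]),
                        rmsd(sel["ph_uav"].to_numpy(), sel["ph_r"].to_numpy()),
                        len(sel),
                    )
                )
        metrics = pd.DataFrame(metric_rows, columns=["percentile", "mode", "r", "rmsd_m", "n"])

        pvals = []
        for p in config.percentiles:
            lower = selections[(p, "lower")].set_index(["accession_id", "treatment"])
            mean = selections[(p, "mean")].set_index(["accession_id", "treatment"])
            shared = lower.index.intersection(mean.index)
            pval = compare_dependent_correlations(
                lower.loc[shared, "ph_uav"],
                mean.loc[shared, "ph_uav"],
                lower.loc[shared, "ph_r"],
                n_boot=config.n_boot,
                seed=config.seed,
            )
            pvals.append((p, "lower_vs_mean", pval, len(shared)))
        pframe = pd.DataFrame(pvals, columns=["percentile", "comparison", "p_value", "n"])

        diagnostics = adjacency_ratios(layout, table, percentile=config.eval_percentile)

        paths = {
            "metrics": stage.track(out / "metrics.csv"),
            "bootstrap": stage.track(out / "replicate_comparison.csv"),
            "diagnostics": stage.track(out / "adjacency.csv"),
        }
        _write_csv(metrics, paths["metrics"], config)
        _write_csv(pframe, paths["bootstrap"], config)
        _write_csv(diagnostics, paths["diagnostics"], config)
        return paths


def run_predict(config: RunConfig) -> dict[str, Path]:
    """G-BLUP LOOCV per phenotype source and treatment; cross-source summary."""
    with _Stage(config, "predict") as stage:
        out = Path(config.outdir)
        layout = FieldLayout.read_csv(_input(config, config.layout_path, "layout.csv"))
        table = _combined_height_table(config)
        genotypes = read_genotypes(_input(config, config.genotypes_path, "genotypes.vcf"))

        sel = select_replicates(
            table, layout, mode=config.replicate_mode, percentile=config.eval_percentile
        )
        phenotyped = sorted(sel["accession_id"].unique())
        shared = [a for a in phenotyped if a in set(genotypes.accession_ids)]
        dropped = sorted(set(phenotyped) - set(shared))
        logger.info(
            "genotype-phenotype join: %d shared accessions, %d phenotyped-only dropped",
            len(shared),
            len(dropped),
        )
        grm = genomic_relationship_matrix(genotypes.subset(shared), min_maf=config.min_maf)

        pred_rows = []
        summary_rows = []
        predictions: dict[tuple[str, str], pd.Series] = {}
        for treatment, grp in sel.groupby("treatment", sort=True):
            grp = grp.set_index("accession_id").loc[[a for a in shared if a in grp["accession_id"].values]]
            for source, column in (("PH_UAV", "ph_uav"), ("PH_R", "ph_r")):
                y = grp[column].to_numpy(dtype=float)
                result = loocv(y, grm.subset(list(grp.index)))
                predictions[(treatment, source)] = result.predictions
                summary_rows.append(
                    (treatment, source, result.accuracy, len(grp), result.n_failed)
                )
                for acc in grp.index:
                    pred_rows.append(
                        (
                            acc,
                            treatment,
                            source,
                            float(result.observed[acc]),
                            float(result.predictions[acc]),
                        )
                    )
        cross_rows = []
        for treatment in sel["treatment"].unique():
            key_u, key_r = (treatment, "PH_UAV"), (treatment, "PH_R")
            if key_u in predictions and key_r in predictions:
                cross_rows.append(
                    (
                        treatment,
                        pearson_r(predictions[key_u], predictions[key_r]),
                        len(predictions[key_u]),
                    )
                )
        preds = pd.DataFrame(
            pred_rows, columns=["accession_id", "treatment", "source", "observed", "predicted"]
        )
        summary = pd.DataFrame(
            summary_rows, columns=["treatment", "source", "loocv_r", "n", "n_failed"]
        )
        cross = pd.DataFrame(cross_rows, columns=["treatment", "pred_vs_pred_r", "n"])
        join = pd.DataFrame(
            {"accession_id": dropped, "reason": "not genotyped"}
        )

        paths = {
            "predictions": stage.track(out / "predictions.csv"),
            "summary": stage.track(out / "prediction_summary.csv"),
            "cross": stage.track(out / "prediction_cross_source.csv"),
            "join": stage.track(out / "join_report.csv"),
        }
        _write_csv(preds, paths["predictions"], config)
        _write_csv(summary, paths["summary"], config)
        _write_csv(cross, paths["cross"], config)
        _write_csv(join, paths["join"], config)
        return paths


def run_all(config: RunConfig) -> dict[str, Path]:
    """simulate -> extract -> evaluate -> predict in one call."""
    paths = dict(run_simulate(config))
    paths["heights"] = run_extract(config)
    paths.update(run_evaluate(config))
    paths.update(run_predict(config))
    return paths
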