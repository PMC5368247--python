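"""Field plot layout: plot records, grid adjacency, and CSV round-tripping.

A trial layout is a rectangular grid of plots.  Each plot carries the
accession grown in it, the fertilization treatment, the replication number,
its grid position and its field-coordinate rectangle (north-west corner plus
extents, metres).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["PlotRecord", "FieldLayout", "LAYOUT_COLUMNS"]

LAYOUT_COLUMNS = [
    "plot_id",
    "accession_id",
    "treatment",
    "replication",
    "grid_row",
    "grid_col",
    "x_m",
    "y_m",
    "width_m",
    "height_m",
]


@dataclass(frozen=True)
class PlotRecord:
    plot_id: str
    accession_id: str
    treatment: str
    replication: int
    grid_row: int
    grid_col: int
    x_m: float
    y_m: float
    width_m: float
    height_m: float

    @property
    def rect(self) -> tuple[float, float, float, float]:
        return (self.x_m, self.y_m, self.width_m, self.height_m)


class FieldLayout:
    """An immutable collection of :class:`PlotRecord` with grid lookups."""

    def __init__(self, plots: list[PlotRecord] | pd.DataFrame):
        if isinstance(plots, pd.DataFrame):
            missing = [c for c in LAYOUT_COLUMNS if c not in plots.columns]
            if missing:
                raise ValueError(f"layout table missing required column(s): {missing}")
            plots = [
                PlotRecord(
                    plot_id=str(r.plot_id),
                    accession_id=str(r.accession_id),
                    treatment=str(r.treatment),
                    replication=int(r.replication),
                    grid_row=int(r.grid_row),
                    grid_col=int(r.grid_col),
                    x_m=float(r.x_m),
                    y_m=float(r.y_m),
                    width_m=float(r.width_m),
                    height_m=float(r.height_m),
                )
                for r in plots.itertuples(index=False)
            ]
        self.plots: list[PlotRecord] = list(plots)
        if not self.plots:
            raise ValueError("layout must contain at least one plot")
        ids = [p.plot_id for p in self.plots]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate plot_id in layout")
        cells = [(p.grid_row, p.grid_col) for p in self.plots]
        if len(set(cells)) != len(cells):
            raise ValueError("duplicate (grid_row, grid_col) cell in layout")
        self._by_id = {p.plot_id: p for p in self.plots}
        self._by_cell = {(p.grid_row, p.grid_col): p for p in self.plots}

    def __len__(self) -> int:
        return len(self.plots)

    def __iter__(self):
        return iter(self.plots)

    def __getitem__(self, plot_id: str) -> PlotRecord:
        return self._by_id[plot_id]

    def neighbors(self, plot_id: str) -> list[PlotRecord]:
        """Plots in the 8-neighbourhood of *plot_id* on the grid.

        Border and corner plots simply have fewer neighbours; plots missing
        from the grid (holes) are skipped.
        """
        p = self._by_id[plot_id]
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                q = self._by_cell.get((p.grid_row + dr, p.grid_col + dc))
                if q is not None:
                    out.append(q)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.plots], columns=LAYOUT_COLUMNS)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "FieldLayout":
        df = pd.read_csv(path, comment="#")
        return cls(df)
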