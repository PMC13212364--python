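"""Publication outputs: group time-series and box plots, tables, exports.

Plot kinds mirror the figures a phenotyping analyst reads first: group-mean
trajectories over ordinal time points with a dispersion band (mean +/- standard
error), and per-time-point box comparisons. A facet formula ``row ~ col``
(``.`` for none) splits a plot into a panel grid by factor levels. Plots of
more than ``density_threshold`` measurements switch from individual points to
a density rendering to stay responsive on large experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "FacetSpec",
    "PlotSpec",
    "PlotResult",
    "parse_facet_formula",
    "subsample",
    "descriptive_table",
    "build_plot",
    "export_figure",
    "export_tables",
    "DENSITY_THRESHOLD",
]

#: Above this many plotted measurements, point rendering switches to density.
DENSITY_THRESHOLD = 2000

FIGURE_FORMATS = ("svg", "png", "pdf")


@dataclass(frozen=True)
class FacetSpec:
    row_factor: str | None = None
    col_factor: str | None = None


def parse_facet_formula(formula: str) -> FacetSpec:
    """Parse a ``row ~ col`` facet formula; ``.`` means "no facet on this axis"."""
    parts = [p.strip() for p in formula.split("~")]
    if len(parts) != 2:
        raise ValueError(f"facet formula must be 'row ~ col', got {formula!r}")
    row, col = (None if p in (".", "") else p for p in parts)
    return FacetSpec(row_factor=row, col_factor=col)


@dataclass
class PlotSpec:
    kind: str  # timeseries | box_by_timepoint
    trait: str
    group_factor: str
    selected_levels: dict = field(default_factory=dict)  # factor -> allowed levels
    facet: FacetSpec = field(default_factory=FacetSpec)
    with_outliers: bool = True
    density_threshold: int = DENSITY_THRESHOLD
    time_points: tuple | None = None  # box kind: which time points to draw

    def __post_init__(self):
        if self.kind not in ("timeseries", "box_by_timepoint"):
            raise ValueError(f"unknown plot kind {self.kind!r}")


@dataclass
class PlotResult:
    figure: object
    render_mode: str  # points | density
    n_measurements: int
    n_panels: int


def subsample(data: pd.DataFrame, filters: dict) -> pd.DataFrame:
    """Keep rows whose factor values all lie in the allowed sets.

    An empty filter map is the identity. Unknown factors raise; a filter
    matching nothing returns an empty slice with a warning.
    """
    out = data
    for factor, allowed in filters.items():
        if factor not in data.columns:
            raise KeyError(f"unknown factor {factor!r}")
        out = out[out[factor].isin(set(allowed))]
    if filters and out.empty:
        warnings.warn("subsample filters matched no rows", stacklevel=2)
    return out


def descriptive_table(
    data: pd.DataFrame,
    group_factor: str,
    time_points=None,
    response: str = "value",
) -> pd.DataFrame:
    """Descriptive statistics per (time point, group).

    Columns: n, mean, sd (n-1 denominator, unavailable for n = 1), median,
    q1, q3, min, max.
    """
    if data.empty:
        raise ValueError("cannot describe an empty slice")
    df = data
    if time_points is not None:
        df = df[df["time_point"].isin(set(time_points))]
    rows = []
    for (tp, group), g in df.groupby(["time_point", group_factor], observed=True):
        v = g[response].to_numpy(dtype=float)
        rows.append(
            {
                "time_point": tp,
                group_factor: group,
                "n": len(v),
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
                "median": float(np.median(v)),
                "q1": float(np.quantile(v, 0.25)),
                "q3": float(np.quantile(v, 0.75)),
                "min": float(np.min(v)),
                "max": float(np.max(v)),
            }
        )
    return pd.DataFrame(rows).sort_values(["time_point", group_factor]).reset_index(drop=True)


def _facet_cells(data: pd.DataFrame, facet: FacetSpec):
    rows = sorted(data[facet.row_factor].unique()) if facet.row_factor else [None]
    cols = sorted(data[facet.col_factor].unique()) if facet.col_factor else [None]
    return rows, cols


def _panel_slice(data, facet, r, c):
    out = data
    if facet.row_factor is not None:
        out = out[out[facet.row_factor] == r]
    if facet.col_factor is not None:
        out = out[out[facet.col_factor] == c]
    return out


def _draw_timeseries(ax, panel, spec):
    for level, g in panel.groupby(spec.group_factor, observed=True):
        stats = g.groupby("time_point")["value"].agg(["mean", "std", "count"])
        se = stats["std"] / np.sqrt(stats["count"])
        ax.plot(stats.index, stats["mean"], marker="o", label=str(level))
        ax.fill_between(
            stats.index,
            stats["mean"] - se.fillna(0),
            stats["mean"] + se.fillna(0),
            alpha=0.2,
        )
    ax.set_xlabel("time point")
    ax.set_ylabel(spec.trait)


def _draw_density(ax, panel, spec):
    ax.hexbin(panel["time_point"], panel["value"], gridsize=25, cmap="viridis", mincnt=1)
    for level, g in panel.groupby(spec.group_factor, observed=True):
        stats = g.groupby("time_point")["value"].mean()
        ax.plot(stats.index, stats.to_numpy(), marker="o", label=str(level))
    ax.set_xlabel("time point")
    ax.set_ylabel(spec.trait)


def _draw_box(ax, panel, spec):
    tps = sorted(panel["time_point"].unique())
    levels = sorted(panel[spec.group_factor].unique())
    width = 0.8 / max(len(levels), 1)
    for li, level in enumerate(levels):
        data = [
            panel.loc[(panel["time_point"] == tp) & (panel[spec.group_factor] == level), "value"]
            for tp in tps
        ]
        positions = [tp + (li - (len(levels) - 1) / 2) * width for tp in tps]
        ax.boxplot([d.to_numpy() for d in data], positions=positions, widths=width * 0.9)
    ax.set_xticks(tps)
    ax.set_xticklabels([str(t) for t in tps])
    ax.set_xlabel("time point")
    ax.set_ylabel(spec.trait)


def build_plot(data: pd.DataFrame, spec: PlotSpec) -> PlotResult:
    """Build the figure described by ``spec``.

    Applies level selection, the outlier toggle (annotate-mode rows with
    ``is_outlier`` set are excluded when ``with_outliers`` is False), and
    faceting. Render mode is density when the plotted measurement count
    strictly exceeds ``spec.density_threshold``, points otherwise.
    """
    df = data[data["trait"] == spec.trait] if "trait" in data.columns else data
    df = subsample(df, spec.selected_levels)
    if not spec.with_outliers and "is_outlier" in df.columns:
        df = df[~df["is_outlier"].astype(bool)]
    if spec.time_points is not None:
        df = df[df["time_point"].isin(set(spec.time_points))]
    if df.empty:
        raise ValueError("nothing to plot: the selected slice is empty")

    n = len(df)
    render_mode = "density" if n > spec.density_threshold else "points"
    row_levels, col_levels = _facet_cells(df, spec.facet)

    panels = []
    for r in row_levels:
        for c in col_levels:
            panel = _panel_slice(df, spec.facet, r, c)
            if panel.empty:
                continue
            panels.append((r, c, panel))
    nrow, ncol = len(row_levels), len(col_levels)
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False, sharey=True
    )
    drawn = 0
    for r_i, r in enumerate(row_levels):
        for c_i, c in enumerate(col_levels):
            ax = axes[r_i][c_i]
            panel = _panel_slice(df, spec.facet, r, c)
            if panel.empty:
                ax.set_visible(False)
                continue
            if spec.kind == "box_by_timepoint":
                _draw_box(ax, panel, spec)
            elif render_mode == "density":
                _draw_density(ax, panel, spec)
            else:
                _draw_timeseries(ax, panel, spec)
            title = " / ".join(str(x) for x in (r, c) if x is not None)
            if title:
                ax.set_title(title)
            drawn += 1
    handles, labels = axes[0][0].get_legend_handles_labels()
    if labels:
        fig.legend(handles, labels, loc="upper right", title=spec.group_factor)
    fig.tight_layout()
    return PlotResult(figure=fig, render_mode=render_mode, n_measurements=n, n_panels=drawn)


def export_figure(fig, path, format: str = "png", dpi: int = 300) -> Path:
    """Save a figure as SVG/PNG/PDF; raster formats at the requested dpi (default 300)."""
    if format not in FIGURE_FORMATS:
        raise ValueError(f"unsupported figure format {format!r}; use one of {FIGURE_FORMATS}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    figure = getattr(fig, "figure", fig)
    figure.savefig(path, format=format, dpi=dpi)
    return path


def export_tables(tables, path, format: str = "csv") -> list[Path]:
    """Export one or more result tables to CSV files or one XLSX workbook.

    ``tables`` is a DataFrame or a mapping of section name to DataFrame; CSV
    export writes one file per section, XLSX one sheet per section.
    """
    if isinstance(tables, pd.DataFrame):
        tables = {"results": tables}
    if not tables:
        raise ValueError("no tables to export")
    if format not in ("csv", "xlsx"):
        raise ValueError(f"unsupported table format {format!r}")
    path = Path(path)
    written = []
    if format == "xlsx":
        path.parent.mkdir(parents=True, exist_ok=True)
        with pd.ExcelWriter(path) as writer:
            for name, table in tables.items():
                table.to_excel(writer, sheet_name=str(name)[:31], index=False)
        written.append(path)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            target = path / f"{name}.csv"
            table.to_csv(target, index=False)
            written.append(target)
    return written
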