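"""Two-stage pipeline orchestration: wizard (preprocessing) and analysis.

The wizard runs load -> validate -> temporal clustering -> outlier policy ->
technical aggregation, logging row counts and wall-times per stage and
caching the processed table beside the project, keyed by a hash of the input
files and the configuration. The analysis stage runs design summary -> model
selection -> fit -> diagnostics -> post hoc -> effect sizes -> growth
summary on a processed table and writes tidy result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import preprocess, report, stats_models, temporal
from .config import RunConfig
from .errors import ProjectValidationError
from .io_project import Project, load_project

__all__ = ["WizardResult", "AnalysisRequest", "run_wizard", "run_analysis"]

log = logging.getLogger(__name__)

CACHE_DIR_NAME = ".phenostat_cache"


@dataclass
class StageRecord:
    stage: str
    rows_in: int
    rows_out: int
    seconds: float


@dataclass
class WizardResult:
    project: Project
    log: list[StageRecord]
    cache_hit: bool = False
    report: object = None

    def log_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.log])


@dataclass
class AnalysisRequest:
    """What to analyze: one trait, the factors, and optional slicing."""

    trait: str
    factors: list[str]
    filters: dict = field(default_factory=dict)
    time_points: tuple | None = None  # default: the last time point
    time_series: bool = False
    posthoc_factor: str | None = None
    with_outliers: bool = False  # include annotate-mode flagged rows in models


def _project_fingerprint(config: RunConfig) -> str:
    h = hashlib.sha256()
    project_dir = Path(config.project_dir)
    for p in sorted(project_dir.iterdir()):
        if p.is_file() and not p.name.startswith("."):
            h.update(p.name.encode())
            h.update(p.read_bytes())
    payload = {k: v for k, v in config.to_dict().items() if k != "project_dir"}
    h.update(json.dumps(payload, sort_keys=True).encode())
    return h.hexdigest()[:16]


def _cache_paths(config: RunConfig):
    cache_dir = Path(config.project_dir) / CACHE_DIR_NAME
    key = _project_fingerprint(config)
    return cache_dir / f"{key}.csv", cache_dir / f"{key}.json"


def run_wizard(config: RunConfig, use_cache: bool = True) -> WizardResult:
    """Execute the preprocessing stage described by ``config``.

    Aborts with :class:`ProjectValidationError` when loading produces
    error-severity issues. Reruns on unchanged inputs and config reuse the
    cached processed table (reported via ``cache_hit`` and a log line).
    """
    data_path, meta_path = _cache_paths(config)
    if use_cache and data_path.exists() and meta_path.exists():
        meta = json.loads(meta_path.read_text())
        measurements = pd.read_csv(data_path, parse_dates=["timestamp"])
        project = Project(
            measurements=measurements,
            meta=pd.DataFrame(meta["meta"]),
            factors=meta["factors"],
            name=meta["name"],
        )
        log.info("wizard cache hit: %s", data_path.name)
        return WizardResult(project=project, log=[], cache_hit=True)

    records = []

    def timed(stage, rows_in, fn):
        t0 = time.perf_counter()
        out = fn()
        rows_out = len(out.measurements) if isinstance(out, Project) else rows_in
        records.append(StageRecord(stage, rows_in, rows_out, time.perf_counter() - t0))
        log.info("stage %-12s rows %d -> %d (%.3fs)", stage, rows_in, records[-1].rows_out,
                 records[-1].seconds)
        return out

    t0 = time.perf_counter()
    project, validation = load_project(config.project_dir)
    records.append(
        StageRecord("load", len(project.measurements), len(project.measurements),
                    time.perf_counter() - t0)
    )
    if not validation.ok:
        raise ProjectValidationError(
            f"project failed validation with {len(validation.errors())} error(s)",
            report=validation,
        )

    project = timed("cluster", len(project.measurements),
                    lambda: temporal.assign_time_points(project, config.eps_hours))
    policy = preprocess.OutlierPolicy(
        method=config.outlier_method,
        mode=config.outlier_mode,
        iqr_k=config.iqr_k,
        z_threshold=config.z_threshold,
        cell_factors=tuple(config.cell_factors),
    )
    n_in = len(project.measurements)
    t0 = time.perf_counter()
    project, flags = preprocess.apply_outlier_policy(project, policy)
    records.append(StageRecord("outliers", n_in, len(project.measurements), time.perf_counter() - t0))
    if config.outlier_mode == "filter":
        log.info("outlier filter removed %d rows", n_in - len(project.measurements))
    project = timed("aggregate", len(project.measurements),
                    lambda: preprocess.technical_aggregate(project, config.aggregation))

    if use_cache:
        data_path.parent.mkdir(exist_ok=True)
        project.measurements.to_csv(data_path, index=False)
        meta_path.write_text(
            json.dumps(
                {
                    "meta": project.meta.to_dict(orient="list"),
                    "factors": project.factors,
                    "name": project.name,
                }
            )
        )
    return WizardResult(project=project, log=records, cache_hit=False, report=validation)


def run_analysis(
    config: RunConfig,
    project: Project,
    request: AnalysisRequest,
    out_dir=None,
) -> dict:
    """Execute the statistics stage on a wizard-processed project.

    Returns a bundle with the design summary, selected model type, model
    result (terms, effect sizes), diagnostics, post hoc table, growth
    summary, and descriptive table; writes each as a tidy CSV when
    ``out_dir`` is given.
    """
    df = project.measurements
    df = df[df["trait"] == request.trait]
    if not request.with_outliers and "is_outlier" in df.columns:
        df = df[~df["is_outlier"].astype(bool)]
    if request.filters:
        df = report.subsample(df, request.filters)
    if df.empty:
        raise ValueError(f"no measurements for trait {request.trait!r} after filtering")

    # Day offset from the first scan, for spline/time models.
    df = df.copy()
    df["day"] = (df["timestamp"] - df["timestamp"].min()) / pd.Timedelta(days=1)

    if request.time_series:
        design = stats_models.summarize_design(df, request.factors)
        model_type = stats_models.select_model(design, time_series=True, override=config.model_override)
    else:
        tps = request.time_points
        if tps is None:
            tps = (int(df["time_point"].max()),)
        slice_ = df[df["time_point"].isin(set(tps))]
        design = stats_models.summarize_design(slice_, request.factors)
        model_type = stats_models.select_model(design, time_series=False, override=config.model_override)

    if model_type == "spline":
        result = stats_models.fit_spline(df, "day", request.factors[0])
        diag_data = df
    elif model_type == "mixed":
        result = stats_models.fit_mixed(slice_, request.factors)
        diag_data = slice_
    else:
        result = stats_models.fit_anova(slice_, request.factors)
        diag_data = slice_

    diagnostics = None
    if result.fitted is not None and hasattr(result.fitted, "resid"):
        diagnostics = stats_models.diagnose(result, diag_data)

    ph_factor = request.posthoc_factor or request.factors[0]
    ph_data = diag_data if model_type != "spline" else df
    posthoc = stats_models.posthoc_tukey(ph_data, ph_factor)
    result.posthoc = posthoc

    growth = None
    if df["time_point"].nunique() >= 2:
        growth = stats_models.growth_summary(df, request.factors[0])

    desc = report.descriptive_table(df, request.factors[0])

    bundle = {
        "design": design,
        "model_type": model_type,
        "result": result,
        "diagnostics": diagnostics,
        "posthoc": posthoc,
        "effect_sizes": result.effect_sizes,
        "growth": growth,
        "descriptive": desc,
    }
    if out_dir is not None:
        tables = {"model_terms": result.terms, "posthoc": posthoc, "descriptive": desc}
        if result.effect_sizes:
            tables["effect_sizes"] = pd.DataFrame(
                sorted(result.effect_sizes.items()), columns=["term", "partial_eta_sq"]
            )
        if growth is not None:
            tables["growth_intervals"] = growth.intervals
            tables["growth_totals"] = growth.totals
        if diagnostics is not None:
            tables["diagnostics"] = pd.DataFrame(
                [{"normality_p": diagnostics.normality_p, "homogeneity_p": diagnostics.homogeneity_p}]
            )
        report.export_tables(tables, out_dir, format="csv")
    return bundle
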