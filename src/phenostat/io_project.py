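"""Read, validate, and join phenotyping project directories.

A project directory mirrors the layout produced around a HortControl-style
phenotyping platform export:

* ``*_data.zip``       — ZIP holding one CSV of raw measurements (wide format:
  one row per plant scan, one column per trait);
* ``*_handmade.csv``   — per-sample metadata: ``V.T.R`` (unique biological
  sample id), ``Treatment`` (overrides any treatment column in the raw
  export), ``Cultivar``, plus optional extra factor columns;
* ``*_translation.csv``— maps ``V.T.R`` to the spatial unit coordinate
  ``T:X:Y`` used in the raw export;
* ``groups.xlsx``      — optional cultivar-level grouping factors (mandatory
  ``Cultivar`` column).

Loading joins raw measurements to sample metadata through the translation
table and melts the trait columns into one long-format table with one row per
(plant, trait, scan).
"""

from __future__ import annotations

import re
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .errors import CoordinateParseError, ProjectLayoutError

__all__ = [
    "UnitCoord",
    "Issue",
    "ValidationReport",
    "Project",
    "parse_unit_coordinate",
    "validate_factor_names",
    "load_project",
    "write_project",
    "DEFAULT_COLUMN_MAP",
]

#: Maps canonical roles to the column names expected in the raw CSV.
#: Override when a platform export uses different headers.
DEFAULT_COLUMN_MAP = {"unit": "unit", "timestamp": "timestamp", "treatment": "treatment"}

_FACTOR_NAME_RE = re.compile(r"^[A-Za-z0-9_]+$")

MEASUREMENT_COLUMNS = ["vtr", "unit_coord", "timestamp", "trait", "value"]


@dataclass(frozen=True, order=True)
class UnitCoord:
    """Spatial position of a plant: block, row from the barcode, index in row."""

    block: int
    row: int
    index: int

    def __post_init__(self):
        for name in ("block", "row", "index"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise CoordinateParseError(
                    f"unit coordinate component {name!r} must be a positive integer, got {v!r}"
                )

    def __str__(self) -> str:
        return f"{self.block}:{self.row}:{self.index}"


def parse_unit_coordinate(s: str) -> UnitCoord:
    """Parse a ``block:row:index`` coordinate string.

    Raises :class:`CoordinateParseError` naming the offending component when
    the string has the wrong arity or a non-positive/non-integer part.
    """
    if not s or not s.strip():
        raise CoordinateParseError("unit coordinate string is empty")
    parts = s.strip().split(":")
    if len(parts) != 3:
        raise CoordinateParseError(
            f"unit coordinate {s!r} must have exactly 3 colon-separated components, got {len(parts)}"
        )
    values = []
    for name, part in zip(("block", "row", "index"), parts):
        try:
            v = int(part)
        except ValueError:
            raise CoordinateParseError(
                f"unit coordinate component {name!r} is not an integer: {part!r}"
            ) from None
        if v < 1:
            raise CoordinateParseError(
                f"unit coordinate component {name!r} must be >= 1, got {v}"
            )
        values.append(v)
    return UnitCoord(*values)


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    table: str
    location: str
    message: str


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def add(self, severity: str, table: str, location: str, message: str) -> None:
        self.issues.append(Issue(severity, table, location, message))

    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    def warnings(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "warning"]


@dataclass
class Project:
    """Long-format measurement table joined with sample metadata.

    ``measurements`` carries one row per (plant, trait, scan) with columns
    ``vtr, unit_coord, timestamp, trait, value`` plus one column per factor
    (``cultivar``, ``treatment``, any extras). Downstream stages append
    ``time_point`` and ``is_outlier`` columns.
    """

    measurements: pd.DataFrame
    meta: pd.DataFrame
    factors: list[str]
    name: str = "project"

    @property
    def traits(self) -> list[str]:
        return sorted(self.measurements["trait"].unique())

    def with_measurements(self, measurements: pd.DataFrame) -> "Project":
        return replace(self, measurements=measurements)


def validate_factor_names(names) -> ValidationReport:
    """Check candidate ANOVA factor names against the allowed charset.

    Factor names must contain only Latin letters, digits, and underscores.
    Report-only: violations come back as error issues, nothing is raised.
    """
    report = ValidationReport()
    for name in names:
        if not name:
            report.add("error", "factors", repr(name), "factor name is empty")
            continue
        if not _FACTOR_NAME_RE.match(name):
            bad = sorted({c for c in name if not re.match(r"[A-Za-z0-9_]", c)})
            report.add(
                "error",
                "factors",
                name,
                f"factor name contains disallowed characters: {', '.join(map(repr, bad))}",
            )
    return report


def _find_one(project_dir: Path, pattern: str, required: bool = True) -> Path | None:
    matches = sorted(project_dir.glob(pattern))
    if not matches:
        if required:
            raise ProjectLayoutError(f"no file matching {pattern!r} in {project_dir}")
        return None
    if len(matches) > 1:
        raise ProjectLayoutError(
            f"expected exactly one file matching {pattern!r} in {project_dir}, found {len(matches)}"
        )
    return matches[0]


def _read_zipped_csv(zip_path: Path, sep: str, encoding: str) -> pd.DataFrame:
    with zipfile.ZipFile(zip_path) as zf:
        members = [m for m in zf.namelist() if m.lower().endswith(".csv")]
        if len(members) != 1:
            raise ProjectLayoutError(
                f"{zip_path.name} must contain exactly one CSV, found {len(members)}"
            )
        with zf.open(members[0]) as fh:
            return pd.read_csv(fh, sep=sep, encoding=encoding)


def load_project(
    project_dir,
    column_map: dict | None = None,
    sep: str = ",",
    encoding: str = "utf-8",
) -> tuple[Project, ValidationReport]:
    """Load and join the three-table-plus-optional-groups project layout.

    Join order: raw rows → translation (unit coordinate → V.T.R) → handmade
    (V.T.R → cultivar/treatment/extras) → optional groups (on Cultivar). The
    handmade ``Treatment`` column overrides any treatment column in the raw
    export. Rows that cannot be joined or whose trait value is non-numeric
    are dropped and reported.

    Returns the project together with a :class:`ValidationReport`; ``ok`` is
    False when any error-severity issue was found.
    """
    project_dir = Path(project_dir)
    if not project_dir.is_dir():
        raise ProjectLayoutError(f"{project_dir} is not a directory")
    report = ValidationReport()
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    zip_path = _find_one(project_dir, "*_data.zip")
    handmade_path = _find_one(project_dir, "*_handmade.csv")
    translation_path = _find_one(project_dir, "*_translation.csv")
    groups_path = _find_one(project_dir, "groups.xlsx", required=False)

    raw = _read_zipped_csv(zip_path, sep, encoding)
    handmade = pd.read_csv(handmade_path, sep=sep, encoding=encoding, dtype=str)
    translation = pd.read_csv(translation_path, sep=sep, encoding=encoding, dtype=str)

    for col, tbl, path in (
        ("V.T.R", handmade, handmade_path),
        ("Cultivar", handmade, handmade_path),
        ("Treatment", handmade, handmade_path),
        ("V.T.R", translation, translation_path),
        ("T:X:Y", translation, translation_path),
    ):
        if col not in tbl.columns:
            raise ProjectLayoutError(f"{path.name} lacks required column {col!r}")

    unit_col = cmap["unit"]
    time_col = cmap["timestamp"]
    if unit_col not in raw.columns:
        raise ProjectLayoutError(f"raw CSV lacks unit column {unit_col!r}")
    if time_col not in raw.columns:
        raise ProjectLayoutError(f"raw CSV lacks timestamp column {time_col!r}")

    # Trait columns: everything that is not a mapped role column.
    role_cols = {unit_col, time_col, cmap.get("treatment")}
    trait_cols = [c for c in raw.columns if c not in role_cols]
    if not trait_cols:
        raise ProjectLayoutError("raw CSV contains no trait columns")

    long = raw.melt(
        id_vars=[c for c in (unit_col, time_col) if c in raw.columns],
        value_vars=trait_cols,
        var_name="trait",
        value_name="value",
    ).rename(columns={unit_col: "unit_coord", time_col: "timestamp"})
    long["unit_coord"] = long["unit_coord"].astype(str).str.strip()

    # Validate coordinates once per distinct unit string.
    bad_units = set()
    for u in long["unit_coord"].unique():
        try:
            parse_unit_coordinate(u)
        except CoordinateParseError as exc:
            bad_units.add(u)
            report.add("error", "data", u, f"unparseable unit coordinate: {exc}")
    if bad_units:
        long = long[~long["unit_coord"].isin(bad_units)]

    long["timestamp"] = pd.to_datetime(long["timestamp"], format="mixed")
    long["value"] = pd.to_numeric(long["value"], errors="coerce")
    n_bad = int(long["value"].isna().sum())
    if n_bad:
        report.add(
            "warning", "data", "value", f"dropped {n_bad} non-numeric trait values"
        )
        long = long.dropna(subset=["value"])

    # Translation: unit coordinate -> V.T.R.
    translation = translation.copy()
    translation["T:X:Y"] = translation["T:X:Y"].str.strip()
    translation["V.T.R"] = translation["V.T.R"].str.strip()
    if translation["T:X:Y"].duplicated().any():
        for u in translation.loc[translation["T:X:Y"].duplicated(), "T:X:Y"]:
            report.add("error", "translation", u, "duplicate unit coordinate")
    unit_to_vtr = dict(zip(translation["T:X:Y"], translation["V.T.R"]))
    orphan_units = sorted(set(long["unit_coord"]) - set(unit_to_vtr))
    for u in orphan_units:
        report.add(
            "error", "translation", u,
            "unit coordinate present in raw data but missing from the translation table",
        )
    long = long[long["unit_coord"].isin(unit_to_vtr)]
    long["vtr"] = long["unit_coord"].map(unit_to_vtr)

    # Handmade metadata: V.T.R -> cultivar / treatment / extras.
    handmade = handmade.copy()
    handmade["V.T.R"] = handmade["V.T.R"].str.strip()
    dup = handmade["V.T.R"].duplicated()
    if dup.any():
        for v in handmade.loc[dup, "V.T.R"]:
            report.add("error", "handmade", v, "duplicate V.T.R")
        handmade = handmade[~handmade["V.T.R"].duplicated(keep="first")]
    missing_meta = sorted(set(long["vtr"]) - set(handmade["V.T.R"]))
    for v in missing_meta:
        report.add(
            "error", "handmade", v,
            "V.T.R present in translation but absent from the handmade table",
        )
    long = long[long["vtr"].isin(set(handmade["V.T.R"]))]

    for col in ("Cultivar", "Treatment"):
        blank = handmade[col].isna() | (handmade[col].str.strip() == "")
        if blank.any():
            report.add("error", "handmade", col, f"{int(blank.sum())} empty {col} entries")

    meta = handmade.rename(columns={"V.T.R": "vtr", "Cultivar": "cultivar", "Treatment": "treatment"})
    extra_cols = [c for c in meta.columns if c not in ("vtr", "cultivar", "treatment")]

    # Optional cultivar-level grouping factors.
    if groups_path is not None:
        groups = pd.read_excel(groups_path, dtype=str)
        if "Cultivar" not in groups.columns:
            raise ProjectLayoutError("groups.xlsx lacks the mandatory Cultivar column")
        groups = groups.rename(columns={"Cultivar": "cultivar"})
        group_extras = [c for c in groups.columns if c != "cultivar"]
        meta = meta.merge(groups, on="cultivar", how="left")
        extra_cols += group_extras

    # Extra columns are candidate factors only when their names pass the charset rule.
    name_report = validate_factor_names(extra_cols)
    invalid = {i.location for i in name_report.errors()}
    for i in name_report.errors():
        report.add("warning", "factors", i.location, i.message + " (excluded from factors)")
    factors = ["cultivar", "treatment"] + [c for c in extra_cols if c not in invalid]

    measurements = long.merge(meta, on="vtr", how="left")
    # Handmade Treatment overrides the raw export's treatment column by
    # construction: the raw column was never carried into the melt.
    measurements = measurements.sort_values(["vtr", "trait", "timestamp"], kind="mergesort")
    measurements = measurements[
        MEASUREMENT_COLUMNS + [c for c in measurements.columns if c not in MEASUREMENT_COLUMNS]
    ].reset_index(drop=True)

    project = Project(
        measurements=measurements,
        meta=meta.reset_index(drop=True),
        factors=factors,
        name=project_dir.name,
    )
    return project, report


def write_project(project: Project, out_dir, name: str | None = None) -> Path:
    """Write a project back to the three-table-plus-groups directory layout.

    Inverse of :func:`load_project` up to row/column order: the measurement
    table is pivoted back to one wide CSV row per (unit, timestamp).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = name or project.name

    wide = (
        project.measurements.pivot_table(
            index=["unit_coord", "timestamp"],
            columns="trait",
            values="value",
            aggfunc="first",
        )
        .reset_index()
        .rename(columns={"unit_coord": "unit"})
    )
    wide.columns.name = None
    wide["timestamp"] = wide["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S")

    zip_path = out_dir / f"{name}_data.zip"
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        info = zipfile.ZipInfo(f"{name}_raw.csv", date_time=(2026, 1, 1, 0, 0, 0))
        zf.writestr(info, wide.to_csv(index=False))

    vtr_units = (
        project.measurements[["vtr", "unit_coord"]]
        .drop_duplicates()
        .rename(columns={"vtr": "V.T.R", "unit_coord": "T:X:Y"})
        .sort_values("V.T.R")
    )
    vtr_units.to_csv(out_dir / f"{name}_translation.csv", index=False)

    meta_cols = [c for c in project.meta.columns]
    handmade = project.meta[meta_cols].rename(
        columns={"vtr": "V.T.R", "cultivar": "Cultivar", "treatment": "Treatment"}
    )
    handmade.to_csv(out_dir / f"{name}_handmade.csv", index=False)
    return out_dir
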