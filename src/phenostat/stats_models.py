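"""Automatic model selection and fitting with diagnostics and growth summaries.

The model-selection rule mirrors the analysis workflow the pipeline
automates: classical ANOVA for balanced designs whose largest factor has at
most 10 levels, mixed models (random intercept per plant) for unbalanced or
larger designs up to 20 levels, mixed with a high-cardinality warning beyond
that, and spline models whenever the question is a time-series one. All
fixed-effect models include every requested main effect and all pairwise
interactions; sums of squares are Type II, which coincides with Type I on
balanced data and tolerates mild imbalance.

Diagnostics are Shapiro-Wilk on residuals (normality) and Brown-Forsythe
(median-centered Levene) across cells (homogeneity of variances). Post hoc
comparisons use Tukey's HSD. Effect sizes are partial eta squared,
SS_term / (SS_term + SS_residual).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ConvergenceError, DegenerateDesignError

__all__ = [
    "DesignSummary",
    "Diagnostics",
    "ModelResult",
    "GrowthSummary",
    "summarize_design",
    "select_model",
    "fit_anova",
    "fit_mixed",
    "fit_spline",
    "diagnose",
    "posthoc_tukey",
    "effect_sizes",
    "growth_summary",
]

log = logging.getLogger(__name__)

#: Largest per-factor level count for classical ANOVA on a balanced design.
ANOVA_MAX_LEVELS = 10
#: Largest per-factor level count before a high-cardinality warning is logged.
MIXED_MAX_LEVELS = 20


@dataclass
class DesignSummary:
    factors: list[tuple[str, int]]
    balanced: bool
    max_levels: int
    n_obs: int


@dataclass
class Diagnostics:
    """Assumption-check p-values; ``None`` marks an unavailable diagnostic."""

    normality_p: float | None
    homogeneity_p: float | None


@dataclass
class ModelResult:
    model_type: str  # anova | mixed | spline
    terms: pd.DataFrame  # term, sum_sq/statistic, df, F, p
    effect_sizes: dict | None = None
    diagnostics: Diagnostics | None = None
    posthoc: pd.DataFrame | None = None
    factors: list[str] = field(default_factory=list)
    response: str = "value"
    random_sd: float | None = None
    fitted: object = None


def summarize_design(data: pd.DataFrame, factors: list[str]) -> DesignSummary:
    """Level counts, balance, and size of the design defined by ``factors``.

    A design is balanced when every cell of the full factorial cross has the
    same positive count. Raises :class:`DegenerateDesignError` naming any
    factor with fewer than two observed levels.
    """
    if not factors:
        raise DegenerateDesignError("no factors given")
    counts = []
    for f in factors:
        if f not in data.columns:
            raise KeyError(f"unknown factor {f!r}")
        nlev = int(data[f].nunique())
        if nlev < 2:
            raise DegenerateDesignError(f"factor {f!r} has a single observed level")
        counts.append((f, nlev))
    cells = data.groupby(factors, observed=True).size()
    full_cross = int(np.prod([n for _, n in counts]))
    balanced = bool(len(cells) == full_cross and cells.nunique() == 1)
    return DesignSummary(
        factors=counts,
        balanced=balanced,
        max_levels=max(n for _, n in counts),
        n_obs=len(data),
    )


def select_model(design: DesignSummary, time_series: bool = False, override: str | None = None) -> str:
    """Pick anova / mixed / spline for a design; a user override always wins."""
    if override is not None:
        if override not in ("anova", "mixed", "spline"):
            raise ValueError(f"unknown model override {override!r}")
        auto = select_model(design, time_series)
        if override != auto:
            log.warning("model override %r replaces automatic choice %r", override, auto)
        return override
    if time_series:
        return "spline"
    if design.balanced and design.max_levels <= ANOVA_MAX_LEVELS:
        return "anova"
    if design.max_levels > MIXED_MAX_LEVELS:
        log.warning(
            "factor with %d levels exceeds %d; fitting a mixed model anyway",
            design.max_levels, MIXED_MAX_LEVELS,
        )
    return "mixed"


def _fixed_effects_formula(response: str, factors: list[str]) -> str:
    mains = [f"C({f})" for f in factors]
    pairs = [f"C({a}):C({b})" for a, b in itertools.combinations(factors, 2)]
    return f"{response} ~ " + " + ".join(mains + pairs)


def fit_anova(data: pd.DataFrame, factors: list[str], response: str = "value") -> ModelResult:
    """Fixed-effects ANOVA with all main effects and pairwise interactions.

    Type II sums of squares; per-term F and p; partial eta squared per term.
    """
    if data[response].nunique() <= 1:
        raise DegenerateDesignError("response is constant; nothing to test")
    n_cells = data.groupby(factors, observed=True).ngroups
    if len(data) - n_cells < 2:
        raise DegenerateDesignError(
            f"saturated design: {len(data)} observations for {n_cells} cells "
            "leave fewer than 2 residual degrees of freedom"
        )
    formula = _fixed_effects_formula(response, factors)
    res = smf.ols(formula, data=data).fit()
    table = sm.stats.anova_lm(res, typ=2)
    resid_ss = float(table.loc["Residual", "sum_sq"])
    terms = (
        table.drop(index="Residual")
        .reset_index()
        .rename(columns={"index": "term", "PR(>F)": "p", "F": "F"})
    )
    terms["term"] = (
        terms["term"].str.replace(r"C\((\w+)\)", r"\1", regex=True)
    )
    es = {
        row.term: float(row.sum_sq / (row.sum_sq + resid_ss)) if (row.sum_sq + resid_ss) > 0 else 0.0
        for row in terms.itertuples()
    }
    return ModelResult(
        model_type="anova",
        terms=terms[["term", "sum_sq", "df", "F", "p"]],
        effect_sizes=es,
        factors=list(factors),
        response=response,
        fitted=res,
    )


def effect_sizes(result: ModelResult) -> dict:
    """Partial eta squared per term, SS_term / (SS_term + SS_residual)."""
    if result.effect_sizes is None:
        raise ValueError(
            "effect sizes require a sums-of-squares fit (anova/spline); "
            f"not available for model_type={result.model_type!r}"
        )
    return result.effect_sizes


def diagnose(result: ModelResult, data: pd.DataFrame) -> Diagnostics:
    """Assumption checks on a fitted model's residuals.

    Normality: Shapiro-Wilk (subsampled to 5000 residuals when larger).
    Homogeneity: Brown-Forsythe (median-centered Levene) across the cells of
    the model's factors. A check outside its validity range is reported as
    ``None`` (unavailable), never as a failure.
    """
    resid = np.asarray(result.fitted.resid)
    normality_p = None
    if len(resid) >= 3:
        sample = resid
        if len(sample) > 5000:
            sample = np.random.default_rng(0).choice(sample, 5000, replace=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normality_p = float(sps.shapiro(sample).pvalue)

    homogeneity_p = None
    cat_factors = [f for f in result.factors if f in data.columns]
    if cat_factors:
        groups = [g[result.response].to_numpy() for _, g in data.groupby(cat_factors, observed=True)]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = sps.levene(*groups, center="median")
            homogeneity_p = float(p) if np.isfinite(p) else None
    diag = Diagnostics(normality_p=normality_p, homogeneity_p=homogeneity_p)
    result.diagnostics = diag
    return diag


def posthoc_tukey(data: pd.DataFrame, factor: str, response: str = "value") -> pd.DataFrame:
    """All pairwise level comparisons of ``factor`` with Tukey HSD adjustment."""
    levels = data[factor].dropna().unique()
    if len(levels) < 2:
        raise DegenerateDesignError(f"factor {factor!r} needs >= 2 levels for post hoc tests")
    counts = data.groupby(factor, observed=True)[response].size()
    empty = [str(l) for l in levels if counts.get(l, 0) == 0]
    if empty:
        raise DegenerateDesignError(f"empty level(s) for {factor!r}: {empty}")
    hsd = pairwise_tukeyhsd(endog=data[response].to_numpy(), groups=data[factor].astype(str).to_numpy())
    table = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
    table = table.rename(
        columns={"group1": "level_a", "group2": "level_b", "meandiff": "mean_diff", "p-adj": "p_adj"}
    )
    return table[["level_a", "level_b", "mean_diff", "p_adj", "lower", "upper", "reject"]]


def fit_mixed(
    data: pd.DataFrame,
    fixed_factors: list[str],
    random_grouping: str = "vtr",
    response: str = "value",
) -> ModelResult:
    """Mixed model: fixed main effects + pairwise interactions, random intercept.

    The default random grouping is the individual plant (``vtr``), absorbing
    the dependence of repeated measures on the same plant. Per-term Wald
    tests are reported; a non-converged fit raises :class:`ConvergenceError`.
    """
    n_groups = data[random_grouping].nunique()
    if n_groups < 3:
        raise DegenerateDesignError(
            f"random grouping {random_grouping!r} has {n_groups} group(s); need >= 3"
        )
    formula = _fixed_effects_formula(response, fixed_factors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data[random_grouping])
        res = model.fit(reml=True)
    if not res.converged:
        raise ConvergenceError("mixed model failed to converge", details=getattr(res, "hist", None))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wald = res.wald_test_terms(scalar=True).table
    wald = wald[~wald.index.str.contains("Intercept|Group", regex=True)]
    terms = pd.DataFrame(
        {
            "term": wald.index.str.replace(r"C\((\w+)\)", r"\1", regex=True),
            "statistic": wald["statistic"].to_numpy(dtype=float),
            "df": wald["df_constraint"].to_numpy(dtype=float),
            "p": wald["pvalue"].to_numpy(dtype=float),
        }
    ).reset_index(drop=True)
    return ModelResult(
        model_type="mixed",
        terms=terms,
        effect_sizes=None,
        factors=list(fixed_factors),
        response=response,
        random_sd=float(np.sqrt(res.cov_re.iloc[0, 0])) if model.k_re == 1 else None,
        fitted=res,
    )


def fit_spline(
    data: pd.DataFrame,
    time_column: str,
    group_factor: str,
    df: int = 4,
    response: str = "value",
) -> ModelResult:
    """Cubic B-spline time model with a group effect and group x curve interaction.

    The model is ``response ~ C(group) * bs(time, df)``; the group-wise
    difference of time curves is tested by the Type II F-test of the
    interaction block (for the highest-order term this equals the nested
    model comparison). Default df = 4: few knots, matching short scan series.
    """
    n_times = data[time_column].nunique()
    if n_times < df + 2:
        raise DegenerateDesignError(
            f"{n_times} distinct time values cannot support a df={df} spline; "
            "consider ANOVA on the ordinal time_point instead"
        )
    formula = f"{response} ~ C({group_factor}) * bs({time_column}, df={df})"
    res = smf.ols(formula, data=data).fit()
    table = sm.stats.anova_lm(res, typ=2)
    resid_ss = float(table.loc["Residual", "sum_sq"])
    terms = table.drop(index="Residual").reset_index().rename(columns={"index": "term", "PR(>F)": "p"})
    pretty = {
        f"C({group_factor})": group_factor,
        f"bs({time_column}, df={df})": "time_curve",
        f"C({group_factor}):bs({time_column}, df={df})": f"{group_factor}:time_curve",
    }
    terms["term"] = terms["term"].map(lambda t: pretty.get(t, t))
    es = {
        row.term: float(row.sum_sq / (row.sum_sq + resid_ss)) if (row.sum_sq + resid_ss) > 0 else 0.0
        for row in terms.itertuples()
    }
    return ModelResult(
        model_type="spline",
        terms=terms[["term", "sum_sq", "df", "F", "p"]],
        effect_sizes=es,
        factors=[group_factor],
        response=response,
        fitted=res,
    )


@dataclass
class GrowthSummary:
    """Per-group growth rates between consecutive time points.

    ``intervals`` has one row per (group, consecutive time-point pair):
    absolute rate in trait units/day, relative rate per day (log-ratio of
    means; unavailable for non-positive means), and the interval length in
    days. ``totals`` carries last-minus-first mean per group.
    """

    intervals: pd.DataFrame
    totals: pd.DataFrame


def growth_summary(
    data: pd.DataFrame,
    group_factor: str,
    response: str = "value",
    time_point_column: str = "time_point",
    timestamp_column: str = "timestamp",
) -> GrowthSummary:
    """Absolute/relative growth rates per group between consecutive time points."""
    if data[time_point_column].nunique() < 2:
        raise DegenerateDesignError("growth summary needs at least 2 time points")
    per_tp = (
        data.groupby([group_factor, time_point_column], observed=True)
        .agg(mean_value=(response, "mean"), mean_time=(timestamp_column, "mean"))
        .reset_index()
        .sort_values([group_factor, time_point_column])
    )
    rows = []
    totals = []
    for group, g in per_tp.groupby(group_factor, observed=True):
        g = g.reset_index(drop=True)
        for i in range(len(g) - 1):
            a, b = g.loc[i], g.loc[i + 1]
            delta_days = (b.mean_time - a.mean_time) / pd.Timedelta(days=1)
            abs_rate = (b.mean_value - a.mean_value) / delta_days
            rel_rate = (
                (np.log(b.mean_value) - np.log(a.mean_value)) / delta_days
                if a.mean_value > 0 and b.mean_value > 0
                else np.nan
            )
            rows.append(
                {
                    "group": group,
                    "from_time_point": int(a[time_point_column]),
                    "to_time_point": int(b[time_point_column]),
                    "delta_days": float(delta_days),
                    "absolute_rate": float(abs_rate),
                    "relative_rate": float(rel_rate),
                }
            )
        totals.append({"group": group, "total_gain": float(g.mean_value.iloc[-1] - g.mean_value.iloc[0])})
    return GrowthSummary(intervals=pd.DataFrame(rows), totals=pd.DataFrame(totals))
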