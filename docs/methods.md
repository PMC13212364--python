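# Methods

## Data model

A project is a long-format measurement table: one row per (plant, trait,
scan) with an absolute timestamp, joined to per-plant metadata (cultivar,
treatment, free extra factors) through a spatial translation table
(`block:row:index` unit coordinates → sample ids). The sample id (`V.T.R`)
is treated as an opaque unique string and never parsed for semantics;
cultivar and treatment always come from the metadata table, whose
`Treatment` column overrides any treatment column in the raw export. Extra
factor columns are admitted only when their names contain Latin letters,
digits, and underscores exclusively; offending columns are kept in the table
but excluded from the factor list, with a warning. Non-numeric trait values
(sensor sentinels) are counted, reported as warnings, and dropped. The raw
CSV dialect defaults to comma-separated, `.` decimal, UTF-8, one header row;
the separator, encoding, and role-column names are overridable because
platform exports vary by locale.

## Timestamp synchronization

Measurements are assigned ordinal time points by one-dimensional DBSCAN
over timestamps with `min_samples = 1`, so no measurement is ever labeled
noise — downstream models need a complete assignment. In one dimension with
`min_samples = 1`, DBSCAN is exactly the sorted gap-split rule (cluster
boundaries wherever the adjacent gap exceeds eps), which is how the test
suite cross-checks it against an independent oracle. Cluster ids are
renumbered chronologically by their median member timestamp, which also
serves as the representative time (median rather than mean: robust to
stragglers). Default `eps = 6 h`: large enough to absorb same-day block
start offsets (≈ 2 h) and scan jitter, small enough to keep daily waves
apart; it is the first knob to retune for schedules with sub-daily waves.
Increasing eps can only merge clusters, never split them.

## Outlier policy

Flags are computed independently within experimental cells — by default
cultivar × treatment × trait × time point, the finest subgroup in which
trait values are biologically exchangeable. Two detectors:

* IQR: fences Q1 − k·IQR .. Q3 + k·IQR, k = 1.5 by default, with quartiles
  by linear interpolation between order statistics (the common
  spreadsheet/statistical default; the convention matters because it moves
  the fences, so it is fixed and documented).
* Z-score: |value − mean| / sd > 3 by default, sd with n−1 denominator.

k = 1.5 and z = 3 are conventional defaults; the source workflow does not
prescribe values. Cells smaller than 4 (IQR) or 3 (Z) pass through
unflagged — fences estimated from tiny cells are noise. Three modes: filter
(drop), winsorize (clip to the nearest fence, keeping the pre-clip value for
audit), annotate (keep and mark). Outlier handling precedes technical
aggregation, so flags are computed on raw scans. IQR winsorization is
idempotent in practice (clipped values sit exactly on fences and are not
re-flagged under the strict inequality); Z-score winsorization is only
approximately so, because clipping shrinks the standard deviation — the
property tests therefore pin idempotence for the IQR method. Analyses run
on annotate-mode output exclude flagged rows by default
(`AnalysisRequest.with_outliers=False`); the "with outliers" toggle on plots
and models is the same switch.

## Model selection and fitting

The selector implements the workflow rule: spline for time-series
questions; otherwise classical ANOVA when the design is balanced (every
cell of the full factorial cross has the same positive count) and no single
factor exceeds 10 levels; otherwise a mixed model. "Factor levels" is read
as the maximum level count of any single factor, not the sum — the only
reading under which a 2-treatment × 50-cultivar design crosses the 10-level
boundary. Beyond 20 levels the pipeline degrades gracefully to a mixed
model with a logged high-cardinality warning rather than refusing. A user
override always wins and is logged.

* ANOVA: OLS with all main effects and pairwise interactions (never
  higher), Type II sums of squares — identical to Type I on balanced data
  and robust to mild imbalance. Saturated designs (fewer than 2 residual
  degrees of freedom, estimated conservatively from the observed cell
  count) and constant responses are rejected before fitting.
* Mixed: same fixed-effects structure plus a random intercept per plant
  (`vtr`) — repeated measures on the same plant are the dominant dependence.
  Per-term Wald tests; non-convergence raises with optimizer history.
  Partial eta squared is undefined without a sums-of-squares decomposition,
  so mixed results carry no effect sizes.
* Spline: OLS on a cubic B-spline basis of time (default df = 4 — few
  knots, matching short scan series) with group main effect and
  group × basis interactions. The group-wise curve difference is the Type II
  F-test of the interaction block, which for the highest-order term equals
  the nested-model comparison. Needs at least df + 2 distinct time values;
  otherwise it points the user to ANOVA on the ordinal time point.

Diagnostics: Shapiro–Wilk on residuals (subsampled to 5,000 when larger;
unavailable, not failing, below n = 3) and Brown–Forsythe (median-centered
Levene) across design cells. Post hoc: Tukey HSD, the single built-in
adjustment. Growth summaries report, per group and consecutive time-point
interval, the absolute rate Δmean/Δdays, the relative rate
(ln m₂ − ln m₁)/Δdays (reported unavailable for non-positive means), and the
total gain last − first; interval lengths use the mean timestamp per time
point.

## Synthetic data generator

The generator emulates a controlled-chamber longitudinal experiment in the
exact input layout, with defaults mirroring a realistic study: 50 cultivars
× 2 treatments × 2 replicates (200 plants) over 9 blocks, five scan waves
over 20 days. Heights follow a logistic curve H(t) = K/(1 + e^{−r(t−t0)})
(sigmoid growth is a harness choice, not a claim about any particular crop),
with per-cultivar K and r variation (8 % and 5 % relative sd), a relative K
difference between treatments (default 15 %, first treatment taller), and
Gaussian noise with sd a fraction of K (default 5 %). NDVI drifts linearly
from 0.50 to 0.80 with an extra end-of-experiment bonus for the second
treatment, clipped into [−1, 1]; PSRI rises from 0.05 and plateaus at 0.25
mid-experiment (day 10). Timestamps get per-block start offsets (≤ 2 h
across blocks) and per-scan uniform jitter (≤ 1 h) — below the clustering
eps, while inter-wave gaps (≥ 5 days) are far above it, so clustering
recovers exactly the scan waves. Each measurement is independently
multiplied by `spike_magnitude` (default 5×) with probability
`artifact_rate` (default 1 %), emulating foreign objects in the camera's
field of view. All randomness flows from one seed; artifact draws are
consumed even at rate 0 so configs differing only in the artifact rate share
a noise stream. Output files use fixed float formatting and fixed ZIP
metadata, so identical configs give byte-identical output.

What the generator does *not* emulate: spatial field gradients, missing
scans, trait correlations beyond their shared schedule, heteroscedastic
noise (noise sd is constant over time, so early-time measurements near zero
height can go negative), and platform-specific column dialects. Passing
tests therefore demonstrate the pipeline's correctness on well-specified
inputs, not robustness to every field pathology.

## Pipeline, configuration, determinism

The wizard stage (load → validate → cluster → outlier policy → aggregate)
logs per-stage row counts and wall-times, and caches the processed table
beside the project keyed by a hash of the input files and the
configuration; reruns on unchanged inputs reuse the cache (reported as a
cache hit, never asserted by timing). The run configuration is one flat
YAML file with a strict schema — unknown keys fail the import by name — so
an exported config fully reproduces a run. Timings appear only in logs and
are never part of any assertion.

## Problem sizes used in the checks

Simulation-based checks run at sizes chosen to make the statistical
assertions sharp while keeping the suite quick: the headline
treatment-significance check uses 50 seeded replicates of the full pipeline
(4 cultivars × 2 treatments × 10 replicates = 40 plants/treatment); type-I
calibration of the ANOVA uses 500 null replicates at n = 40 with a 4-sd
binomial tolerance around α = 0.05; the spline null calibration uses 120
replicates and its power check 20 replicates at 40 plants/group; the DBSCAN
oracle comparison runs 1,000 random instances plus a derandomized
property-based sweep. The NDVI bound is evaluated on a 201 × 201 grid.

## Known limitations

* The PSRI band arithmetic is implemented as the standard (R − G)/NIR and
  isolated in one function; platforms computing a different senescence
  variant should pass their own column through, which the pipeline leaves
  untouched (indices are only computed when absent).
* Mixed-model selection at a single time point leaves one observation per
  random group; the fit then degenerates gracefully toward OLS (the random
  variance is unidentifiable but the fixed-effect tests remain valid).
* No spatial (row-column) modelling, no Bayesian models, no variance
  component / heritability pipelines, no automatic eps estimation — eps is
  a user decision.
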