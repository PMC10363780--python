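# Methods

`boarrest` reconstructs the daytime resting strategy of a nocturnal ungulate
from two collar streams — a 0–255 activity summary (ACT) every 5 min and a
GPS fix every 30 min — and models where rest happens, how often sites are
re-used, and how often rest is interrupted.  This note records the models,
the numerical choices, and what the synthetic generator does and does not
emulate.

## Inactive-phase segmentation

Each 5-min epoch is classified *resting* (ACT ≤ 40) or *active* (ACT > 40).
The daily inactive phase is a single consolidated resting bout spanning
daytime, so short activity bouts inside rest must be smoothed away.  The
smoothing rule is: an active run strictly shorter than `max_gap_minutes`
(default 60) flanked on both sides by resting runs of at least
`min_rest_run_minutes` (default 120) is absorbed; absorption is applied
iteratively (shortest gap first, earliest on ties) to a fixed point.  The
flank requirement is what stops isolated resting-classified epochs in the
middle of the night from chaining into the phase.  Both durations are
config-exposed; they are this package's reconstruction of the qualitative
rule "disregard short activity bouts between long resting bouts", not a
published constant.

A merged resting run is attributed to the local day whose daylight window
[sunrise, sunset] it overlaps; per day the phase is the run with the largest
daylight overlap (ties: longer run, then earlier start).  This is equivalent
in intent to noon-to-noon day windows — a phase beginning in the last hours
of the night is attributed to the following daytime — but avoids cutting a
phase at an arbitrary window edge.  Days whose phase overlaps a sensor gap
longer than three nominal intervals are flagged low-confidence; days with no
resting run overlapping daylight yield no phase (logged).

Sunrise and sunset come from the NOAA solar-position equations evaluated at
12:00 UTC of each date (refraction-corrected zenith 90.833°), accurate to
about a minute at mid-latitudes; polar latitudes are rejected.  Timestamps
are stored UTC; a configured time zone is used only to assign epochs to
local calendar days.

## Relocation detection

A relocation is a move of more than 100 m (strictly) during the inactive
phase.  Candidates are maximal supra-threshold ACT runs lasting at least 10
min (two epochs — one-epoch spikes are noise); for each candidate, the mean
GPS position from the phase start (or the previous event) to the candidate
start is compared with the mean position from the candidate end to the next
candidate (or phase end).  At least 2 fixes are required on each side; an
event is emitted iff the centroid distance exceeds 100 m, and multiple
events per phase are processed in time order with centroids recomputed
between successive candidates.  Event distance is the centroid-to-centroid
Euclidean norm, the same statistic the detection uses.

With GPS noise of 15 m (sd, isotropic) the centroid difference of a
stationary animal has an sd of a few meters, so the 100 m criterion yields a
false-positive rate of zero in practice; displacement-free comfort bouts
never fire.

## Resting sites

The daily resting location is the mean of the phase's fixes acquired before
the first relocation event, reflecting the dawn choice of a site.  Daily
locations are clustered per animal (sites are per-animal constructs) by
agglomerative clustering with average linkage, cutting the dendrogram at
50 m: merges at inter-cluster average distance ≤ 50 m are kept.  Exact-50 m
merges are allowed; distance ties are resolved by the deterministic merge
order of the linkage algorithm, so permuting the input does not change the
partition in generic position.  Site covariates (vegetation class, signed
distance to village, distance to road) are evaluated at the site centroid.

## Landscape covariates

Villages are derived from building footprints by morphological closing:
buffer each building by 50 m (round joins, 16 segments per quarter circle —
fixed so the area rule is reproducible), union, and shrink each connected
component by 50 m.  Components are decided at the dilation stage, so
buildings closer than 100 m belong to one candidate even if the eroded shape
is multipart; candidates larger than 1.5 ha are villages.  The operation is
idempotent up to the polygonal discretization of the disk.  The road network
keeps the five high-traffic categories (motorway, trunk, primary, secondary,
tertiary); unknown categories are dropped with a log line.  Distance to
village is signed (negative inside).  The hunting calendar labels each date
NHS (closed season), HS non-hunting day, or HS hunting day (Wednesday,
Saturday, Sunday, or a configured bank holiday inside the open season,
which runs 15 August to the end of February or March).  The two-level
NHS/HS label used by the selection and revisitation models collapses the
last two.

Geometry is planar metric throughout.  Geographic input is projected with
an ellipsoidal Lambert conformal conic (defaults reproduce the Lambert-93
grid, GRS80), implemented from the standard map-projection series and
verified by forward–inverse round-trips to 10⁻⁶ degrees.

## Mixed models

Three families share one likelihood engine: binomial (logit), zero-truncated
Poisson — P(Y=k | k≥1) = λᵏe^{−λ}/(k!(1−e^{−λ})) — and gamma with log link
(positive relocation distances; the gamma shape is estimated jointly).
Random structure is a study-site intercept plus an animal-within-site
intercept, each with its own variance.  The marginal likelihood uses a
Laplace approximation over the joint random-effects vector: the penalized
log-likelihood is maximized by damped Newton steps that solve the nested
(arrowhead) Hessian exactly via a Schur complement per site, and the
Gaussian integral is corrected by the block determinant.  Fixed-seed checks
against brute-force quadrature on small datasets agree to < 0.1%.  With a
single level in a factor the variance is pinned at zero (warning), and with
no random factors the likelihood is the exact GLM likelihood (agreement
with IRLS to 10⁻⁶).

Outer optimization is L-BFGS-B over (β, log sd's, log shape), with the
variance parameters bounded in log-space ([−6, 3]) so a zero-variance
optimum is reachable as a boundary.  Standard errors are Wald, from the
numerically observed information (central differences) of the marginal
likelihood; p-values are two-sided normal.  Rank-deficient designs drop
aliased columns with a log line.  Binomial fits with runaway coefficients
(|β| > 10, the complete-separation signature) are refitted with a small
ridge (10⁻²) on the slopes and flagged `penalized`.

Marginal (Nakagawa) R² is var(Xβ) / (var(Xβ) + Σ random variances + family
residual variance), with residual variance π²/3 for binomial-logit,
ln(1 + 1/λ̄) for (truncated) Poisson via the lognormal approximation at the
mean fitted rate, and trigamma(shape) for gamma.  Predictions are at random
effects zero, with link-scale Wald intervals back-transformed.

## Resource selection

The home range is the 90% contour of a kernel utilization distribution of
active-phase fixes: Gaussian product kernel, per-axis normal-reference
bandwidth h = σ·n^(−1/6), evaluated on a 50 m grid; the contour is the
smallest set of cells holding 90% of the estimated mass, represented as the
union of those cells.  Available points are sampled uniformly over that
cell union (cells are equal-area, so cell-then-offset sampling is exactly
uniform).  For each used resting site of a season, 1000 available points
are drawn, pooled per animal.

The RSF is a binomial GLMM of used (1) vs available (0) with vegetation ×
distance-to-road and vegetation × distance-to-village interactions and the
nested random intercepts.  Distances enter in km and are z-scored within
each seasonal dataset before fitting (the coefficient scale is otherwise
arbitrary; raw-km fitting is available by skipping the standardization
step).  Each used site enters once per seasonal model regardless of visit
count; revisitation intensity is modeled separately.  Selection ratios are
SR(x) = (n_available/n_used)·exp(η(x)) with η the full fitted linear
predictor, so SR is the use-density to availability-density ratio (1 =
neutrality); CIs are the delta-method Wald band on the link scale.

Cross-validation follows the area-adjusted-frequency design: 5 folds over
used points, refit on the training portion, score held-out used points and
all available points, 10 equal-interval bins over the pooled score range,
area-adjusted frequency = used fraction / available fraction per bin,
Spearman correlation against bin rank, averaged over folds, with mean ± SE
over 20 replicates.  Bins with no available mass are merged with their
lower neighbor.  Fold refits use the fixed-effects logistic model (the
random-intercept structure is estimated once on the full data; refitting it
100 times would dominate runtime without changing the ranking of scores).

## Behavioral models

Revisitation: one row per (site, season) with ≥ 1 visit; zero-truncated
Poisson GLMM with the RSF predictors plus the log survey length (in days)
as a control covariate — entered as a predictor, not an offset (an offset
variant is a one-line change in the model spec).  Relocation probability:
binomial GLMM over phases, with the 3-level season factor (reference NHS)
and covariates of the phase's initial resting location; `relocated` is
"any event in the phase".  Relocation distance: gamma log-link GLMM on the
first event's distance (km) over relocated phases only.  Per-season
predicted probabilities are reported at a reference profile of vegetation =
1 and distances at their data means (zero after standardization); the
reference is config-exposed.

## The synthetic generator

The generator is the ground-truth engine: it emulates the statistical
structure the analysis assumes, with every draw taken from a single seeded
generator so a seed fixes the whole study.

* **Landscape** — clusters of rectangular buildings forming villages, a few
  straight high-traffic roads (plus residential/track decoys for the
  filter), and circular vegetation patches accumulated until the target
  cover (default 0.4, realized within ±5 points) is reached in an 8 km
  square.
* **Schedule** — phase end ~ N(sunset, 45 min); phase start ~ N(sunrise +
  μ, 90 min), both truncated at ±2.5 sd and snapped to the 5-min grid, with
  μ set so the expected phase length equals the target inactive fraction
  (default 0.585) of the 24-h day given the mean day length of the survey
  window.  This reproduces the observed asymmetry — ends tightly anchored
  to sunset, starts loosely to sunrise.
* **Activity** — rest epochs ~ N(10, 8), active epochs ~ N(120, 40), both
  clipped to [0, 255] and rounded.  Short comfort bouts inside rest
  (Poisson mean 2 per phase, 5–15 min, no displacement) and relocation
  bouts draw from the active distribution *conditioned on exceeding the
  classification threshold*: a bout is by construction a period the
  classifier should flag, and a sub-threshold epoch inside one would split
  it into fragments no smoothing rule could reassemble.  Bouts are placed
  at least 2 h from the phase bounds and from each other, so the simulated
  phase remains one consolidated rest under the smoothing definition.
* **Sites** — a per-animal pool of 100 candidate sites within 1.5 km of the
  home centre, at least 200 m apart, sampled with weights exp(βᵀx) from the
  configured true selection coefficients (default: vegetation +1.3).  Each
  dawn a site is drawn with log-odds increasing as distance-to-village
  decreases (default 1.0 per km).  Pool size and concentration were chosen
  so that over a ~4-month survey roughly half the used sites are one-offs
  and the rest revisited, with revisits concentrated near villages.
* **Movement** — during the phase, fixes jitter isotropically (sd 15 m)
  around the site (below the 50 m clustering cut); at night an
  Ornstein-Uhlenbeck walk around the home centre (stationary sd 600 m,
  lag-30-min correlation 0.85), with the animal commuting to within ~30 m
  of the chosen site during the last hour of the night and lingering near
  the site for the first hour after rising.
* **Relocations** — with per-season probability (defaults 0.08 NHS, 0.12
  HS non-hunting, 0.17 HS hunting days), one event at a uniform time in the
  phase interior (≥ 2 h from the bounds so both sides retain fixes and the
  phase stays consolidated), displacing by 100 m + lognormal(log 130, 0.7)
  × a season multiplier — so every true relocation exceeds 100 m, long
  moves are rare and concentrated in the hunting season, and the overall
  scale matches a few-hundred-metre median.

What the generator does **not** emulate: GPS fix failures and multipath
outliers, collar-specific ACT calibration drift, social structure, diurnal
activity of individual animals, weather, and any coupling between covariates
and relocation probability (the season is the only relocation driver, which
is what makes the per-season recovery check interpretable).  Passing tests
therefore demonstrate the pipeline's correctness under its stated
assumptions, not robustness to every field artifact.

## Problem sizes

The test suite exercises the segmentation/detection/clustering stages on 5
animals × 120 days (600 phases), mixed-model parameter recovery on 100
replicates per family of 2000 observations in 20 groups, RSF recovery on 50
replicates of 1000 used points with 20 available each, and the end-to-end
relocation-probability check on 20 animals × 365 days (≈ 7300 phases, ≥
1000 per season category).  The acceptance script uses the same
behaviour-scale study, a 12 × 126-day study for the revisitation pattern
(which depends on survey length), and a 5 × 120 selection study spanning
both seasons with the full 1000:1 availability ratio.  These sizes keep the
default runs desk-scale while leaving Monte-Carlo noise well inside the
stated tolerances.

Two quantitative caveats of the generator worth knowing.  First, the phase
start offset from sunrise is normal with its mean pinned by the inactive-
fraction target (about −1.9 h for a mid-latitude year), so the share of
starts falling within ±30/±90 min of sunrise is lower than field data show:
empirical start distributions are skewed with extra mass right at sunrise,
which a truncated normal cannot reproduce while holding the time budget.
The asymmetry itself — ends tightly sunset-anchored, starts loosely
sunrise-anchored — is reproduced.  Second, the detector's perfect
recall/zero-false-positive behaviour holds at the 600-phase criterion
scale; at ~7000 phases the ~1% of days with an imperfect segmentation
boundary contribute a handful of missed or spurious events (recall ≈ 0.99,
false-positive rate ≈ 0.003), which the acceptance script reports honestly
rather than hiding.

## Known limitations

* The bout-smoothing thresholds are a parameterized reconstruction; on real
  data they should be tuned against visual inspection of actograms.
* The Laplace approximation can be mildly biased for binomial data with few
  observations per group; the quadrature cross-checks cover the regimes
  used here.
* Selection-ratio neutrality holds for the estimand; a single finite-sample
  curve can drift outside ±0.1 at covariate extremes, which is why the
  neutrality check averages replicate curves.
* The dendrogram cut treats exact-50 m separations as mergeable; strict
  separation would shift only measure-zero configurations.
* Home ranges are unions of 50 m cells, not smooth contours; areas agree
  with analytic Gaussian contours to well within 10%.
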