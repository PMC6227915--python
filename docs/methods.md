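# Methods

This note documents the models, the numerical choices, and what the
synthetic-data experiments do and do not demonstrate.  It is the
maintainer's account of the science in the package; every number quoted
here is computed by the test suite or by `scripts/acceptance.py`, not
asserted from memory.

## Projection engine and conventions

Populations live on single ages 0–94 plus an open interval 95+, two
sexes, mid-year time points.  Within each one-year interval the order of
operations is: half of net migrants added, cohorts survived one age
step, remaining migrants added, births computed and survived to the
first mid-year.  Two conventions had to be fixed where standard practice
offers choices, and both are declared rather than inferred:

* **Migration timing** — half at the start and half at the end of each
  interval.  This is the common cohort-component compromise between
  "migrants exposed all year" and "not at all".
* **Birth exposure** — the mean of start- and end-of-interval female
  population.  End-of-interval counts at fertile ages do not depend on
  the current year's births, so this is well defined without iteration.

The open interval is survived by pooling ages 94 and 95+ and applying
T(95)/T(94), the person-years ratio.  When a table has no deaths below
the terminal age, the open-interval ratio is set to exactly 1: the
forced q(110) = 1 is a table-closure artifact, not mortality.

Deaths are recorded per cohort so the balancing identity
N(t+1) = N(t) + B − D + G holds to machine precision (the acceptance
suite observes residuals ≈ 4×10⁻¹⁶ relative).  If a projection step
would produce a negative count (large negative migration), the cell is
clipped to zero and the correction is folded into the recorded net
migration, so the identity survives clipping; the clip count is kept on
the returned grid.

Back-projection inverts the survival step under zero net migration.
Age 0 of year t−1 is recovered from the age-1 survivors of year t, so
no birth series is needed; the pooled open interval is split by the
anchor's own 94 vs 95+ proportions.  Consequence: after k back-steps,
ages ≥ 94−(k−1) depend on that heuristic split, and a forward
re-projection reproduces the anchor exactly only at ages ≥ k ("closed
ages").  The round-trip is exact there (≈ 3×10⁻¹⁶ relative), and a
14-year back-projection recovers a migration-free 1950 truth within 2%
at ages 5–80.

## Life-table graduation

Abridged tables use the standard grouped ages (<1, 1–4, then 5-year to
110+).  Expansion to single ages:

* **Ages 15–99** — monotone piecewise-cubic (PCHIP) interpolation of
  group-boundary survivorship, done on the log-lx (cumulative-hazard)
  scale.  Monotonicity is preserved either way; the log scale matters
  because lx spans orders of magnitude at old ages, and interpolating
  on the natural scale loses relative accuracy exactly where qx is
  computed from ratios of nearly-equal small numbers.  On a 200-table
  synthetic library the worst single-age qx error at ages 20–90 is
  about 1.2% (natural-scale interpolation peaked near 15%).  Because
  boundary values are interpolated exactly, group consistency at these
  ages is automatic and no rescaling is applied.
* **Ages 0–14 and 100–109** — per-age OLS of log single-year qx on the
  log of the parent group's qx, fitted on a library of internally
  consistent complete/abridged pairs, then rescaled within each group
  so `1 − Π(1−1qx) = 5qx` holds exactly (a scalar multiplier found by
  root-bracketing; an extinct group, 5qx = 1, keeps the predicted age
  pattern and closes with q = 1).  Age 110 is terminal with q ≡ 1 and
  carries no regression.
* **ax** — 0.5 at every single age except <1 and the terminal group,
  which copy the abridged values.

The seams at ages 14/15 and 99/100 may be discontinuous in the slope of
qx; this is accepted as a property of the construction.  Fatal
discontinuities (conflict, disasters) are added on the mx scale as a
group-constant rate, converting q↔m with q = m/(1+(1−a)m), and capped
at q = 1 with a warning.

## Census preparation

Completeness is modelled on a scaled logit, logit(c/1.25), regressed on
SDI — the scaling makes modest overcounts representable; predictions
are capped at 1.02.  The global age pattern of enumeration is an
inverse-variance-weighted penalized natural-cubic-spline fit of
age-specific completeness ratios, normalized to mean 1 — a desk-scale
stand-in filling the same role as a full Bayesian meta-regression.
High-SDI censuses with their own post-enumeration survey use the
nationally reported completeness; low/middle-SDI censuses additionally
flag under-5 counts for exclusion from the balancing likelihood, since
young-child undercount there is too severe to correct.

Age-heaping corrections:

* **Feeney (single-year counts)** — iterative redistribution: each
  multiple of 5 is compared with the 4-point cubic Lagrange interpolant
  of ages d±1, d±2 (weights (−1, 4, 4, −1)/6), and the excess is moved
  back onto those ages with double weight on immediate neighbours,
  damped by ½ per sweep until the largest relative change is below
  10⁻⁸.  Because transfers stay inside disjoint 5-age blocks, block
  totals are conserved exactly, which pins the equilibrium at the
  undisturbed level; a cubic-interpolant target (rather than the plain
  neighbour mean) makes smooth schedules fixed points to interpolation
  accuracy (< 10⁻⁷ relative on an exponential schedule).  On synthetic
  censuses heaped with strength 0.3 the Whipple index moves from ~188
  to ~99.7 — more than 99% of the way back to 100.
* **Arriaga (5-year groups)** — 10-year totals are re-split with the
  standard interior weights (−older + 11·this + 2·younger)/24; endpoint
  groups use a linearly extrapolated phantom neighbour (the classical
  endpoint formulas live in sources not reproduced here; the phantom
  gives the same order of accuracy).  10-year totals are preserved
  exactly.  **Arriaga strong** first smooths the 10-year totals with a
  (1, 2, 1)/4 moving average rescaled to the overall total.
* **Selection** — single-year counts with Whipple > 105 get Feeney;
  grouped counts get Arriaga at a UN joint accuracy score of 20–40 and
  Arriaga strong above 40.  The thresholds follow UN accuracy-index
  conventions; the joint score is 3·(sex-ratio score) + both age-ratio
  scores.

## Fertility

Internal rates are births per woman-year; ×1000 only at I/O.

Stage 1 estimates the seven groups 15–19 … 45–49.  The 20–24 prior is
log-linear in mean schooling (a linear time trend in the high-income
super-region, where schooling is not used as a covariate); other groups
use a natural cubic spline on the *estimated* 20–24 ASFR — knot at 0.1
births per woman-year, configurable — plus schooling.  The spline knot
is where the late-fertility upturn engages as early fertility falls.
Source random effects are mean log-residual offsets relative to the
reference source (cascade: flagged source → vital registration → DHS
birth histories → other birth histories); data are shifted to the
reference level before smoothing.  Residuals are smoothed with a
tricube moving average, then a Matérn-5/2 GP over time with amplitude
1.4826·MAD of the smoothed residual curve (floored at 10⁻³) and noise =
sampling variance (log scale) plus a non-sampling variance estimated as
(1.4826·MAD of the scatter around the smoothed curve)².  Hyperparameters
(smoothing bandwidth 5/10/20 years, GP length-scale 5/10/15) follow a
three-tier rule on the count of observed years (≥40 dense, ≥15
moderate, else sparse).  With a single location the spatial dimension
degenerates and smoothing is time-only.

Stage 2 splits aggregates against the stage-1 surface.  For a 5-year
maternal cohort's children-ever-born: the implied cumulative fertility
integrates the stage-1 single-age surface along the five cohort
diagonals (truncated to the estimation window — the same bookkeeping
the synthetic generator uses, which is what makes the constructed-bias
recovery exact); the ratio observed/implied scales the stage-1 rate at
every 5-year lag where the cohort occupies a single age group, for
groups 15–45.  Pseudo-points enter the refit at reference level with no
further source offset (splitting has already anchored them to the
reference surface).  Total-birth records are split by the stage-1 age
pattern of births, which requires female exposure by age group.

Extreme ages: ASFR(10–14) = ASFR(15–19)·exp(β0 + β1·ASFR(15–19)) with
(β0, β1) from regression on registration data; ASFR(50–54) is a
constant ratio to ASFR(45–49).  The regressor range is narrow, so the
coefficients are collinear; the *predictions* are the validated object
(within 3% of a generating law on synthetic registration data).

Sex ratio at birth: GP over time on the proportion of live-born males
around a time-invariant prior mean of 0.512 (SRB 1.05), amplitude from
residual MAD (floored at 0.002 so sparse data revert to the prior);
SRB = p/(1−p), with p clipped to keep SRB inside (0.8, 1.4).

## Demographic balancing

Given fertility, mortality and the sex ratio at birth, the projection
is *exactly linear* in the baseline counts and the migrant counts —
births are linear in female population, survival is linear, and flows
add.  The fitter exploits this: the map from (baseline, migration-knot
rates) to model counts at the census cells is precomputed by unit
projections, after which each optimizer iteration is a handful of
matrix-vector products with analytic gradients (L-BFGS-B on the
penalized likelihood).  This replaces heavier automatic-differentiation
machinery at identical MAP solutions.

Model: census cells (age-group × sex × census) are lognormal around the
projected counts with an age-varying sd — 2% at ages 5–44, inflated ×3
under age 5, rising log-linearly after 45 to ×4 at the open interval —
reflecting where age misreporting concentrates.  The baseline has a
lognormal prior (sd 0.1) around its initialization (a zero-migration
back-projection of the oldest census — "measured with substantial
error"; the posterior may move far from it).  Migration is parameterized
as per-capita rates on a 2-year (age) × 2-year (time) knot grid,
bilinearly interpolated, converted to counts against a fixed reference
population (the zero-migration projection of the initial baseline — a
linearisation in the tradition of Bayesian population reconstruction),
with a mean-zero AR1(age)⊗AR1(time) Gaussian prior: ρ_age = 0.9,
ρ_time = 0.7, marginal sd 0.05/year.  Defaults were chosen by the
package's own synthetic sensitivity runs.  The deaths-vs-emigration
identifiability degeneracy is resolved by the mean-zero prior, as in
the source framework.

Model versions differ by the maximum census age admitted; selection
takes the highest maximum age among versions within 0.005 of the best
in-sample R² whose mean |migration rate| over ages 55+ is below
0.01/year, else the best R².

**Recovery study (frozen conditions).**  One country, 1950–2000, with a
refugee-style migration wave: rate amplitude 0.012/year × a Gaussian in
time (centre 1975, sd 4 years) × a Gaussian age profile (mode 25, sd 6),
observed by noise-free 5-year-group censuses in 1960/1970/1980/1990.
The MAP fit attains in-sample log-space R² ≈ 1 (≥ 0.98 required),
Pearson r ≈ 0.97 between fitted and true migration over the wave
window, census-year population error < 0.01%, and migration RMSE ≈ 20%
of the true surface's sd.  A caveat found during the sensitivity runs
and worth stating: a *rectangular* (hard on/off) shock is not
recoverable at that RMSE — the AR1-smooth prior necessarily rounds its
edges and extrapolates a decaying tail past the last constraining
census.  Smoothly-shaped waves inside the census-covered window are the
conditions under which fine recovery holds.

## Uncertainty

Between-census error: hold out one census, refit the balancing model on
the rest, record the relative error of the fitted total at the held-out
year against the adjusted count, and the gap (years to nearest kept
census).  Absolute errors are scaled by √(π/2) (E|N(0,σ)| = σ√(2/π))
and regressed isotonically on the gap — monotone nondecreasing, as
error cannot shrink with distance from data.  Census-year error: the
delta-method relative sd of the completeness prediction from the
model's coefficient covariance.  Draws: per location-year,
ε ~ Normal(0, σ_gap² + σ_pes²), truncated at −0.9 to keep populations
positive (the distributional family is a package choice; errors are
treated as mean-zero), fully correlated across ages within a
location-year; in registry years only the completeness term applies.
1000 draws by default; 95% intervals from the 2.5th/97.5th percentiles.

**Calibration study (frozen conditions).**  Replicate countries
1950–1990 with seeded AR1 migration-amplitude noise (sd 0.004,
correlation 0.85) and ±3% scenario jitter, censuses in
1955/1963/1975/1985 (mixed spacing so the error model sees gaps of 8
and 10 years).  The error model pools hold-out errors from 8 training
replicates (coarser 5×5 balancing knots: many refits, and only error
*size* matters here); coverage is then measured on 50 fresh replicates
by holding out the 1975 census.  Observed coverage is 94–100% across
seeds against the 95% nominal — within binomial error at n = 50.

## Synthetic data: what it does and does not emulate

The generator produces truths whose statistical structure matches the
real data ecosystem in the features the estimators exploit: smooth
unimodal fertility schedules declining over time, mortality with
childhood and senescent components improving over time, age-peaked
migration with temporal waves, development-dependent undercount with an
under-5/over-65 deficit, total-preserving terminal-digit heaping
(strength h from immediate neighbours, h/2 from two ages away), source
bias and lognormal noise on rates (keeping them positive — no
count-level noise), and cohort children-ever-born integrated along true
diagonals.  The library mortality parameters bracket observed human
schedules (q(0) ~ 0.01–0.15, m(80) ~ 0.04–0.15).

Not emulated, hence not demonstrated by passing tests: real-world
volumes and their spatial correlation; de-jure vs de-facto differences
(a flag is carried, the counts are the same); non-classical age errors
(systematic old-age exaggeration is exercised only through the
variance schedule and version selection, not generated); census-date
fractions of a year; fertility responses to conflict.  Recovery results
on this synthetic ecosystem show the estimators are correct and
well-calibrated *under their own assumptions*, not that those
assumptions hold for any particular country's records.

## Degenerate inputs and numerical details

* Zero-variance regressors in the qx regression raise, naming the age.
* A cohort with zero implied cumulative fertility but positive observed
  children-ever-born raises (the split is undefined).
* GP noise floors: 10⁻⁸ on log-scale sampling variance, so exact dense
  data are interpolated rather than smoothed away.
* The optimizer treats non-convergence as an error (with diagnostics);
  the returned posterior value can only improve on the initialization,
  which the tests assert indirectly through the recovery metrics.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; same seed, same bits.
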