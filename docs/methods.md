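# Methods

This note documents the models, the operational definitions behind the
trajectory segmentation, the synthetic data generator, and the numerical
and design choices that were genuinely open.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The estimation pipeline

**Preprocessing.** Raw fixes are regularized to a nominal fix rate
(default 240 min) with a ±10 min tolerance by a greedy forward pass: from
the current anchor, the earliest fix whose gap falls in the window is
accepted and becomes the new anchor; a failure closes the burst.  The rule
the matching should follow is not uniquely determined by the tolerance
alone; greedy-forward was chosen because it is deterministic, order
independent, and idempotent on already-regular data.  Bursts need at least
3 fixes (one full step with a turning angle).  Kill-site clusters are
found by a sequential scan with three parameters — minimum 4 member fixes,
a 150 m spatial buffer, a 24 h temporal buffer — where membership is
tested against the *running centroid* (recomputed as members join) and the
temporal buffer bounds the gap between consecutive members rather than the
total span, so multi-day feeding sites persist.  Removal keeps the
cluster's first fix as the end of the incoming step and its last fix as
the start of the departing step; everything strictly between is dropped,
so no step ever spans a cluster interior.  After state classification a
3-day transition period at the start of each state is removed and the
remainder re-bursted.  All timestamps are UTC; intervals are half-open
`[start, end)`.

**Dispersal-state segmentation.** NSD is the squared distance (km²) from
the natal-range origin of the daily fix nearest local noon; missing days
stay missing.  The natal range is estimated from the initial residency
window (first 30 days, extended while daily fixes stay inside the current
radius): origin = fix centroid, radius = the 0.95 quantile of daily
distances from it.  Residency itself is accepted only if the window is a
plateau rather than a drift, operationalized as: the distance between the
centroids of the window's first and second halves must not exceed the
radius.  A stationary cloud passes (the two half-centroids nearly
coincide); a monotone march fails (they are half the path apart).  Animals
failing this are flagged and excluded, mirroring field studies' exclusion
of collared juveniles that never display home-ranging behavior around the
capture site.

The canonical NSD shapes are made operational with explicit thresholds
(all exposed in `SegmentationParams`):

* *in the natal range*: NSD ≤ return_threshold × radius² (default
  multiplier 1.0);
* *exploratory*: an excursion of ≥ 7 consecutive days beyond threshold
  that later re-enters; the segment covers ramp-up through return.
  Shorter sallies remain natal (precedence natal > plateau > travel);
* *departure*: the excursion that never re-enters, from its first day
  beyond threshold;
* *transient home range / established*: within post-departure data, a
  maximal plateau — days whose 21-day window has NSD coefficient of
  variation ≤ 0.15 **and** near-zero linear trend — is transient if its
  span is under 183 days ("six months") and established otherwise.  The
  trend guard matters because NSD of steady travel at large displacement
  has a small CV purely because the level is large.  Detected plateau runs
  are refined by extending their ends while NSD stays within the plateau
  band (max(2 SD, 10% of the mean)), since the sliding window lags the
  true arrival by up to half its width.

**iSSA.** Tentative kernels are fitted to used steps: gamma (shape, scale)
by maximum likelihood (zero step lengths replaced by half the 5 m GPS
precision floor so the support is positive), von Mises concentration by
solving `I₁(κ)/I₀(κ) = mean(cos ta)` with the mean direction fixed at 0.
Twenty available steps per used step share the start point; lengths and
relative angles are kernel draws, endpoints by planar dead reckoning.  The
first step of a burst has no turning angle and forms no stratum.  Habitat
covariates are taken at end points, anthropogenic covariates additionally
at start points for the movement interactions (default log(sl) × a and
cos(ta) × a; raw sl is supported).  Movement terms are sl, log(sl) and
cos(ta) — all three, because the gamma density ratio between a tentative
and a true kernel lies exactly in the span of (sl, log sl), which is what
makes habitat coefficients insensitive to tentative-kernel error and what
the kernel-update formulas consume.  Covariates are z-scored with
stack-wide means/SDs so coefficients are comparable across layers and
sites; this scaling is recorded in the stack.

The conditional (matched-set) log-likelihood is maximized by Newton
iterations on the analytic gradient and observed information with step
halving; convergence at gradient ∞-norm < 1e-6; deterministic given the
data.  Columns with no within-stratum contrast are dropped with a warning.
Complete separation is detected directly (a covariate that perfectly ranks
the used step first or last in every stratum) because the gradient of a
separated likelihood decays below any tolerance at a finite coefficient;
separated or diverged fits are flagged non-converged with infinite
standard errors and excluded from pooling, as are fits with fewer than 30
strata.

**Pooling.** Fixed-effect inverse-variance weighting per site × state ×
term, 95% normal-theory intervals, significance = CI excluding zero.
Cochran's Q and I² are reported for information only.  No multiple-testing
correction is applied.  The two-site table marks terms significant at both
sites on the same side.

## The synthetic generator

**Landscape.** Land-cover patches are Poisson-placed discs (expected
count = density × area; realized radii uniform in [0.5, 1.5] × nominal)
rasterized in a fixed class order onto a square-celled grid (30 m in the
examples, 120 m in the large study landscapes); four-wheel-drive roads
are random straight transects one cell wide; elevation is a sum of ten
sinusoids with absolute wavelengths of 2–12 km — absolute, not
extent-relative, so terrain ruggedness has comparable local variance on
small and large domains — scaled to the configured relief.  Every class
with positive density occupies at least one cell.  Distance layers are
exact Euclidean distance transforms; the log transform uses
`ln(d + 15 m)` (half a cell) so it is defined on-feature and scale-aware.

Sparse classes (developed, hay/crop, water) are specified as *many small
patches* rather than few large ones at the same areal cover (e.g.
developed: 0.5 patches/km² of ~100 m radius).  This is a validity
requirement, not a cosmetic choice: a home range must span many
independent patches of each class for the per-animal model-based standard
errors to reflect the real uncertainty about that class's distance field.
With few patches per range, a large locality random effect appears that
per-animal SEs cannot see, the pooled z-statistics become overdispersed
(measured at ~1.2× under an earlier choice of 0.12 patches/km²), and
the calibration the validation studies assert is unattainable by any
estimator.  The same caution applies to real data: selection coefficients
for covariates whose correlation length approaches the home-range size
carry between-individual variance that inverse-variance pooling
understates.

**Trajectories.** A discrete-choice biased random walk: at each fix
interval, candidate steps are drawn from the gamma/von Mises kernels and
one is chosen with probability ∝ exp(β·z(end) + state term).  States are
time-scheduled so ground-truth change points are exact.  Home-ranging
states (natal, transient, established) add an attraction penalty per
meter beyond the state-center radius (0.01/m in the dispersal
simulations, where sharp NSD plateaus are the point; zero — free movement
— in the estimator-path simulations, see below); travelling states add
an outward drift (0.6 per mean step of outward progress); the exploratory
state drifts out for its first half and homes back at the same rate until
inside the natal radius.  These mechanisms are stand-ins — the literature
specifies no generative model for residency or return — chosen only to
produce the canonical NSD shapes with realistic speeds (~2 km/day of net
travel at a 4-h fix rate with mean steps of 600–800 m).

**Generative candidate count.** The estimator-path simulators draw 200
candidates per step even though the analysis matches each used step with
20 random steps.  The conditional logit estimates the *continuous*
redistribution kernel ∝ f₀(s)·exp(β·z(s)); a 20-candidate softmax choice
is a biased discretization of it, and the resulting attenuation of smooth
covariates (measured at 5–10%) is a property of the approximation, not of
the estimator.  With 200 candidates the discrete choice is close to the
continuous model and the 20-random-step analysis recovers β.  The
dispersal/segmentation simulator keeps 20 candidates (selection strength
is irrelevant to NSD shape recovery).

**Why the estimator studies simulate free-ranging movement.** The
recovery, power and calibration studies place 10 animals at staggered
starts in the central block of one shared 150 × 150 km landscape and let
them range freely — the generative process is exactly the step-selection
model class the estimator fits, with no home-range confinement.  This is
a requirement of what the studies certify, not a simplification: the
calibration claims (bias within 2 pooled SEs, 95% CI coverage, nominal
type-I error) are statements about the estimator *under its own model*,
and they are unattainable by any estimator when the generative process
contains a mechanism the fitted model can only approximate.  This was
measured directly during development with confined (home-ranging)
generative movement: a fitted `home_excess` nuisance term — the
endpoint's distance beyond the track's empirical 0.9-quantile range
radius from the fix centroid — removed most of the attenuation that
omitting confinement causes (non-collapsibility of the logit), but the
residual approximation error leaked into the habitat coefficients with a
locality-dependent sign and size.  The result was between-animal
heterogeneity invisible to the per-animal model SEs (Cochran's Q/df of
1.1–1.4, i.e. an extra variance component of roughly half a per-animal
SE), pooled z-scores overdispersed by ~1.2×, and CI coverage of ~89%
instead of ~95%; richer empirical confinement bases (distance splines)
did not remove it, while an oracle term built from the true center did
(Q/df ≈ 1.0), pinning the cause on estimating the confinement nuisance
from the track.  The domain is sized so that free walks (root-mean-square
wander ~20 km over 300 steps) essentially never meet the boundary.
Confined movement remains in the dispersal simulator, where sharp NSD
plateaus are the point and no coefficients are estimated.

Two consequences carry over to real data.  First, for genuinely
home-ranging animals the `home_excess` term (available via
`fit_track(..., home_range_term=True)`) is still the right nuisance to
include — omitting it attenuates habitat coefficients — but the
heterogeneity its approximation error induces means pooled SEs should be
read as optimistic, and between-animal heterogeneity (Q, I²) should be
inspected rather than assumed away.  Second, animals sharing one local
covariate field have positively correlated estimation errors that
fixed-effect pooling cannot see; the studies' spread-out starts keep each
simulated animal in its own neighborhood.

**Fix schedule.** Nominal interval 240 min (the collar programming of the
motivating study; 60–120 min schedules are resampled to it), Gaussian
timestamp jitter, independent fix drop-outs with probability `p_missed`.

## Problem sizes of the validation studies

Chosen as the package's standard validation conditions: likelihood oracle
on instances of ≤ 10 strata and ≤ 2 coefficients (staged exhaustive grids
from step 1e-3 down to 1e-5); recovery with 100 replicates of 10 animals ×
300 strata against truth (forest −0.5, TRI +0.25, developed +0.3); power
with 50 replicates of two 10-animal sites (developed +0.4 vs 0);
segmentation on 20 dispersers over a 185-day schedule; null calibration
with 200 replicates of 100 strata; permutation with 200 shuffles of 150
strata.  Bias is judged against 2 pooled SEs, coverage against [90%, 99%],
power against 90%, segmentation against 90% per-day accuracy and a 3-day
mean change-point error.

## Known limitations

* The NSD thresholds operationalize visual shape definitions; published
  analyses applied them by eye, so parameter defaults here are validated
  only against the simulator's shapes, not against hand-labelled field
  data.
* The simulator's landscapes are stationary patch mosaics; real covariate
  fields have long-range structure (valleys, towns, river networks) that
  can make within-home-range covariate contrast much poorer than the
  simulation suggests.
* Passing recovery tests show the estimator is correct *under its own
  model*; they cannot certify unmodelled behavior (memory, territorial
  interactions, time-varying selection) in field data.
* One planar CRS in meters throughout; no reprojection, no sub-cell
  geometry, no DOP-based fix screening.
* Mixed-effects (random-slope) pooled models and model selection across
  candidate structures are out of scope; only the global model is fitted.
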