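# Methods

This note documents the statistical models, the numerical choices behind
them, what the synthetic-data generator does and does not emulate, and the
known limitations. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`.

## Baseline model

For one animal and one variable (core temperature T_B in °C or oxygen
consumption VO2 in ml O2/g/hr), observations on a regular grid of K bins per
day (default K = 240, 6-min bins) follow

    Y_t = alpha_{k(t)} + eps_t,   eps_t ~ N(0, sigma1^2),

with one baseline vector alpha of length K per animal shared by all of its
days, and a circular second-order trend prior

    eta_k = alpha_k - 2 alpha_{k-1} + alpha_{k-2} ~ N(0, sigma2^2),

indices modulo K. The circular wrap makes the baseline a function of
time-of-day only, which is what licenses predicting days 2-3 from a day-1
fit. The second-difference operator annihilates constants, so the prior is
improper (flat) in the level of alpha; the data alone set the level.

**Identification and grid dependence.** sigma2 is a *per-step* roughness
scale, so its meaning depends on the grid: a circadian cosine of amplitude
A contributes second differences of magnitude A·(2 - 2cos(2*pi/K)), which is
negligible relative to the default sigma2 values at K = 240 but dominates
them on coarse grids (K <= 60). The shipped defaults (0.01877 °C,
0.00650 ml/g/hr) therefore belong to the 6-min grid; tests that exercise
sigma2 recovery on coarse grids use a flat profile for this reason.

**Sampling.** Given (sigma1, sigma2) the model is linear-Gaussian, so alpha
is marginalised in closed form: the posterior precision of alpha is
diag(n_k)/sigma1^2 + M/sigma2^2 with M the circular second-difference Gram
matrix, and the marginal likelihood needs one K x K solve. When every bin
has the same observation count the precision diagonalises in the (cached)
eigenbasis of M and each evaluation is O(K); unbalanced or missing data fall
back to a dense Cholesky. The ensemble sampler (emcee, walkers treated as
chains for rank-normalised R-hat/ESS via arviz) then explores only the one-
to-five-dimensional space of log noise scales — log-uniform-corrected so the
priors are uniform on the natural scale, Uniform(0, 10) for sigma1 and
Uniform(0, 1) for sigma2 in native units, with a warning if posterior mass
piles up near a bound. For every retained draw alpha is drawn *exactly* from
its Gaussian conditional; the combination is an exact sampler for the joint
posterior. `exact_gaussian_posterior` re-derives the conditional from the
dense precision with generic solves and serves as an independent oracle in
the tests (agreement within 3 Monte-Carlo standard errors).

Missing observations are dropped from the likelihood; alpha remains defined
at every bin through the trend prior. All fits are deterministic given
their seed.

**Hierarchical sigma2 fit.** The calibration fit pools several non-torpid
animals' multi-day recordings: shared sigma2, per-animal sigma1 and alpha
(the alphas marginalised). The posterior median of sigma2 is then frozen for
all single-day baseline fits, mirroring a calibrate-once / apply-per-animal
workflow. Defaults: 24 walkers, 2000 warmup, 600 retained draws per walker;
a coarse separable grid search supplies the initial point.

**Predictive bands.** The band at level 1 - gamma (default 0.999) is the
equal-tailed interval of the posterior predictive of Y per bin — the Gaussian
mixture over draws N(alpha_draw_k, sigma1_draw^2). Its quantiles are found by
vectorised bisection on the mixture CDF (60 halvings, draws thinned to about
2000), which keeps the extreme 0.05% tails smooth instead of relying on
empirical quantiles of finite draws. Equal-tailed intervals are used for
bands; the shortest-interval HPDI is reserved for parameter summaries. The
predictive (noise-inclusive) reading is used because detection thresholds on
raw observations would over-trigger with an alpha-only band.

## Torpor detection

A time point on the evaluation days (all days after the baseline day) is
torpor when the observation is *strictly below* the lower band bound —
jointly for T_B and VO2 under the default rule; T_B-only, VO2-only and fixed
absolute T_B thresholds (31 / 34 °C) are provided for comparison. Missing
points are never flagged. Episodes are maximal runs of flagged bins with no
gap merging and no minimum duration (configurable, but defaults must not
silently smooth); argmin ties break to the earliest time. The per-cohort
induction rate is the fraction of animals with at least one episode.

The minimal metabolic point of a window is the time of minimum T_B (first
occurrence on ties) with VO2 read at that same time; for the normal state
the window is the dark phase of the baseline day, for the torpid state the
flagged points of the later days.

## Thermoregulatory parameters

Heat flows are expressed as oxygen equivalents (1 ml O2 = 5.3 cal = 22.175 J).
The resting heat balance is C dT_B/dt = H (T_R - T_B) - G (T_B - T_A); at
steady state T_B = (H T_R + G T_A)/(G + H) and VO2 = G (T_B - T_A) =
H (T_R - T_B).

Per-animal minimal points across ambient temperatures T_A in {12, 16, 20,
24} °C (the 8 °C probe is excluded because induction is unreliable there)
enter two Bayesian regressions, min T_B = a1 T_A + b1 and min VO2 =
-a2 T_A + b2, with LogNormal(0, 1) priors on the positive slope magnitudes,
uniform priors on intercepts, and Uniform(0, 100) on residual SDs.
Eliminating T_A between the two lines and matching the thermogenesis law
VO2 = H (T_R - T_B) identifies

    H = a2 / a1,      T_R = b1 + a1 b2 / a2,

computed draw-wise from index-paired draws of the two *independently fitted*
regressions (no joint model is attempted; the draw-wise algebraic identity
between the eliminated line and the thermogenesis line is exact and tested).
G comes from the separate no-intercept conduction fit on (T_B - T_A, VO2)
pairs; rows with non-positive gradients are excluded with a warning rather
than sign-flipped. Point summaries are posterior means with 89% HPDIs
(shortest contiguous window of sorted draws; ties to the earliest window).
Percent changes between states use ratios of posterior means; for the gain a
geometric-mean ratio over paired draws is reported alongside, since ratio
summaries do not commute with averaging.

The probe check at T_A = 8 °C asks whether the observed group mean of n new
animals exceeds the 89% HPDI of the predicted mean of n new observations
(linear predictor plus residual noise shrunk by 1/sqrt(n), one sample per
posterior draw).

Q10 between states is computed in the log domain from group-level mean
minima per T_A by default; a per-animal variant exists because the averaging
level of such summaries is a genuine modelling choice.

## Synthetic-data generator

Two generators serve different purposes.

**Calibration generator** (`simulate_baseline_day`): simulates *exactly*
from the baseline model — cosine circadian profile plus one exact draw of
the circular smoothness prior (zero-mean in the constant direction), shared
across D days, fresh observation noise per point. Exactness matters because
the prior's lowest harmonics are extremely diffuse (component variance grows
as the fourth power of the period); any "anchoring" of those harmonics
toward the profile measurably biases sigma2 recovery downward. The price of
exactness is that trajectories are physically unconstrained and can wander
tens of °C; for the oxygen series the level is raised by a constant
(default +20 ml/g/hr) so the unbounded Gaussian trend stays in the
representable non-negative range — the fit is invariant to the level, so
this is purely cosmetic. These series are model-scale objects for
calibration and coverage studies, not physiological look-alikes.

**Cohort generator** (`simulate_cohort`): produces physiological three-day
recordings for the induction protocol (food removed at ZT0 of day 2,
returned at ZT0 of day 3; cohorts across T_A in {8, 12, 16, 20, 24} °C).
The circadian profile is the normal-state steady state plus a non-negative
activity excess that vanishes once per dark phase (ZT18), so a noise-free
animal's dark-phase minimum sits exactly on the steady-state line the
analysis fits; the trend deviation here *is* anchored (scale tau = 0.3 °C /
0.2 ml/g/hr) to keep baselines physiological. Torpor bouts switch the regime
to the torpid (G, H, T_R) triple and integrate the linear heat-balance ODE
with the exact exponential update per bin (unconditionally stable, exact for
constant T_A); VO2 during bouts is max(0, H (T_R - T_B)) plus noise, floored
at zero. After a bout the normal regime rewarms the animal and the series is
handed back to the baseline once the trajectory reaches it or closes within
0.05 °C of the euthermic steady state (rewarming is a minutes-scale
transient). Bout entry is drawn uniformly in ZT 12-15 with a 5-7 h duration
("latter half of the fasting day"), one bout per animal by default.

Defaults: 6-min bins (K = 240), sigma1 = 0.2 °C / 0.2 ml/g/hr, sigma2 at
the calibrated per-step values, normal state (G, H, T_R) =
(0.228, 5.1, 36.6), torpid state (0.144, 0.437, 32.8), heat capacity
C = 0.655 ml O2/g/°C (≈ 3.47 J/g/°C tissue specific heat via the oxygen-
energy conversion; C shapes transients only, never steady states). The
torpid triple reproduces the steady-state slopes a1 = G/(G+H) ≈ 0.248 and
a2 = GH/(G+H) ≈ 0.108, i.e. a T_A-dependent torpor depth, without any
pasted-in rectangles.

What the generator does **not** emulate: locomotor and feeding ultradian
structure; the murine phase relationship of the circadian profile (only the
dark-phase resting touch-point matters to the analysis; the light-phase
shape is schematic); failure to enter torpor at 8 °C (every scheduled bout
happens, so simulated induction rates are 100%); and the extra
thermoregulatory response at 8 °C — that phenomenon is meant to be
*detected* by the probe check, and tests construct it explicitly as a
positive control. Passing tests on these simulations therefore validate the
statistical machinery under the stated assumptions, not the biology of any
particular real cohort.

## Validation layout and problem sizes

The test suite checks, among others: exact-oracle agreement of the sampler
(K = 24); calibration of the predictive band over 50 in-model datasets
(binomial tolerance); hierarchical sigma2 interval calibration over 20
replicates at a coarse grid; predictive-band coverage of held-out days
> 99% at the 99.9% level (4 animals, K = 240); sigma2 recovery within 15%
of the generating values; conductance recovery within 5% (n = 30, noise SD
0.2); detector false-positive rate <= 0.2% on torpor-free days and
sensitivity >= 95% on deep-bout interiors; and a 20-replicate end-to-end
recovery of (H, T_R) at reduced scale (2 animals per T_A, shortened chains).
These sizes were chosen to keep the full suite in the ten-minute range on a
single CPU while leaving the statistical assertions well-powered.

## Known limitations

* **Minimal-point bias.** The minimal metabolic point is the argmin over
  ~120 noisy bins, and the minimum of m noisy observations is biased low by
  roughly sigma1 * E[min of m standard normals] (≈ 0.4 °C at sigma1 =
  0.2 °C). This common bias shifts the intercept b1 — and with it T_R — down
  by the same amount in *both* states, while credible intervals only reflect
  iid scatter and cannot absorb a shared bias. Consequences, measured in the
  end-to-end recovery study: slope-based quantities (a1, a2, H = a2/a1) and
  the *between-state difference* in T_R are unbiased; the absolute T_R of
  the tightly-estimated normal state is the one quantity whose 89% HPDI
  under-covers its generating value (about half of replicates at the
  reduced scale, versus >= 80% for H in both states and for torpid T_R).
  This is a property of minimal-point analyses as such, not of the Bayesian
  machinery; any application that needs absolute set-points should model
  the extreme-value offset or smooth before taking minima.
* The two minimal-metabolism regressions are fitted independently and paired
  by draw index for the H and T_R transforms; a joint errors-in-both-lines
  model is a possible extension.
* sigma2 is grid-bound (see above); transferring the shipped defaults to a
  different bin width requires re-running the hierarchical calibration.
* emcee walkers mix slowly for the 5-parameter hierarchical posterior
  (rank-normalised R-hat around 1.01-1.1 at default lengths); medians are
  stable (ESS ~ 200) but tail summaries of sigma2 deserve longer chains.
* The detector's evaluation days include the post-refeed morning of day 3;
  genuinely depressed rewarming points are counted as torpor, consistent
  with defining the fasting response as part of the hypometabolic episode.
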