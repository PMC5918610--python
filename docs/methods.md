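# Methods

## The decision problem and model structure

The package simulates individual woman/fetus dyads through a two-arm
decision tree for uncomplicated nulliparous pregnancies at 39 weeks:
elective induction of labor at 39 weeks (eIOL_39) versus expectant
management with induction by 41 weeks (EM_41).  Trajectories are drawn by
Monte Carlo micro-simulation rather than expected-value rollback so that
rare events (maternal death, stillbirth) produce countable occurrences and
between-arm contrasts can be tested on simulated 2×2 tables.

Weekly progression in the expectant arm follows: week-39 onset
(spontaneous labor / indicated induction / continue), an antepartum
stillbirth hazard over 39→40, week-40 onset, a second stillbirth hazard
over 40→41, then a mandatory scheduled induction at 41 weeks.  The
elective arm has no continuation period and therefore no stillbirth
exposure: its structural stillbirth count is exactly zero, which matches
the reported arm contrast and encodes the assumption that demise risk
accrues only while the pregnancy continues undelivered.

A woman who suffers an antepartum stillbirth still delivers: the model
routes a 39→40 demise to an indicated induction at week 40 and a 40→41
demise to the 41-week induction, using those contexts' cesarean
probabilities.  This choice (not dictated by the arm structure itself)
affects only ~0.13% of the expectant cohort.

## Cervical status and the 41-week cesarean curve

Cervical readiness is the modified Bishop score (dilation, effacement,
station), taken as an integer in [0, 12]; a score ≤ 4 is unfavorable
("unripe").  Each patient receives a favorability draw and a score uniform
within her band — the score is a severity proxy, not a mechanistic
sub-model of the three components.

Cesarean probability per labor event is conditioned on (onset type, week,
favorability).  For the scheduled 41-week induction the per-score rate
comes from a two-parameter logistic curve fitted to (score, rate) points
supplied in the configuration.  The logistic form guarantees predictions
in [0, 1]; fitting is ordinary least squares on the logit scale (linear,
hence deterministic and permutation-invariant), and a positive fitted
slope is clamped to a flat curve so predictions are never increasing in
the score.  Out-of-range scores are errors, not clamps.

## Outcome taxonomy

Maternal terminal states: no complication; morbidity (transfusion,
chorioamnionitis, preeclampsia); severe morbidity managed in labor and
delivery (eclampsia, hemorrhage, uterine rupture, septic shock, unplanned
hysterectomy or operation, thromboembolism); severe morbidity requiring
ICU care; death.  Neonatal terminal states for live births: no
complication; morbidity (meconium-stained fluid, shoulder dystocia without
lasting damage); severe morbidity (major-comorbidity or respiratory
composite); death.  Component conditions document what each composite
stands for; they are not simulated individually.

Maternal and neonatal outcomes are drawn after the mode of delivery,
conditional on mode.  The packaged fixtures use the same mode-conditional
probabilities in both arms, so the arm contrast in morbidity and mortality
arises entirely through the arms' different cesarean mixes (plus the
stillbirth exposure); the configuration permits arm-specific values where
a user wants an additional direct arm effect.

The five-minute Apgar score is sampled uniformly within the band implied
by the neonatal state (severe → 1–3, non-severe morbidity → 4–7, healthy →
8–10); neonates who die carry no Apgar.  Maternal age is drawn once per
patient from its normal distribution and carried as a covariate for
sensitivity analyses only; it does not enter branch probabilities in the
baseline model.

## Preference weighting and utilities

Perfect health scores 1 and death 0.  The importance ratio x > 0 yields
dyad weights w_M = 1/(1+x) and w_B = x/(1+x), which sum to one by
construction.  The implementation uses this literal formula; because the
ratio's verbal interpretation can be read in either direction, a
`weight_convention` switch flips the two weights, and sweeps over x cover
both readings — the headline verdict is convention-robust since the two
conventions coincide at x = 1 and the sweep spans x and 1/x.

Morbidity-versus-mortality importance is the ratio y (default 1/4 for
both members: death four times as important).  The maternal mapping is

    utility = 1 − w · y_M · (1 − floor)

with floor 0.6 for non-ICU states (the 0.6–1 utility range for maternal
morbid states) and 0.5 for ICU-level morbidity, and severity weight w
drawn on [0.3, 1] (non-ICU) or [0.5, 1] (ICU).  The neonatal mapping is

    utility = 1 − w · y_B

with w on the Apgar band's range ([0.5, 1] severe, [0.3, 1] non-severe),
so that at w = 1 the morbidity disutility is exactly y_B times the
mortality disutility.  These closed forms are this package's own
formalisation of the stated ranges and ratios — the source ranges do not
pin down a unique arithmetic — and both are config-replaceable; all
rate-based results are independent of them.  A stillbirth contributes
infant utility 0 to the dyad combination.  Severity weights default to
triangular distributions on their stated ranges with the mode at the
midpoint (a neutral choice, overridable); utilities are clipped at 0 for
extreme (y > 1) ratio settings.

## Parameters, distributions and sampling

The model has 41 primary variables and 14 derived calculations expressed
declaratively (complement / product / mixture) so chance-node
normalisation can be audited mechanically: at every declared node the
referenced probabilities must sum to 1 within 1e-9.  Distributions follow
the variable's nature: beta for event probabilities (the natural conjugate
form for binomial evidence), triangular for subjectively ranged weights,
normal for maternal age.  Normal distributions are rejected for
probability-role variables at validation time.

Sampling draws every variable from its distribution, applies the derived
rules in order, and re-validates; a draw violating range or normalisation
constraints is rejected and resampled (up to 1000 rounds) rather than
clipped, because clipping would distort the stated distributions.  All
sampling is seed-deterministic.

Each simulated patient consumes a fixed 13-slot block of uniforms from a
counter-based Philox stream, so patient *i*'s trajectory depends only on
(seed, *i*): cohorts are reproducible, independent of iteration order and
cohort size, and common random numbers across arms, parameter settings and
sweep grid points come for free (this also makes the cesarean rate
monotone in any single cesarean branch probability under a shared seed).

## The packaged fixtures and calibration

The original baseline-probability table behind this comparison is not
redistributed with the package.  The `paperlike` fixture therefore carries
*calibrated* point values: starting from clinically shaped values
(week-39/40 onset probabilities around 0.42/0.12 and 0.45/0.17, a 50%
unfavorable-cervix share, a weekly demise hazard near 2 per 1,000), the
calibration routine solves the closed-form expected arm rates for the
branch probabilities that reproduce the reference rates exactly —
cesarean 13.9% / 35.9%, unfavorable-subgroup cesarean 8.0% / 26.1%,
maternal morbidity 16.5% / 21.2%, stillbirth 0% / 0.13%, neonatal death
0.12% / 0.25%, severe neonatal morbidity 9.4% / 12.1% — and then verifies
by simulation (tolerance ±0.005 absolute, matching one-decimal percent
reporting).  Every adjusted variable is tagged `calibrated` in its
provenance field.  Calibration moves only point values; the tree structure,
nodes and derived rules are never altered.

One consequence of the reference numbers is worth flagging: because the
reported unfavorable-subgroup cesarean rates (8.0%, 26.1%) lie *below* the
overall arm rates (13.9%, 35.9%), the implied favorable-subgroup rates are
higher than the unfavorable ones for any unfavorable prevalence — the
calibrated fixture reproduces this as printed, even though it runs against
the usual clinical gradient.  The 41-week logistic curve itself remains
monotone non-increasing in the score; the inversion is carried by the
week-39/40 context parameters.

The unfavorable-cervix subgroup cesarean rate uses the subgroup as its
denominator.  The `synthetic_default` fixture is a pure prior draw
(beta(1.5, 8) for common branches, beta(1, 600) for rare ones) used for
property testing; generated sets are exchangeable with hand-written
configurations everywhere in the pipeline.

## Statistical analyses

Arm contrasts use the uncorrected chi-square test on the 2×2 event table
(1 df), computed from the closed-form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) and
cross-checked in the test suite against an independent library
implementation.  The continuity correction is deliberately off — the
0-versus-1-event maternal mortality contrast at 100,000 per arm gives the
reference p ≈ 0.317 only without it — and is available behind a flag; when
a table has an empty cell a Fisher exact p-value is reported alongside.
Differences are expressed per 100,000 deliveries, and the cesareans-averted
figure is the rate difference × 100,000; the single costing quantity is
that count times the excess cost of a cesarean over a vaginal delivery
(≈ $3,900), with no discounting or further cost-effectiveness structure.

One-way sensitivity sweeps re-simulate both arms per grid value under
common random numbers and declare the higher-mean-dyad-utility strategy
optimal (ties within 1e-12 are "indifferent"); adjacent verdict flips are
reported as crossover intervals.  The probabilistic sensitivity analysis
redraws the full parameter vector per replicate (each replicate's
substream derived from (seed, draw index)) and reports winner frequencies.
Saturation runs start at 100,000 patients and double (capped at 1,000,000)
until every headline rate moves less than the tolerance between stages; a
first stage whose headline rates all have zero binomial variance is
treated as already saturated.

## Problem sizes used in the shipped analyses

The acceptance script simulates 100,000 patients per arm for the headline
rates, 100,000 per arm per grid point for the five-point preference sweep,
and 100 PSA replicates of 10,000 patients per arm; the test suite uses
cohorts between 10 and 200,000 depending on the property under test.
These sizes put binomial noise well inside the reported precision (4
standard errors at n = 100,000 is ±0.6 percentage points at a 35.9% rate
and ±0.05 points at a 0.13% rate).

## Limitations

* The calibrated fixture reproduces the reference *marginal* rates but is
  not a transcription of the original evidence table; conclusions about
  mechanism (e.g. which labor-onset path drives the cesarean gap) reflect
  the calibration's degrees of freedom, not evidence.
* Operative vaginal delivery, antenatal fetal surveillance, perineal
  trauma and labor-management variation are not modeled.
* The utility arithmetic for morbid states is a declared stand-in
  consistent with the stated ranges and ratios; utility-based results
  (mean dyad utility, sweep verdicts) should be read with that in mind,
  while all rate-based results are unaffected.
* Synthetic cohorts share the independence assumptions of the tree:
  passing property tests demonstrates internal consistency of the
  implementation, not external validity of the probabilities.
* No quality-adjusted life-expectancy framing and no formal
  cost-effectiveness analysis are attempted.
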