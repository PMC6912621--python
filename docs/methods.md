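# Methods

This note documents the models, conventions and design choices behind
`drinkstates`, in the spirit of a statistical package's model
documentation.  It states no empirical result beyond what the test suite
and `scripts/acceptance.py` compute themselves.

## Data model

The unit of observation is a diary week: 7 daily standard-drink counts
for one student at one wave.  Four waves (baseline, 7, 14, 20 weeks) are
concatenated, Monday-first, into one 28-day sequence per student, with
no modelling of the gaps between the observed weeks — the sequence is
treated as a single record, and the wave spacing enters only through the
wave index used by the trend analysis.  Nonresponse is
questionnaire-level, so missingness acts on whole weeks: a dropped wave
is 7 jointly missing days.  Missing days are marginalized in every
likelihood (emission probability 1), which is exact under missingness at
random; nothing is imputed.

## Weekly outcomes

- **Quantity**: sum of the 7 daily counts.  **Frequency**: days with ≥ 1
  drink (a day is at most one occasion, matching the one-count-per-day
  diary).  **Binge occasions**: days at or above 4 (women) / 5 (men)
  drinks — the conventional gendered heavy-episodic threshold;
  configurable.
- **eBAC** (Widmark): `100·(drinks·12 g)/(weight_g·r) − 0.017·hours`,
  floored at 0, with r = 0.68 (men) / 0.55 (women); these are the
  conventional Widmark constants and all are configurable.  The weekly
  mean averages over all 7 days including zeros; the monthly peak is the
  maximum single-occasion value over the recall window (here the wave's
  observed week).  Output is available in percent (g/dL) or per-mille
  (g/L, exactly 10× percent) because the two scales are both used in
  this literature and are easy to confuse.
- **Hazardous** use: AUDIT ≥ 6 (women) / ≥ 8 (men).  **Excessive**
  drinking: quantity > 9 / > 14 drinks per week (Swedish national
  recommendation), evaluated per wave.
- A fully missing week yields missing outcomes, never zero.

## The hidden Markov model

One parameter set is shared across the cohort (a population HMM);
sequences are independent realizations.  The emission family is a
per-state *hurdle*: Bernoulli drinking indicator (probability p_k) times
a zero-truncated Poisson (rate λ_k) for the count given drinking.  The
hurdle makes the dominant zero mass explicit, keeps every parameter
interpretable (7·p_k is the state's expected drinking days/week), and
gives a well-defined free-parameter count for BIC:
(K−1) + K(K−1) + 2K.  A Bernoulli-only family (drinking indicator, one
parameter per state) is available for sensitivity checks.

Numerics: the forward–backward recursions use per-step scaling,
vectorized across all sequences (mathematically equivalent to log-space
accumulation; 28-step products underflow in unscaled linear space).
Emissions are evaluated once per distinct observed count and gathered,
since drink counts repeat heavily.  Viterbi runs in log space with ties
broken toward the lower state index.

Estimation is Baum–Welch EM.  Initialization is random: Dirichlet(1)
for π and the rows of A, p_k ~ U(0.05, 0.95), λ_k ~ U(0.5, 8); 20
restarts by default.  Restarts use a short-run strategy (every restart
runs 25 iterations; the best three continue to convergence), a standard
device that retains the local-optimum protection of many restarts at a
fraction of the cost.  Convergence is a relative log-likelihood change
below 1e-6 (500 iterations cap); the observed-data log-likelihood is
checked to be nondecreasing within 1e-8 at every step.  The M-step for
λ_k inverts the zero-truncated-Poisson mean equation
m = λ/(1−e^{−λ}) by bracketed root finding; weighted means ≤ 1 map to a
small floor (1e-3), and p_k is kept 1e-6 off the simplex boundary when
evaluating emissions.  Label switching is handled only at evaluation
time (matching estimated to generative states), never inside EM.

Model selection minimizes BIC over a K range, with n defined as the
total number of observed (non-missing) student-days — the most common
convention for sequence-model BIC; ties go to the smaller K.

## State interpretation

- **Frequent-heavy state**: among states with expected drinking days
  7·p_k ≥ 3.5 and self-transition A_kk ≥ 0.5, the one with the largest
  7·p_k (ties to the larger A_kk); none may qualify.  The thresholds
  operationalize "drinks several days a week" and "very stable" and are
  configurable and echoed in every report.
- **Weekday labels**: the remaining states are labelled with the
  calendar weekday (position mod 7, Monday-first) holding the largest
  share of their decoded occupancy, if that share reaches 0.5;
  otherwise they stay unlabelled.
- **Membership**: from Viterbi paths over observed days only —
  *continual* if every observed day is the frequent-heavy state,
  *itinerant* if some are and some are not, *non-member* otherwise;
  students with zero observed days are excluded with a warning.
- **Group comparisons**: total frequent-heavy (continual + itinerant)
  versus everyone else; Welch two-sample t (with Welch–Satterthwaite
  df) for continuous baseline variables, pooled two-proportion Z for
  binary ones.  Group 1 is the frequent-heavy group, so positive
  statistics mean larger there.
- **Trend analysis**: day-level logistic regression of the drinking
  indicator on wave (0–3), arm, and wave×arm, within the membership
  stratum, with cluster-robust (by student) standard errors; the
  exponentiated interaction is the trend odds ratio.  This is the
  simplest maximum-likelihood estimator consistent with an arm-wise
  change in daily drinking probability per wave; contrasts involving
  the nested add-on arms use waves 1–3 only, since the add-on starts at
  the first follow-up.  Separation and degenerate strata are flagged,
  not estimated.

## Synthetic cohort generator

The generator emulates the study design the analysis targets, and its
defaults are the package's fixed study conditions:

- n = 2166 students, 1:1:1 block randomization to control /
  promillekoll / partyplanner; 67.5% women; age ~ N(25.6, 6.2²) (≥18);
  AUDIT ~ round N(10.8, 4.1²) clipped to 0–40; motivation ~ round
  N(4.0, 2.6²) clipped to 0–10; weight ~ N(70, 10²) kg women /
  N(82, 12²) men, truncated at 45 kg (plausible Swedish student
  anthropometrics; a fixture choice).
- Eight latent classes: seven *weekday* classes that drink on one
  specific day (own-day probability 0.85, off-day 0.06), with
  weekend-weighted prevalences (Mon–Sun: 0.03, 0.05, 0.08, 0.12, 0.28,
  0.23, 0.14) and per-occasion quantities rising into the weekend
  (2.2–5.8 mean drinks), and one **frequent-heavy** class (prevalence
  0.07) drinking 65% of days (4.55 expected days/week) at 3.6 drinks
  per occasion.  The frequent-heavy class carries covariate shifts
  (+3.9 years age, +3.0 AUDIT, +0.8 motivation, +0.88 male log-odds) so
  that group comparisons have a known direction.  Weekday separation in
  prevalence and quantity is what makes the classes identifiable to the
  HMM; the distinct own-day patterns are also what the weekday
  labelling step is designed to recover.
- Day-to-day dynamics: a sticky Markov chain over the classes.  A
  student keeps their current behavioural pattern each day with that
  class's persistence (0.99 weekday classes, 0.995 frequent-heavy);
  switching moves them to a uniformly random other class, whose
  persistence then governs them.  Switches are lasting behavioural
  changes rather than day trips — which is what makes some members of
  the frequent-heavy pattern itinerant (they leave it at some point)
  rather than continual.  Short latent spells still occur when a
  student switches twice in quick succession; spells of only a few days
  are intrinsically hard for any decoder to separate from noise, a
  limit that the membership-classification accuracy inherits.
- Quantities given drinking are zero-truncated Poisson parameterized by
  their mean — deliberately the same family as the HMM emission, so
  parameter recovery is well-posed.  The `quantity_dispersion` field is
  validated but inert under this family (reserved for overdispersed
  alternatives).
- Arm effects: an additive per-wave shift on the daily drinking
  log-odds, by default −0.05 (control), −0.0796 (promillekoll), −0.0696
  (partyplanner) — i.e. drinking declines everywhere, least in the
  control arm, with a control-vs-promillekoll trend odds ratio of
  exp(0.0296) ≈ 1.03 and a partyplanner-vs-promillekoll ratio of
  exp(0.01) ≈ 1.01 per wave.
- Missingness: each follow-up wave is observed with probability 0.78 /
  0.62 / 0.65 (within the 55–83% response band typical of app studies),
  whole weeks at a time, optionally modulated by observed baseline
  covariates through `mar_coef` (MAR by construction); the baseline
  wave is never dropped.
- The add-on assignment mirrors the nested design: app-arm students
  excessive at the observed wave-1 diary split 1:1 into telecoach /
  waitlist; control-arm students excessive at baseline become the
  assessment-only comparison group.
- Hours per occasion default to max(1, drinks/2) — no duration model is
  part of the design being emulated; this keeps eBAC in plausible
  ranges and is configurable.  Each wave is treated as an actually
  observed week (not a "typical week" report).

What the generator does *not* emulate: AUDIT item-level responses, app
usage/engagement, within-week correlation beyond the class structure,
seasonal/holiday effects, misreporting, or informative (MNAR) dropout.
Passing tests therefore demonstrate that the estimators recover the
structure they assume, at realistic sizes and missingness — not that
real diary data satisfies those assumptions.

## Problem sizes used in validation

The test suite and acceptance script choose sizes that keep full runs
tractable on one CPU while leaving sampling error well inside the
tolerances tested: oracle equivalence on 50 random instances (K ≤ 3,
T ≤ 8) against exhaustive path enumeration; parameter recovery on 500
sequences; BIC selection on ten seeds of a 3-class n = 300 cohort and
ten seeds of the default 8-class n = 1000 cohort over K = 6–10 with 12
restarts; trend calibration on 20 null seeds (n = 300) and 10
slope-difference seeds (n = 400); and one full n = 2166 pipeline run in
the acceptance script.  The default weekday cohort's BIC-optimal K
typically lands at 8–9: the seven weekday patterns plus the
frequent-heavy state, with the extra state (when selected) absorbing
the off-day/rest structure the generator's excursions create.

## Known limitations

- The population HMM has no covariate-dependent transitions and no
  student-level random effects; heterogeneity within a state is
  averaged.
- The weekday labelling assumes Monday-anchored diaries; diaries
  anchored on other days would permute the labels.
- BIC with the observed-day n convention can over-penalize when
  missingness is heavy, since information per free parameter is not
  uniform across states.
- The hurdle ZTP cannot represent overdispersed drinking quantities; a
  negative-binomial hurdle would be the natural extension.
- The trend estimator conditions on decoded membership, ignoring
  decoding uncertainty; a fully joint model would propagate it.
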