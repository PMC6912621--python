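# drinkstates

Latent drinking-state analysis of weekly drinking diaries from a
three-arm smartphone-app trial design in university students.

Students in such trials report, at each of four waves (baseline, 7, 14
and 20 weeks), how many standard drinks they had on each day of one week.
`drinkstates` turns those diaries into the standard drinking outcomes,
discovers latent drinking states in the 28-day records with a hidden
Markov model written for this data type, identifies the small
*frequent-heavy* subgroup that drinks most days of the week, and
estimates how the trial arms differ in their drinking-probability trends.
Because participant-level trial data of this kind is rarely shareable,
the package ships a synthetic cohort generator with the same statistical
structure, so the entire pipeline is testable and demonstrable end to
end.

It is aimed at biostatisticians and addiction researchers working with
Daily Drinking Questionnaire–style diaries in longitudinal or randomized
designs.

## The model

Each student contributes a sequence of 28 daily drink counts
(4 waves × 7 days, Monday-first, concatenated).  A single hidden Markov
model is shared by the whole cohort: initial distribution π, transition
matrix **A**, and per-state *hurdle* emissions — state *k* produces a
drinking day with probability *p<sub>k</sub>* and, given drinking, a
zero-truncated Poisson count with rate λ<sub>k</sub>:

    P(y | k) = 1 − p_k                            if y = 0
    P(y | k) = p_k · Poisson(y; λ_k) / (1 − e^{−λ_k})   if y ≥ 1

Missing diary weeks are marginalized exactly (their emission term is 1),
which is the likelihood-based handling appropriate under missingness at
random.  Parameters are estimated by Baum–Welch EM with random restarts;
the number of states K is chosen by minimizing
BIC = −2·logL + #params·ln(n), with n the number of observed
student-days.  Decoded Viterbi paths drive the downstream analysis:
states are labelled by the calendar weekday they occupy, the
frequent-heavy state is the sticky state with the most expected drinking
days per week (7·p<sub>k</sub> ≥ 3.5, A<sub>kk</sub> ≥ 0.5), its members
are classified *continual* (never leave it) or *itinerant* (enter and
leave), and arm contrasts on the daily drinking probability are
estimated by day-level logistic regression with student-clustered robust
standard errors.

Weekly outcomes follow the conventions of this literature: quantity
(drinks/week), frequency (drinking days/week), binge occasions
(days ≥ 4 drinks for women / ≥ 5 for men), estimated blood alcohol
concentration by the Widmark formula
(eBAC = 100·grams/(weight·r) − β·hours, floored at zero, r = 0.68 men /
0.55 women, β = 0.017 %/h, 12 g per Swedish standard drink), hazardous
use (AUDIT ≥ 6 women / ≥ 8 men) and excessive weekly drinking
(> 9 / > 14 drinks per week).

## Worked example

```python
import drinkstates as ds

cfg = ds.SimConfig(n_students=500, seed=1)          # trial-like cohort
report = ds.run_pipeline(ds.PipelineConfig(
    sim=cfg, k_range=range(6, 11), n_restarts=12, seed=1))

print(report.best_k)
print(report.best_fit.summary())
fh = report.fh_report
print(fh.n_members, fh.n_continual, fh.n_itinerant)
```

prints (seed 1, n = 500):

```
9
Hurdle HMM fit: K=9 states, emission=hurdle
  sequences: 500, observed days: 10703
  log-likelihood: -8261.008   BIC: 17431.287   free params: 98
  converged: True after 290 iterations (12 restarts, seed=988257097)
  state   pi      p(drink)  E[drinks|drink]  self-transition
      0  0.111   0.061        4.41          0.000
      1  0.311   0.033        5.19          0.001
      2  0.008   0.839        4.63          0.007
      3  0.091   0.034        4.50          0.001
      4  0.117   0.168        2.11          0.976
      5  0.210   0.044        4.81          0.001
      6  0.071   0.049        4.96          0.000
      7  0.037   0.054        4.59          0.000
      8  0.045   0.642        3.62          0.997
28 22 6
```

The BIC-minimizing model has nine states.  State 8 is the
frequent-heavy state: drinking on 64% of days (≈ 4.5 days/week) with a
0.997 self-transition; the low-p states are the weekday phase states the
Monday-anchored sequences induce, and state 4 absorbs residual off-day
drinking.  28 of the 500 students are decoded into the frequent-heavy
state (7% generative prevalence), 22 of them continually.
`report.fh_report` also carries Welch-t / two-proportion-Z baseline
comparisons of that group against the rest, and the cluster-robust trend
odds ratios per arm contrast.

The same pipeline runs from the command line:

```
drinkstates run-all -n 500 --seed 1 --k-min 6 --k-max 10 -o results/
drinkstates simulate -n 2166 --seed 7 -o data/
drinkstates fit-hmm --diaries data/diaries.csv --k-min 6 --k-max 10
```

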