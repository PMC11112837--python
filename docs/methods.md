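# Methods

## Scope and data model

The package evaluates a two-grader diabetic-retinopathy screening cohort:
each eye carries an ordinal grade from a reference grader (an
ophthalmologist, treated as the gold standard throughout) and from an
automated grader, plus a binary maculopathy call from each.  Grades use a
collapsed 4-level ICDR analysis scale — none (0), mild NPDR (1), moderate
NPDR (2), severe NPDR/PDR (3).  Severe NPDR and proliferative disease are
pooled because the agreement analysis operates on four ordinal categories
and the top two clinical stages are managed identically at referral.

Eyes with an image of insufficient quality carry an `UNGRADABLE` sentinel
that never participates in ordinal comparison.  An eye is excluded from
every paired statistic when **either** grader flags it ungradable: an eye
one grader cannot read cannot contribute a pair.  In the packaged fixture
both graders flag the same two eyes, so the either/both choice is
unobservable there; the rule matters only for generated cohorts with
discordant quality flags.

## The reconstructed pilot cohort

`oslo_fixture()` rebuilds, eye by eye, a pilot screening cohort of 33
patients (66 eyes; 2 concordantly ungradable) from its published marginal
summaries.  The published grade shares over the 64 gradable eyes —
(81, 3, 11, 5)% for the reference grader, (81, 6, 8, 5)% for the
automated one — are converted to integer counts by largest-remainder
rounding to a sum of 64, giving marginals (52, 2, 7, 3) and (52, 4, 5, 3).
Given perfect binary any-DR agreement (12 positives per grader, implied by
100% sensitivity and specificity) the unique joint table consistent with
both marginals places the only disagreements as two moderate-NPDR eyes
read as mild by the automated grader.  Two eyes are maculopathy-positive
by both graders (2/64 = 3.1%); the fixture attaches them to severe-grade
eyes, an arbitrary but fixed placement that no computed statistic depends
on.  On this table the linear weighted kappa is 0.9509, the quadratic
0.9778, and the Spearman rank correlation 0.9984 — one reconstruction
simultaneously reproducing the several agreement figures reported for the
cohort, which we take as strong evidence the reconstruction is exact.

## Agreement statistics

Weighted Cohen's kappa is computed from the k×k contingency table as
κ_w = (Po_w − Pe_w)/(1 − Pe_w) with Po_w = Σ w_ij p_ij and
Pe_w = Σ w_ij r_i c_j.  Weight schemes: identity (recovers the unweighted
statistic exactly), linear w_ij = 1 − |i−j|/(k−1), and quadratic
w_ij = 1 − (|i−j|/(k−1))².  **Linear is the default**: it is the scheme
that reproduces the fixture's reported 4-level agreement of 0.95
(quadratic gives 0.98).  Unused categories keep their empty rows/columns
so weights stay defined over the full scale; kappa is undefined (raised,
not returned) when expected agreement is 1.

The standard error is the Fleiss–Cohen–Everitt large-sample variance of
weighted kappa; the p-value is a two-sided z-test of κ = 0 using the
null-hypothesis variance.  The source report states only significance
thresholds, so the exact test it used is unknowable; the choice is
recorded in the result metadata and cross-checked against statsmodels in
the test suite.  Landis–Koch verbal bands use upper-inclusive intervals
(≤ 0.20 poor, ≤ 0.40 fair, ≤ 0.60 moderate, ≤ 0.80 good, else very good),
with negative kappa falling in "poor".

Spearman's rho (average ranks for ties) is included because it is the
natural ordinal companion statistic; it is reported with its p-value and
declared undefined on zero-variance input.

## Diagnostic accuracy

Grades are dichotomised at one of two clinical thresholds: **any DR**
(grade ≥ 1, the default — it reproduces the reported 12/64 = 18.8%
prevalence) or **referable DR** (grade ≥ 2, the threshold automated
graders typically target).  The manual grader is the reference standard;
prevalence, sensitivity, specificity and accuracy are proportions with
binomial CIs.  A metric with a zero denominator is reported as undefined
(`None`/`null`), never as 0.

CI methods and defaults:

* `clopper_pearson` (default for sensitivity, specificity, accuracy, and
  rare-outcome prevalence such as maculopathy): exact beta-quantile
  bounds, at-least-nominal coverage by construction; lower bound
  (α/2)^(1/n) when x = n.
* `wald` (default for the headline disease prevalence): p ± z·√(p(1−p)/n),
  clipped to [0, 1].  These defaults are the unique standard pairing that
  reproduces every printed interval digit in the source report's summary
  table; both are selectable per metric.
* `wilson`: score interval, always within [0, 1]; the x = 0 and x = n
  endpoints are set to exactly 0 and 1 (their analytic values) to avoid
  floating-point cancellation.

Report percentages are rounded half-up to one decimal.  The source report
itself mixes rounding and truncation: its Wald lower bound for 12/64
prints as 9.1 where the computed value is 9.19 → 9.2, and its specificity
lower bound prints 93.1 where 52/52 gives 93.15 → 93.2.  The package
rounds consistently and does not chase those two truncated digits.

## Cost-minimization model

Both strategies are assumed equally effective (supported by the perfect
binary agreement), so the comparison is purely of cost, in USD:

    total/patient = visits × (screening_cost
                              + transport_cost_round_trip × transport_multiplier
                              + patient_time_hours × time_cost_per_hour)

Packaged baselines (one visit each): manual — fee $164 (DRG weight for
fundus photography incl. screening), 1.5 h patient time; automated — fee
$33 (US government-program reimbursement, 2021), 1 h; both with $73
round-trip transport and $24/h time cost.  Grader labour is excluded
(assumed equal across strategies).  An NOK→USD converter (default 9.89
NOK/USD) supports re-basing the Norwegian cost inputs.

Two deliberate modelling decisions where the source text is internally
inconsistent:

* The source text describes doubling the transport cost for the round
  trip, but its own printed totals ($273 = 164 + 73 + 36) enter $73
  exactly once.  The model follows the totals: `transport_cost_round_trip`
  is the full round-trip amount, applied once per visit.  A
  `transport_multiplier` knob (default 1) lets the literal doubling be
  explored.
* The stated parameters give an automated-strategy total of $130/patient,
  consistent with the printed $143 saving (273 − 130); the source
  nevertheless prints $131/patient, $4323 for 33 patients and $6666 for a
  half-and-half mixture.  The model computes from the stated parameters:
  $130, $4290 and $6649.50.  The $1-per-patient deltas are documented
  here and are not targets.

All arithmetic is double precision with no intermediate rounding;
currency rounding (half-up to whole dollars) happens only at report time.

## Sensitivity analyses

One-way and two-way deterministic sweeps substitute grid values into
copies of a base strategy (bases are never mutated) and tabulate both
per-patient totals and their difference; two-way sweeps evaluate the full
cartesian product with entry (i, j) at (grid1[i], grid2[j]).  Default
grids mirror the evaluated ranges: automated fee $33–$164 (up to the
manual DRG weight), manual patient time 0.5–2 h, automated patient time
5 min (1/12 h, stored unrounded)–2 h; endpoints inclusive, step counts
configurable.  Because the model is affine in every parameter, sweep
differences have exactly zero second differences — a property the tests
assert — and the break-even value is solved in closed form from two
evaluations, with a bisection fallback retained for non-affine strategy
extensions.  Numeric tables (long-format CSV/JSON) are the contract;
plotting is left to the caller.

## Synthetic cohort generator

`generate_cohort` emulates a screening day: each of `n_patients`
contributes `eyes_per_patient` eyes; the reference grade of each eye is an
i.i.d. draw from `grade_probs`; the automated grade is drawn from the
row of a 4×4 row-stochastic confusion matrix conditioned on the reference
grade.  Each eye has one latent maculopathy state (Bernoulli
`maculopathy_prob`) reported by every grader with a readable image — the
generator has no maculopathy-disagreement parameter because the emulated
cohort shows perfect maculopathy concordance.  Image-quality failures are
per-eye Bernoulli events (`ungradable_prob`); the automated grader flags
the same eye with probability `ungradable_concordance` (default 1,
matching the emulated cohort where both graders flagged the same two
eyes).  All randomness flows from a single seed through one
`numpy.random.Generator` per call; no global state.

Defaults are the emulated study's conditions: 33 patients × 2 eyes, grade
shares (81, 3, 11, 5)%, maculopathy 3%, ungradable 1/33 per eye, and a
confusion matrix whose only off-diagonal mass is moderate→mild at 2/7
(the observed disagreement rate among moderate eyes).

What the generator does **not** emulate: within-patient correlation
between fellow eyes (real DR is strongly bilateral; grades here are
independent across eyes), grade-dependent image-quality failure,
maculopathy–grade association, and any grader drift or learning.  Tests
passing on synthetic cohorts therefore validate the statistical machinery
and its calibration under independence, not the clinical behaviour of any
particular grading system.

## Numerical and degenerate-input conventions

* Kappa with Pe = 1, rank correlation with zero variance, metrics on an
  empty table, and empty gradable cohorts raise typed errors rather than
  returning sentinel numbers; the pipeline report records such statistics
  as `null` with the reason.
* Probability vectors must sum to 1 within 1e-9; confusion matrices must
  be row-stochastic within the same tolerance.
* Grade shares in reports are rounded half-up to whole percent (the
  fixture's shares then sum to exactly 100).
* Break-even tolerance is 1e-9 on the cost difference; the closed form
  and bisection agree to 1e-6 on random affine instances in the tests.

## Problem sizes used in the test suite

The suite is desk-scale by design: the fixture analyses run on 64 eyes in
milliseconds; law-of-large-numbers checks use 2,000-patient cohorts;
exact-coverage enumeration spans all n ≤ 25 against a 0.05 grid of true
proportions; and the parameter-recovery study uses 200 replicate cohorts
of 5,000 patients (10,000 eyes) with known binary sensitivity 0.9 and
specificity 0.95, asserting ≥ 90% CI coverage of the generating values.
The full suite completes in well under a minute on one CPU.

## Known limitations

* The cost model is a cost-minimization: no effectiveness differences, no
  discounting, no multi-year horizon, no QALYs, no probabilistic
  sensitivity analysis.
* Agreement is two-grader only; no multi-rater kappa or Krippendorff's
  alpha, and no bootstrap CIs for kappa.
* The diagnostic module reports no ROC/AUC (the graders emit categories,
  not scores) and no predictive values re-weighted to external prevalence.
* The fixture encodes one published cohort; its per-eye layout beyond the
  published marginals (which patients carry disease, where maculopathy
  sits) is an arbitrary fixed choice that paired statistics are invariant
  to.
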