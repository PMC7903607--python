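# Methods

This note records the models implemented in `cpa`, the assumptions behind
them, and the design choices made where the procedure was genuinely open.

## Data model

A cohort is a patient × clinotype float matrix with `NaN` as the missing
marker, accompanied by two aligned matrices holding each record's reference
range.  Ranges are stored **per record**, not per clinotype, because they
depend on the individual (sex-specific Hematocrit ranges: 35–45% for women,
40–50% for men).  A value is annotated *low* when it falls strictly below
its range, *high* strictly above, *normal* otherwise; endpoint values are
normal (the inclusive convention — the boundary rule is not dictated by the
procedure itself, so we fixed the common one).  Imputed cells carry no
recorded range and therefore stay unannotated.

Repeated measurements of the same (patient, clinotype) are collapsed to the
most recent dated record — a "current state" snapshot that is deterministic
under re-reads.  The patient's earliest record date is retained for the
temporal split.

## Preprocessing cascade

* **Rarity filter.**  A clinotype is dropped when observed by fewer than
  `max(min_patients, ⌈min_fraction·n⌉)` patients (defaults 1000 and 1%).
  The two printed criteria nearly coincide at the cohort scale the defaults
  were written for, so the composite `max` keeps both honest.  The bound is
  strict: a clinotype observed by exactly the bound survives.  Patients
  left with no observed values, and pediatric patients (age < 18 at their
  earliest record), are removed.
* **Temporal split.**  Patient-level: a patient joins the training side
  (Pr) iff their earliest record is on or before the cutoff date (default
  2013-06-30).  A record-level split would let one patient straddle both
  sides and leak information into validation, so the patient-level variant
  was chosen.  The synthetic generator's default study window
  (2010-07-01 … 2014-06-30) makes this cutoff a 3:1 split in expectation.
* **Normalization.**  z-scores with mean and *sample* (n−1) standard
  deviation computed on Pr only; at cohort scale the n vs n−1 distinction
  is irrelevant, and the sample estimator is the statistical default.  Both
  reference-range endpoints are transformed with the same affine map, which
  makes annotation exactly invariant under normalization (a tested
  property).  Zero-variance clinotypes are excluded from modeling with a
  warning.

## ε-insensitive linear SVR (the imputer)

For target clinotype *y* with predictors *x* (all other clinotypes):

    minimize   ½‖w‖² + C Σₙ ξₙ
    subject to |wᵀxₙ + b − yₙ| ≤ ε + ξₙ,   ξₙ ≥ 0.

A single slack per sample is equivalent to the textbook ξ/ξ\* pair since at
most one side of the band can be violated when ε ≥ 0.  Defaults C = 1,
ε = 0.001.

**Solver.**  The dual — minimize ½βᵀKβ − yᵀβ + ε‖β‖₁ over β ∈ [−C, C]ⁿ with
Σβ = 0, K = XXᵀ — is solved by sequential minimal optimization: the first
working-set coordinate minimizes the right directional derivative among
box-feasible increases, the second maximizes the second-order gain
(violation²/curvature), and the one-dimensional subproblem is minimized
exactly over its breakpoints (the ℓ1 kinks, the box ends, and the
per-sign-piece quadratic minimizers).  The inner loop is JIT-compiled with
numba.  The intercept is recovered afterwards by exact minimization of the
piecewise-linear primal in *b*; when the optimum is a flat interval the
midpoint is taken, so a constant target *y = c* yields (w, b) = (0, c).
Solutions are certified in the tests by the primal–dual gap (≤ 10⁻⁶
relative) and cross-checked against a generic convex solver
(`scipy.optimize` trust-constr on the primal QP) and libsvm.  Tolerances:
standalone fits stop at KKT violation 10⁻⁸; the resampled imputation fits
default to 10⁻⁴, where coefficients are already stable to ~10⁻⁴ while
degenerate noiseless instances (rank-deficient K, tiny ε) stay fast.

**Balanced resampling.**  Lab data are dominated by "normal", so each of
`n_repetitions` (default 50) repetitions trains on a 1:1:1 under-resample:
m indices per class without replacement, m = smallest class count.
Repetition r draws with seed `base_seed + r`.  The model reports the
arithmetic mean of the per-repetition (w, b) and keeps the full archive.
If a target lacks a class entirely, resampling downgrades to the available
classes with a logged warning rather than refusing (configurable).

**Prediction.**  Missing predictor entries are set to 0 — the mean on the
normalized scale — in a single pass; no chained iteration.  This preserves
sample size and keeps prediction defined under any missingness pattern, at
the cost of attenuating coefficients when predictors are missing often.  A
cell whose predictors are all missing is filled with 0 and flagged
degenerate.

**Evaluation.**  Observed test cells are predicted, both prediction and
truth are annotated against the cell's (normalized) range, and the pair is
mapped to a confusion cell with abnormal as the positive class:

| true \ predicted | high | normal | low |
|---|---|---|---|
| high   | TP | FN | FP |
| normal | FP | TN | FP |
| low    | FP | FN | TP |

A high↔low swap is deliberately a false positive: predicting the wrong
direction of abnormality is a clinically misleading positive call.  Under
independent uniform-random truth and prediction all nine cells are
equiprobable (1/9), giving expected ACC = PPV = NPV = 1/3 exactly — the
random baseline the tests and the acceptance script recompute.  Ratios
with a zero denominator are reported as undefined (never 0) and excluded
from across-clinotype averages, which weight by evaluated-cell counts.

**Clinotype–clinotype associations.**  The per-repetition coefficient
archives yield association candidates: pair (target, predictor) is flagged
when the coefficient sign is constant in ≥ 95% of repetitions *and* the
averaged |coefficient| exceeds 0.1 normalized units; symmetric duplicates
keep the larger effect.  Two caveats are inherent and documented by tests:
(i) balanced tail-enrichment thins the density near the conditional median,
inflating the ε-insensitive estimator's noise — the 0.1 floor is calibrated
for cohorts of roughly 10⁴ patients and will over-flag on small cohorts;
(ii) collinear predictors produce large opposite-signed coefficient pairs
that pass the stability gate, so flagged pairs among highly correlated
clinotypes should be read jointly, not marginally.

## Association screen and validation

Controls are patients with < 5% abnormal values among their *observed*
cells and no diagnosis history; disease cohorts match an ICD-10 prefix
case-insensitively.  The per-clinotype screen is a two-sided two-sample
Student t-test (pooled variance by default, matching the cited test; Welch
behind a flag), with the raw p < 0.05 rule as the default and
Benjamini–Hochberg as an option — raw is the default so that
published-style counts are reproducible on synthetic replays.  Screening
for validation uses training patients only.  Validation fits a
pluggable classifier (default: 100-tree random forest, seeded) twice — on
the associated clinotypes (ASS) and on the complement (NON) — on Pr and
scores AUC/ACC/PPV on Pt.  The two feature sets partition the clinotype
set by construction.  Note that healthy-control selection itself makes
every clinotype mildly informative (controls are centered by design), so
NON AUCs sit above 0.5 even for pure-noise features; the validation claim
is the ASS > NON *ordering*, not NON ≈ 0.5.

## Stratification

Distances are Euclidean over imputed normalized values (the metric was an
open choice; Euclidean matches the z-scored scale).  The default backend is
a deterministic-annealing pairwise clustering: soft memberships M are
iterated to the mean-field fixed point of the pairwise cost
ε(i,c) = avg-distance(i → c) − ½·avg-within(c) at temperature T, with
T starting at the largest observed distance, geometric cooling (factor
0.95, floor 10⁻³·T₀), convergence tolerance 10⁻⁶ on membership change,
tiny multiplicative jitter per temperature step to break cluster-collapse
symmetry, and a zero-temperature hard reassignment pass at the end.  Runs
that still converge with an empty cluster are retried with a perturbed
initialization (3 attempts).  A PAM k-medoids backend (best of 5 seeded
restarts) serves as an algorithmically independent cross-check; both agree
(ARI ≥ 0.95) on separated synthetic mixtures.

k is selected by maximizing the mean silhouette width computed directly
from the distance matrix; points in singleton clusters contribute 0 (the
standard convention).  Clusters are annotated by one-way fixed-effects
ANOVA per clinotype (significant iff p < 0.05; degenerate zero-within-
variance cases are flagged, with F = 0, p = 1 when group means also
coincide), and by hypergeometric disease enrichment: the upper-tail
probability of ≥ κ carriers in a cluster of size η given Κ carriers among
Ν patients, computed with log-space stable routines (`scipy.stats.
hypergeom.sf`) and verified against exhaustive enumeration for all Ν ≤ 12.
Ν counts all patients in the normalized cohort.

## Name normalization and geneset linking

Clinotype names are stripped of non-biological qualifier terms (seeded
with: absolute value, percentage, ratio, volume, count, concentration,
width, mean, distributed — configurable, since assay-name conventions
vary), then singularized by trailing-'s' removal with an irregular-form
exception map.  The query term is matched as a case-insensitive substring
(spaces also tried as underscores) against geneset names from local GMT
files; matching semantics against curated databases are not standardized,
so substring matching is an explicit, documented stand-in.  Gene-identifier
unification is reduced to symbol-level deduplication; cross-namespace ID
mapping would require live external services and is out of scope.

## Synthetic cohort generator

The generator is the test bed standing in for a private hospital cohort.
Defaults, chosen once:

* **Demographics** — six adult strata (young 18–39 / middle 40–59 / old
  60+ × male/female) at proportions 21.33 / 18.41 / 27.36 / 20.66 / 7.61 /
  4.63%, the published shape of a large checkup population.
* **Study window** — one visit date per patient, uniform over
  2010-07-01 … 2014-06-30, so the 2013-06-30 cutoff gives the 3:1 split.
* **Values** — a standardized latent z per clinotype built by a forward
  pass through a linear-Gaussian DAG (coefficients over earlier clinotypes,
  intercept, noise sd; optional quadratic term to emulate the nonlinear
  regime where a linear imputer degrades).  The default latent model is
  independent standard normals — dependencies are planted explicitly by
  each experiment so that ground truth is always known.  Raw values are
  `mu + sigma·z` from a per-clinotype, per-sex panel; named panel entries
  use plausible adult values (Hematocrit carries the exact sex-specific
  ranges above), generic entries use mean 100, sd 10.
* **Reference ranges** — centered on the mean at ±1.5 sd (≈ 6.7% of values
  abnormal on each side), wide enough to be lab-like yet populated enough
  that balanced resampling has material class sizes.
* **Effects** — diseases are Bernoulli(prevalence) labels adding a mean
  shift (in sd units) to affected clinotypes; clusters are mixture
  components with per-clinotype mean-shift vectors.  Additive shifts are
  the simplest structure the t-test screen and ANOVA annotation are
  designed to detect.
* **Missingness** — applied last; exactly `round(rate × eligible cells)`
  cells removed.  MCAR is uniform; MAR-by-clinotype upweights a target
  clinotype's cells by the tercile of a driver clinotype (weights
  0.5/1.0/1.5 scaled to the overall rate).  Removed true values are kept
  in the ground truth.

What the generator does **not** emulate: longitudinal trajectories (one
visit per patient), non-numerical results, measurement-device batch
effects, realistic correlation between missingness and diagnosis, and
pediatric cohorts.  Passing tests therefore demonstrate method
correctness under the stated generative assumptions, not performance on
real hospital data.

## Problem sizes used in the checks

The automated checks run at sizes chosen to exercise each property
cleanly: solver oracle equivalence on 20 random instances of ≤ 10 rows ×
≤ 3 features; noiseless imputation recovery on 2000 patients × 10
clinotypes with 5 resampling repetitions (recovery of a noiseless target
does not need the full 50, which remain the default); t-test calibration
on 1000 null replicates (5000 tests) and power at 200 per arm over 100
replicates; ASS/NON ordering over 100 seeded replicates at 100 patients
per arm; cluster recovery on 20 seeded 500-patient mixtures at 6 sd
separation; enrichment against exhaustive enumeration for every
population size up to 12.  The null calibration of the
clinotype–clinotype stability rule uses a 10⁴-patient cohort, the regime
the 0.1 effect floor is calibrated for (see caveat above).

## Known limitations

* Mean-substitution (zero-fill) for missing predictors biases coefficients
  toward zero under heavy missingness; chained or model-based predictor
  imputation was deliberately left out (single pass, as specified).
* The linear imputer underfits nonlinear dependencies; the generator's
  quadratic knob exists precisely to reproduce that failure mode.
* The clinotype–clinotype significance rule (sign stability + effect
  floor) is a documented stand-in — no canonical rule exists for
  coefficients averaged over balanced resamples — and both its caveats
  (cohort-size calibration, collinearity) are stated above.
* Deterministic-annealing clustering optimizes a non-convex objective;
  despite jitter, retries, and the k-medoids cross-check, very overlapping
  mixtures can converge to split/merged variants of the planted structure.
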