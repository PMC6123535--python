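# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices, and the limitations of `icerec`. It is the package's own
account of its design; empirical statements below are limited to what the
test suite and `scripts/acceptance.py` themselves compute.

## Outcome and cost model

The analysis treats a two-arm randomized trial (treatment as usual, TAU, vs
blended treatment, BT) and factorizes the predictive problem per arm and per
target:

    p(o, c | b, tt) = p(o | b, tt) · p(c | b, tt)

Each of the four (arm, target) models is fitted exclusively on patients of
its own arm; the factorization is enforced structurally (the fitting code
never sees the other arm's rows) and verified by perturbation tests.

**QALYs.** EQ-5D-5L response profiles map to utility weights through a value
set (tariff). Utilities are anchored at 1 (perfect health) and 0 (worst
perceivable health); value sets may assign negative weights down to −0.5 for
worse-than-death states. The QALY over the horizon *T* = 0.5 years is the
trapezoidal integral of the utility trajectory with linear interpolation
between measurements at months 0/3/6, so QALY ∈ [−0.25, 0.5]. Measurements
are anchored at the *nominal* month marks (0, 0.25, 0.5 years), not at exact
interview dates; a missing intermediate measurement is bridged by
interpolating directly between its flanking observed points, and a trajectory
ending before the horizon is extended by carrying the last utility forward.
No discounting is applied (irrelevant at 6 months).

Published national EQ-5D-5L tariff coefficients are not redistributable in
this package. `ValueSet` therefore loads any additive decrement table from
CSV, and `synthetic_additive_value_set()` provides a clearly-labelled
synthetic tariff (equal per-dimension decrements summing to 1.5 at the worst
state) for tests and simulation. Real analyses should supply a published
value set by file.

**Societal costs.** cost = Σ quantity × unit cost + hours lost × hourly rate
(+ platform cost iff BT). Unit costs come from a YAML `UnitCostTable`. The
platform cost covers hosting/maintenance and therapist feedback for the
internet-delivered part of BT and is a per-participant constant.

## Learners and evaluation

Six learners: intercept-only mean reference, OLS, ridge, lasso, CART
regression tree, ε-insensitive SVR. Ridge/lasso/SVR standardize features
using training-fold statistics only and leave the intercept unpenalized.
Conventions:

- ridge: minimize ‖y − Xβ‖² + λ‖β‖² (λ = 0 reduces to OLS; solved by SVD);
- lasso: minimize (1/2n)‖y − Xβ‖² + λ‖β‖₁ (coordinate descent; under this
  scaling all slopes vanish at λ_max = max_j |x_jᵀ(y − ȳ)|/n, which the test
  suite asserts via the KKT conditions and, on orthonormal designs, via the
  closed-form soft-threshold solution);
- OLS requires p < n (with all features and p ≥ n it is refused; it re-enters
  after feature selection); rank-deficient designs fall back to the
  minimum-norm solution with a warning;
- SVR iterations are capped at 20 000 (libsvm's SMO can stall on
  near-degenerate linear problems at large C; capped fits are deterministic);
- tree: variance-reduction splits, leaf-mean predictions.

**Evaluation** is leave-one-out cross-validation; per learner and target the
per-arm held-out predictions are pooled over both arms before computing MAE
and RMSE (RMSE ≥ MAE always; asserted). Model-vs-reference comparisons use
the two-sided Wilcoxon signed-rank test on paired absolute errors; if all
paired differences are zero the p-value is defined as 1 with a warning.

**Hyperparameter tuning.** Default grids: ridge λ ∈ {0.01, 0.1, 1, 10, 100,
1000}; tree depth ∈ {2,3,4,5} × min-leaf ∈ {5,10,20}; SVR C ∈ {0.1, 1, 10,
100} × ε ∈ {0.01, 0.1}·SD(y) × kernel ∈ {linear, RBF}. Grid search minimizes
k-fold (k = 5) mean squared error; ties keep the earliest grid entry (grids
are ordered simplest-first). Two workflows exist:

- `loocv(..., nested=True)` (function default): hyperparameters re-tuned by
  inner 5-fold CV inside every LOOCV training fold — no selection leakage;
- `ExperimentConfig.nested_tuning=False` (pipeline default): tune once on the
  full sample, then LOOCV with fixed hyperparameters — the tune-once-then-
  validate workflow typical of applied analyses, and roughly grid×folds
  cheaper. The pipeline and the acceptance tests use this mode; the small
  optimism it can introduce affects all learners and the reference
  comparison equally.

**Feature selection** runs per (arm, target): a log-spaced lasso path from
λ_max downward (100 values, 5-fold CV on standardized features); λ* minimizes
mean CV error and the selected set is the nonzero-coefficient features at λ*.
An empty selection falls back to intercept-only — downstream models then
equal the mean reference — with a warning. Cost models are fitted on the raw
€ scale (so MAE/RMSE are in €); a log-scale mode is deliberately out of scope
for the default pipeline.

## Recommendation rule

With per-patient predicted increments ΔQ = q̂_BT − q̂_TAU and ΔC = ĉ_BT −
ĉ_TAU, the decision rule is net monetary benefit at willingness-to-pay λ
(default 25 000 €/QALY, configurable across the conventional 25 000–35 000
range):

    recommend BT  ⇔  λ·ΔQ − ΔC > 0.

The quadrant case analysis is: NE → BT iff ICER = ΔC/ΔQ < λ; SE → BT
(dominates); NW → TAU (dominates); SW → BT iff the savings per QALY forgone
exceed λ. The NMB formulation was chosen because the threshold rule alone
does not define behaviour in the SW quadrant or at ΔQ = 0, while NMB
reproduces the NE rule and dominance exactly and is division-free; the
equivalence is asserted over an exhaustive sign × threshold grid. Ties
(NMB = 0) go to TAU as the status-quo arm — a conservative, configurable
choice. QALY predictions are clipped to the attainable range [−0.25, 0.5]
and costs floored at 0 before the rule is applied.

**Counterfactual policy value.** Under the recommended allocation,
concordant patients contribute observed (q, c) and discordant patients
contribute the model prediction for the recommended arm. Percent changes are
reported on population totals, which is identical to means for fixed N.
Predictions for discordant patients come from the full-data fits (not LOOCV
fits): the policy question is prospective, and full-data fits are the models
one would deploy. With oracle (ground-truth) predictions the recommended
allocation maximizes total NMB per construction; this is asserted against
the observed and both treat-all allocations.

## Synthetic-trial generator

The generator is the package's study bed; its defaults define the simulated
conditions and are not tuning knobs.

A latent severity s ~ N(0,1) organises each patient: baseline utility
u₀ = clip(0.68 − 0.12·s + N(0, 0.05)), spontaneous recovery
r = 0.10 − 0.02·s + N(0, 0.03), PHQ-9 ≈ 15 + 4·s. The BT effect on the
6-month utility is δ = mean_bt_effect + heterogeneity·z (plus an optional
feature-linked component); BT accrues δ/2 by month 3 and δ by month 6, so the
potential-outcome QALY difference is exactly 0.25·δ wherever the utility
clamp [−0.5, 1] does not bind. The closed-form expectation of the clipped
trajectory (clipped-normal moments) is used as the oracle for the generator's
mean treatment effect. PHQ-9 at month 6 tracks the same trajectory at ≈ 40
points per utility unit.

Costs are arm-independent except the BT platform cost: consultations ~
Poisson, productivity hours ~ gamma, residual healthcare spend ~ lognormal,
and rare hospital admissions (Bernoulli × count at 2 500 €/admission) create
the heavy right tail — sample skewness is positive from n ≈ 500 (asserted).
A latent *utilization propensity* shared between the pre-baseline and
follow-up periods makes baseline resource-use items genuinely predictive of
follow-up costs, emulating the strong autocorrelation of healthcare
utilization; in the `informative` preset its strength (1.0, residual
lognormal σ = 0.55) is calibrated so that lasso-selected ridge cuts the
reference cost MAE by roughly one third — the improvement magnitude reported
for the real-data analysis this package's methodology follows.

Missingness is MCAR by default at rate 0.1 on baseline cells only (the total
missing-cell count of the motivating dataset suggests a rate of this order;
the exact mechanism is unknown). Outcome-defining fields are never masked.
A MAR hook (masking log-odds shifted by severity) exists but is off by
default. Original values are retained so imputation quality can be scored.

Presets: `default_config()` (modest effect, MCAR), `informative_config()`
(stronger baseline signal everywhere, feature-linked effect heterogeneity so
selection has signal to find), `null_config()` (no effect, no platform cost:
both arms share identical potential outcomes).

**What the generator does not emulate.** Utilities are generated directly as
continuous weights rather than as discrete 5-level EQ-5D profiles (profile
quantization would break the exact potential-outcome identities the oracle
tests rely on); there is no item-level questionnaire structure, no
country-level clustering, no informative dropout, and the feature catalogue
is structural (severity-loaded numerics, generic categoricals), not a
reproduction of any real instrument. Passing tests therefore demonstrate
that the *methodology* behaves correctly under known conditions — not that
any particular real dataset has predictable outcomes or costs.

## Preprocessing

Fixed order, mirrored by the pipeline and logged: merge → drop degenerate →
impute → encode. Merging restricts to patients with both dependent variables
observed; duplicate column names get a source prefix. A feature is dropped
if it is entirely missing or has fewer than two distinct observed values —
overall, or within either arm when the arm split is supplied (an arm-wise
constant cannot enter per-arm models). Median/mode imputation breaks median
ties by the mean of the central pair and mode ties by the lexicographically
smallest level (logged); distribution-sampling imputation draws numeric
fills from N(mean, SD) and categorical fills from observed frequencies,
reproducibly under a seed, with a single-observed-value column filled by
that value under a warning. Imputation statistics are computed on the full
table before CV splitting — the usual single-imputation workflow; the mild
leakage this causes is shared by all learners and the reference. One-hot
encoding uses the modal level as reference (L−1 indicators per L-level
feature) with full provenance; levels unseen at fit time map to an all-zero
block with a warning rather than crashing held-out prediction.

## Pipeline, seeds, and problem sizes

`run_experiment` executes simulate → improvement summary (per-arm PHQ-9
means and a Welch t-test on end scores — "a t test" is underspecified, and
Welch's form is the safe default under unequal variances) → preprocess →
all-features LOOCV table → lasso selection + selected-features LOOCV table →
full-data fits → recommendations → contingency table → counterfactual
evaluation, and writes the report bundle atomically (temp directory renamed
into place; failures leave nothing behind). Every stochastic stage consumes
a 31-bit sub-seed derived as sha256(master_seed, stage_name), so adding a
stage never perturbs another stage's stream and runs are bit-for-bit
reproducible.

Test problem sizes were chosen to exercise the full method while keeping the
suite comfortably interactive: the qualitative prediction-pattern check runs
five replicates of the full n = 350 evaluation; support recovery uses 100
runs at n = 300, p = 50 with 3 active features; pipeline determinism and CLI
tests use 40–200 patients.

## Known limitations

- The synthetic tariff and unit costs are placeholders; all € magnitudes in
  simulated output are only order-of-magnitude realistic.
- Single imputation (no multiple-imputation pooling) and a linear, constant
  willingness-to-pay rule; severity-dependent or nonlinear decision rules
  are a documented extension point of `recommend()`, not implemented.
- The 6-month horizon is fixed by the data model; 12-month analyses and
  country-level multilevel structure are out of scope.
- Counterfactual percent changes depend on model predictions for discordant
  patients and inherit their uncertainty; no confidence intervals are
  attached to the policy evaluation.
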