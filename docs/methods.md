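# Methods

This note records the models and procedures implemented in `vacod`, the
parameter choices with their rationale, and the known limitations. It assumes
the reader has seen `README.md`.

## 1. Data model (`vacod.va_data`)

A death record carries a symptom profile of 23 ternary flags (yes / no /
unknown) and 3 non-negative integer counts (`cough_duration_days`,
`weight_loss_duration_days`, `stools_per_day`), plus age in days, site,
reviewer id, reference causes (possibly multiple), PCVA causes and an optional
repeat-review cause. Age strata follow the study design: **neonate** = 0–27
completed days, **child** = 28–1825 days (the 0–27 boundary is configurable
via `derive_age_group(..., neonate_max_days=)`). Cause vocabularies are
closed: children {malaria, pneumonia, meningitis, diarrhea, malnutrition,
HIV/AIDS, other}; neonates {septicemia, meningitis, pneumonia, congenital
malformation, other}. All labels outside the vocabulary for the record's
stratum raise `VocabularyError` at construction, so downstream code never
validates labels.

CSV I/O treats an empty cell as *unknown* (for flags) or *missing* (for
optional fields); multi-cause cells are `;`-joined. `systematic_sample(ids,
interval=k, offset=o)` takes every k-th record in file order starting at
position `o` (default `o = k`, i.e. records k, 2k, …), reproducing a
fixed-interval re-review sample: with n = 719 and k = 5 this yields 143
questionnaires (19.9%).

## 2. Diagnostic criteria and classification (`vacod.rule_engine`)

Each (age group, cause) pair has an expert criterion: a boolean combination of
flags and thresholded counts. Criteria are evaluated in **Kleene three-valued
logic** so that *unknown* propagates correctly through ∧/∨/¬, and a single
evaluator supports all three unknown-handling policies:

- `AS_ABSENT` (default): an indeterminate criterion value is treated as
  *does not fire*. This matches how field algorithms are usually applied.
- `FAILS_CRITERION`: a criterion fires only if it evaluates to definite true
  (identical decisions to `AS_ABSENT`; kept distinct because it differs once
  criteria are negated or composed externally).
- `PROPAGATE`: `evaluate_criterion` may return `None`, letting callers treat
  indeterminacy explicitly.

Count thresholds sit in an `EvaluationPolicy` rather than in the formulas:
chronic cough means duration > 21 days (`cough_max_days=22`, exclusive upper
bound of "acute"), chronic weight loss ≥ 14 days, diarrhea ≥ 3 loose stools
per day. These follow the questionnaire conventions of the study region and
are overridable (also loadable from YAML via `load_policy`).

The **non-hierarchical algorithm** returns the set of all firing causes
(possibly empty → treated as OTHER in evaluation). The **hierarchical
algorithm** walks a precedence list and returns the first firing cause, else
OTHER. Default precedence: children meningitis → pneumonia → malnutrition →
diarrhea → HIV/AIDS → malaria; neonates septicemia → meningitis → pneumonia →
congenital malformation. Custom orders are first-class (`Hierarchy`,
`load_hierarchy`).

A structural consequence of the default neonatal order is implemented
verbatim: the neonatal meningitis criterion (fever ∧ convulsions ∧
(stiff neck ∨ bulging fontanelle)) logically implies the septicemia criterion
(≥2 of its 6 sign groups), so under the hierarchy neonatal meningitis can
never be assigned. This is a property of the published rule set, not a bug;
`analysis/02` and the validation tables make it visible (HA sensitivity 0 for
neonatal meningitis).

`enumerate_truth_table` enumerates all assignments over a chosen flag subset
(≤20 flags) × a duration grid, yielding multi- and single-cause outputs; the
test suite checks it exhaustively against an independent brute-force boolean
oracle written without the package's abstractions.

## 3. Validation metrics (`vacod.evaluation`)

Per cause c, a prediction set P and reference set R give a 2×2 confusion
table (tp = c∈P∧c∈R, etc.); sensitivity tp/(tp+fn), specificity tn/(tn+fp),
PPV tp/(tp+fp). Zero denominators yield `None`, never 0 — undefined and zero
are different findings. Empty assignment sets are mapped to {OTHER} so every
death contributes to every cause's table. CSMF for a multi-cause method counts
a death once per attributed cause, so method CSMFs need not sum to 1 (the
reference CSMF always partitions). Signed CSMF difference is
(method − reference) × 100 percentage points. `evaluate_methods` emits one
tidy row per (method, site, age group, cause), with a pooled `site == "ALL"`
stratum whose confusion counts are exactly the sums of the per-site counts.
Operating characteristics for OTHER are reported as NaN: OTHER is a residual
category, not a diagnosis.

## 4. Reliability (`vacod.reliability`)

For n paired (original, repeat) single-cause assignments: percent agreement
p_o; Cohen's kappa κ = (p_o − p_e)/(1 − p_e) with p_e = Σ_c p̂(c|orig) p̂(c|rep).
Large-sample standard error SE = sqrt(p_o(1 − p_o)) / ((1 − p_e) sqrt(n)),
95% CI κ ± 1.96·SE, and the test of κ = 0 uses z = κ / sqrt(p_e / (n(1 −
p_e)²)) against the standard normal. A seeded nonparametric bootstrap CI
(`ci_method="bootstrap"`, default 2000 resamples) is available; it is the
preferred interval at small n where the normal interval can exceed [−1, 1].
Degenerate marginals (p_e → 1, e.g. a reviewer who used one label throughout)
raise `DegenerateMarginalsError`; `reliability_report` converts that to `None`
for the affected reviewer while still including those pairs in the pooled
estimate. The suite cross-checks κ, SE and z against `statsmodels`'
`cohens_kappa` on hundreds of random contingency tables (statsmodels is a
test-only dependency; the library path is self-contained).

Landis–Koch verbal bands are upper-inclusive: (0.8, 1] almost perfect,
(0.6, 0.8] substantial, (0.4, 0.6] moderate, (0.2, 0.4] fair, (0, 0.2]
slight, [−1, 0] poor. So κ = 0.80 is *substantial* and κ = 0.87 *almost
perfect*; boundary cases are pinned by tests.

`csmf_shift` compares original vs repeat CSMFs per reviewer and pooled, in
percentage points.

## 5. Synthetic cohort generator (`vacod.synthetic_cohort`)

The study's record-level data were never deposited, so validation properties
are demonstrated on synthetic cohorts with known ground truth.

**Generative model.** For each site, true causes are drawn i.i.d. from the
site's CSMF within each age stratum. Given the true cause, symptoms are
emitted **conditionally independently**: each flag is Bernoulli with a
cause-specific probability (default background 0.05), each count is drawn
uniformly from a cause-specific integer range, with duration counts zeroed
when their gating flag is *no*. An `unknown_rate` (default 0.02) randomly
masks flags to *unknown*. Physician review is simulated by row-stochastic
**misclassification kernels** applied to the true cause, per reviewer;
`uniform_kernel(vocab, d)` puts mass d on the diagonal and spreads 1−d
uniformly. Repeat review keeps the original label with probability
`repeat_agreement` and otherwise redraws from a disagreement kernel
(`simulate_repeat_review` handles mixed-age cohorts by splitting per stratum).

**Tuning.** `tuned_emission_model(age_group, hit_probability=h)` sets each
flag in a cause's canonical symptom set to probability h^(1/k) for a k-flag
conjunction, so the cause's own criterion fires with probability ≈ h = 0.7 on
deaths from that cause. This is a design target for realism, not a quantity
any test asserts.

**Default configuration** (`default_config`): 719 deaths shaped like the
study — Kampala 62 neonates/369 children, Tororo 26/154, Kisoro 16/92 (a
60/25/15 site split; the published tables give site CSMFs but not site sizes).
Site CSMFs are taken from the published reference-standard columns (the
Tororo column prints to 1.02 and is renormalized). Four reviewers with
workload weights (0.25, 0.35, 0.25, 0.15) and diagonal accuracies
(0.85, 0.90, 0.85, 0.70), chosen to mirror the ordering of the published
per-reviewer kappas; repeat agreement 0.83, near the published pooled percent
agreement. All sampling flows from a single `numpy.random.default_rng(seed)`;
sub-seeds are drawn below 2³¹. Identical seeds give byte-identical cohorts.

**Recovery properties** (demonstrated in tests and `scripts/acceptance.py`):
a perfect classifier's empirical CSMFs converge to the configured ones
(max error < 2 pp at n = 10 000); a reviewer with a *symmetric* kernel is
CSMF-unbiased **only under a uniform true CSMF** — with a non-uniform CSMF,
symmetric misclassification shrinks fractions toward uniformity — so the
unbiasedness check uses a uniform-CSMF cohort by construction; simulated
repeat review recovers the configured agreement rate within ±2 pp at
n = 5000.

## 6. Published-table arithmetic (`vacod.published`)

Three small CSV tables from the Ugandan validation study ship with the
package: per-site/per-cause CSMFs under the reference standard, PCVA, NHA and
HA with their printed signed differences; original-vs-repeat CSMFs with
printed shifts; and per-reviewer agreement/kappa. `recompute_method_differences`
and `recompute_repeat_shifts` re-derive every difference column from the
printed CSMF columns through the package's own `csmf_difference`. All 84
method differences reconcile except one: the Tororo / HIV-AIDS / PCVA cell
prints −8 where the printed CSMFs (16% vs 8%) give +8 — a sign typo in the
source table. The recomputation reports the computed value; the acceptance
test asserts the magnitude for that single cell and the signed value
everywhere else.

## 7. Numerical and design choices

- Exact rational confusion counts; metrics as float divisions; no smoothing
  or continuity corrections anywhere.
- `None`/NaN for undefined ratios rather than sentinel zeros.
- Percent-point (pp) scale for all CSMF differences, matching the published
  tables.
- Tolerances in property tests reflect binomial Monte-Carlo noise at the
  stated n (e.g. ±2 pp at n = 5000 is ≈ 3.8 SD for a 0.83 proportion).
- `OTHER` may not appear in a hierarchy (it is the fall-through), and
  hierarchies must be duplicate-free subsets of the stratum vocabulary.

## 8. What the generator does and does not emulate

Emulated: the study's size and strata, site-level CSMFs, multi-cause
reference standards, reviewer heterogeneity, every-5th repeat review, item
nonresponse. Not emulated: symptom correlation beyond the cause (conditional
independence is assumed), free-text or open narrative, recall decay with time
since death, seasonality, within-household interviewer effects, and any
covariance between symptom reporting and reviewer behaviour. Consequently the
synthetic cohorts support *software validation* (do the metrics recover known
parameters?) rather than epidemiological inference.

## 9. Open design decisions

- The neonatal hierarchy's meningitis shadowing (section 2) is kept verbatim;
  an alternative order putting meningitis first is one `Hierarchy(...)` away.
- Unknown handling defaults to `AS_ABSENT`; field practice varies and the
  policy enum exists precisely because no single convention is canonical.
- Kappa CIs default to the normal approximation for comparability with the
  published tables; bootstrap is available and preferred at small n.
- Landis–Koch banding is upper-inclusive; some authors use lower-inclusive
  bands, which would move κ = 0.80 across a boundary.
- Site sizes (60/25/15) and reviewer parameters are plausible reconstructions,
  not published facts; both live in `CohortConfig` and are YAML-serializable
  so alternatives are configuration, not code changes.
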