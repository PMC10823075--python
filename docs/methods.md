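# Methods

This note documents the models and procedures implemented in `bayesboost`,
the parameters that matter, the design choices made where the method leaves
room, and what the bundled synthetic fixtures do and do not establish about
real data.

## The detection model

Bias is operationalised as *under-representation*: a discrete protected
attribute (ethnicity, region, gender, age band) partitions the population,
and a group is under-represented when the data carries too few of its rows
for a classifier to learn it well. Detection therefore looks at classifier
*uncertainty* rather than at raw counts: a group can be small and easy, or
small and hard; only the second needs repair.

The bundled classifier is a mixed-data Naive Bayes: class priors are
relative frequencies, categorical likelihoods are Laplace-smoothed
(α = 1) level tables per class, numeric likelihoods are per-class Gaussians
(variance floored at 1e-9). Posteriors are accumulated in log space. Any
binary probabilistic classifier can be substituted through the
`train` / `predict_proba` surface; Naive Bayes is the default because it is
fast, probabilistic, and its posteriors can be verified against exact Bayes
enumeration in tests.

A validation set is extracted from the audited dataset by **stratified**
sampling on the protected attribute (default 30% of rows), so rare groups
are represented in validation proportionally rather than by luck. Rows whose
predicted positive-class probability falls in the closed interval
[p₁, p₂] form the uncertain set D_Unc.

**Thresholds.** Defaults p₁ = 0.4, p₂ = 0.7. Two semantic choices here were
genuinely open and are resolved as follows: the interval applies to the
probability of the *positive* class (the calibration procedure ties the
lower threshold to the negative class within the (0.25, 0.5] band and the
upper to the positive class within (0.5, 0.75], which only makes sense on
one shared scale), and the interval is closed at both ends (so the
documented endpoints select themselves). Optional recalibration repeats a
split/train/predict cycle (default 10×) and averages the predicted
probabilities inside each half-open band; a band empty in every repeat falls
back to the default with a warning, as does an inverted pair.

**The report.** For every protected level the detection report lists its
share in the audited data and in D_Unc; a level is flagged when the
uncertain share exceeds the reference share. The flag is scale-free
(duplicating all rows changes nothing) and is the package's analogue of
reading grouped representation bars.

## The correction model

Correction generates synthetic members of exactly the strata the uncertain
set points to.

1. **Attribute ordering O.** Every non-target variable is scored by the
   distributional difference between the audited data and D_Unc — total
   variation ½Σ|p̂−q̂| for categorical variables, the two-sample
   Kolmogorov–Smirnov statistic for numeric ones. Both are bounded in [0, 1],
   which makes mixed-type scores comparable in one descending sort; ties keep
   schema order.
2. **Counts m.** For a boosting fraction f ∈ {0.5, 1.0, 2.0} (BB50 / BB100 /
   BB200), the total synthetic budget is round(f·|D_Bias|), split as evenly
   as possible over the uncertain rows: the first (total mod |D_Unc|) rows
   receive one extra. The implementation accepts any positive fraction; the
   three canonical ones are the defaults. The remainder rule (lowest-index
   rows first) is arbitrary but stable and documented.
3. **Generation.** One Bayesian network is learned and fitted on the
   discretized audited data and shared across fractions. For each uncertain
   row, evidence = its protected value plus its values on the top-k
   variables of O (default k = 3, tunable 0..all); its m offspring are drawn
   by likelihood weighting followed by weighted resampling. How the ordered
   set O is consumed is a reconstruction: clamping the highest-divergence
   attributes targets precisely the joint strata the uncertain set says are
   missing, and k = 3 keeps the evidence specific without starving the
   weighting step. The target variable is never used as evidence, so
   synthetic rows carry sampled labels and no validation labels leak into
   BB. Rows whose evidence has zero likelihood fall back to protected-only
   evidence, then are skipped with their budget redistributed (with α = 1
   smoothing this cannot trigger; it guards degenerate hand-built networks).
4. **Merge.** BB = audited rows (provenance `original`) + synthetic rows
   (provenance `synthetic`). The uncertain rows themselves are not copied
   in; only their offspring are. Size contracts are exact by construction.

## The Bayesian network engine

Structure learning is greedy hill climbing over add/delete/reverse moves
scoring BIC, in-degree capped at 3, no restarts, with a fixed lexicographic
scan order so ties — and therefore the whole procedure — are deterministic.
Parameters are Laplace-smoothed frequencies, α = 1 by default so that no CPT
row contains a zero (a zero would break likelihood weighting and make
sampled supports misleading); unseen parent configurations yield uniform
rows. Forward ("logic") sampling walks a topological order; evidence
sampling uses likelihood weighting with 4n proposals (minimum 512) and warns
when the effective sample size drops below n/10. Rejection sampling was
rejected because uncertain-row evidence can span several variables and would
stall. Brute-force joint enumeration (≤ 10⁶ states) provides exact marginals
as the test oracle; it is not an inference engine.

`learn_structure` accepts a set of *root* variables that may not receive
parents. Demographic attributes are exogenous in any reasonable causal
reading of patient data, and the constraint matters operationally: BIC
cannot distinguish Markov-equivalent orientations, and overriding the CPT of
a node that happens to be oriented as a child severs its dependence on its
parents. The bias simulator therefore constrains the protected attribute to
be a root by default (`BiasSpec.protected_as_root=True`), making the
override an exact marginal control that preserves outcome conditionals. The
unconstrained variant is kept available because it models a *harsher*,
structure-destroying corruption (see "Accuracy orderings" below).

Mixed data enters every network operation through quantile discretization
(default 5 bins per numeric variable) with an invertible binning map;
inversion draws uniformly within the cell's bin. This makes each network
operation exact and enumerable at the cost of within-bin resolution; the
bin-membership round trip is asserted in tests.

## The bias simulator

Given a desired post-bias protected marginal: learn a network on the source
data, override the protected node's distribution, draw an intermediate
sample (default: same size as the output), learn a *second* network on that
sample — fully separating the biased output from the source rows — and draw
the final biased dataset from it. An evidence-conditioned mechanism
(per-level quotas via likelihood weighting) is available as an alternative
to the CPT override. The realized protected marginal is checked against the
target within 3 Monte-Carlo standard errors (accounting for both sampling
stages) and the run fails loudly on drift.

## Baselines and evaluation

SMOTE, AdaSyn and the simplified Fair-SMOTE share one mixed-type core in the
SMOTE-NC style: distances are squared Euclidean over standardized numerics
plus a constant penalty (median of the standardized numeric deviations) per
categorical mismatch; synthetic rows interpolate numerics uniformly toward a
random one of the k = 5 nearest minority neighbors and set categoricals by
neighbor majority vote (ties lexicographic). AdaSyn allocates counts
proportionally to each minority row's majority-neighbor fraction, with
largest-remainder rounding and a uniform fallback when every neighborhood is
pure. The simplified Fair-SMOTE binarizes the protected attribute by a
privileged/unprivileged map (defaults: male; "White or not stated" + "Other
ethnic group"; "London" + "South Central") and oversamples each of the four
class × privilege subgroups to the largest's size — deliberately *not* the
full published method, whose situation-testing stage is out of scope here.

Evaluation trains the classifier on every candidate dataset and scores it on
one fixed held-out test set, repeated over reseeded runs (default 10; what
varies is candidate regeneration and any resampling randomness — the test
set never changes). Reported: mean and Student-t 95% interval per metric.
Accuracy/precision/recall/F1 use a 0.5 decision threshold; ROC-AUC is
trapezoidal; PR-AUC uses step interpolation (average precision), the
conservative convention for imbalanced targets. Fairness diagnostics:
demographic-parity gap (max−min per-group positive-prediction rate) and
equalized-odds gap (worst of the TPR and FPR spans; groups without positives
are dropped from the TPR span with a warning).

An experimental alternative uncertain-set criterion selects validation rows
from the group on the disadvantaged side of a chosen fairness gap (lowest
TPR for equalized odds, lowest positive rate for demographic parity), capped
at the count the probability-interval filter would have returned, nearest
the decision threshold first. It is a labelled reconstruction of a loosely
described idea and should be treated as exploratory.

## Fixture design

The CVD-like and Covid-like fixtures emulate the *shape* of large UK primary
care synthetic datasets — a ~10-level ethnicity skewed heavily toward "White
or not stated" (0.78), a 10-level region, binary gender, numeric age / BMI /
systolic blood pressure, smoking status, minority-prevalence binary disease
targets (8–17%) — from hand-authored networks pinned as YAML in
`bayesboost/data/`, so downstream tests recover known parameters. The
ethnicity list names nine groups commonly reported together with a tenth
level, "Mixed", added to complete the set.

Two deliberate departures from textbook epidemiology:

- **Amplified effects.** Minority-group risk elevations (South Asian stroke
  log-odds +1.9 to +2.4, blood pressure +0.8 per band) are larger than
  real-world estimates. An effect learnable by an information criterion at
  several hundred thousand rows must be amplified to remain learnable at the
  10⁴-row scale these fixtures run at — the BIC detectability threshold
  scales as ln(n)/n — and the fixtures are meant to preserve the *regime*
  (dependencies survive network learning), not the effect sizes.
- **A prunable risk channel.** Systolic blood pressure is the stroke node's
  fourth parent. Learned networks cap in-degree at 3, so every regenerated
  dataset loses this channel while real data keeps it. This mirrors the
  structural information loss that generation pipelines inflict on real
  data, and gives "trained on real vs trained on regenerated" comparisons a
  systematic, mechanistically understood gap.

What passing fixture tests does **not** show: robustness to missing data,
label noise, longitudinal structure, continuous protected attributes,
schema sizes of 21–47 columns, or real-data effect sizes. The fixtures are
structural stand-ins, not statistical replicas.

## Accuracy orderings and a known limitation

Two regimes of injected bias behave very differently downstream, and the
package's tests exercise both:

- **Representation-only bias** (protected attribute constrained exogenous):
  group marginals move, outcome conditionals survive. Detection and
  correction work — a level shrunk 12% → 4% is flagged and partially
  restored in every seeded run. But this bias barely hurts a Naive Bayes
  classifier: the protected attribute is itself a feature, so the shifted
  prior and the shifted protected-level likelihoods cancel almost exactly in
  the posterior. Training on such biased data scores within noise of
  training on the ground truth.
- **Structure-destroying bias** (unconstrained override): when the learner
  orients the protected attribute as a child, the override severs its
  dependence on the outcomes. A classifier trained on such data loses the
  group-risk signal entirely and test accuracy drops by about two points on
  the fixture — but the same destruction removes what boosting needs:
  resampling the corrupted network can reweight strata, yet cannot recreate
  severed information, so the boosted sets hover at (not above) the
  corrupted data's accuracy, while SMOTE/AdaSyn fall far below both.

No single injection regime at this scale makes the biased data *both*
clearly worse than ground truth *and* clearly repairable by boosting with a
Naive Bayes learner; the first requires destroying information that the
second needs intact. The acceptance suite asserts the full ordering under
the structure-destroying regime and the corresponding test documents this
tension when it fails; the detection/correction guarantees (the package's
core claims) are unaffected.

## Other numerical choices and degeneracies

- Stratified splits round half-up per stratum; remainders go to part B.
- Constant numeric columns discretize to a single bin with a warning.
- A dataset with a single target class refuses to train (error, not NaNs).
- An empty uncertain set aborts the pipeline with advice to widen [p₁, p₂].
- All randomized operations take explicit integer seeds; pipelines derive
  stage seeds from one master seed, and manifests record every derived seed.
- Experiment runs at the 10⁴-row scale used throughout the tests complete in
  seconds per stage on one CPU; sizes were chosen so the whole suite stays
  comfortably interactive.

## Known limitations

One protected attribute at a time; binary targets only; categorical
protected attributes only (continuous ones need prior banding); no
missing-data handling; m and the evidence depth k are exposed parameters,
not optimized; the Fair-SMOTE baseline is the simplified
privileged/unprivileged variant by design.
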