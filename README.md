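# bayesboost

Detection and correction of **under-representation bias** in tabular health
data, built around a Bayesian-network synthetic data generator.

Electronic health record datasets routinely under-represent specific patient
cohorts — ethnic minorities, particular regions, one gender — because of
cultural sensitivities or standardised collection procedures. Models trained
on such data inherit the gap, and synthetic data generators trained on it
propagate the gap into every derived dataset. This package implements a
probabilistic audit-and-repair loop for that problem, aimed at people who
curate patient-level tabular datasets or run synthetic-data services:

1. **Detect.** Train a classifier (bundled: mixed-data Naive Bayes) to
   predict a binary disease target, and collect the validation rows it is
   *uncertain* about — predicted positive-class probability in the closed
   interval [p₁, p₂], defaults p₁ = 0.4, p₂ = 0.7. Call this set D_Unc. A
   protected-attribute group with a larger share in D_Unc than in the audited
   data D_Bias is flagged under-represented: the data does not carry enough
   of it to classify it confidently.
2. **Correct.** Rank the non-target attributes by distributional difference
   between D_Bias and D_Unc (total variation for categorical columns,
   Kolmogorov–Smirnov for numeric ones), giving the ordered set O. Learn a
   Bayesian network on D_Bias (hill climbing, BIC score, Laplace-smoothed
   CPTs), and for each uncertain row draw m synthetic rows by likelihood
   weighting with the row's protected value and its values on the top-k
   attributes of O clamped as evidence. The per-row counts m sum to 50%,
   100% or 200% of |D_Bias|; merging the synthetic rows with D_Bias yields
   the boosted datasets BB50/BB100/BB200.

The package also ships the surrounding experiment harness: a **bias
simulator** (override the protected attribute's distribution in a learned
network, sample, learn a second network for full separation from the source
rows, sample again), **baseline resamplers** (SMOTE, AdaSyn and a simplified
privileged/unprivileged Fair-SMOTE, all SMOTE-NC-style for mixed data), an
**evaluation harness** (accuracy, ROC-AUC, PR-AUC, precision/recall/F1,
demographic-parity and equalized-odds gaps, with Student-t confidence
intervals over repeated runs), and **seeded CPRD-like fixtures** generated
from pinned, hand-authored networks so every claim is testable by parameter
recovery without access to the licence-restricted originals.

## Worked example

Shrink one minority ethnicity group from ~12% to 4% of a 20,000-row
CVD-like dataset, then let the pipeline find and repair it:

```python
import bayesboost as bb
from bayesboost.bias_simulation import shrink_level

d = bb.make_cvd_like(20_000, seed=7)
shares = bb.measure_representation(d, "ethnicity")
spec = bb.BiasSpec("ethnicity", shrink_level(shares, "Indian", 0.04), n_out=d.n_rows)
d_bias = bb.inject_bias(d, spec, seed=7)

result = bb.bayesboost_pipeline(d_bias, fractions=(1.0,), seed=7)
print(result.report.round(3).to_string(index=False))
```

```text
              level  reference_share  uncertain_share  under_represented
White or not stated            0.858            0.631              False
             Indian            0.042            0.136               True
          Pakistani            0.018            0.042               True
        Bangladeshi            0.010            0.034               True
        ...
```

The Indian group holds 4.2% of the audited data but 13.6% of the rows the
classifier cannot decide on — a three-fold over-representation among the
hard cases, so it is flagged (as are the other elevated-risk minority
groups, which the fixture deliberately under-supplies relative to their
difficulty). Boosting then rebalances it:

```text
|D_Bias| = 20000, |D_Unc| = 477, |BB100| = 40000
Indian share: D = 0.116, D_Bias = 0.042, BB100 = 0.089
```

BB100 contains the original 20,000 audited rows plus exactly 20,000
synthetic rows concentrated on the uncertain strata, lifting the shrunk
group from 4.2% back toward its ground-truth 11.6%.

The same loop is available from the shell:

```sh
bayesboost fixtures --name cvd_like --n 20000 --seed 7 --out-prefix data/cvd
bayesboost simulate-bias --data data/cvd.csv --schema data/cvd.schema.yaml \
    --level Indian --share 0.04 --seed 7 --out data/d_bias.csv
bayesboost boost --data data/d_bias.csv --schema data/cvd.schema.yaml \
    --fractions 0.5,1.0,2.0 --seed 7 --outdir out/
bayesboost run --config experiment.yaml   # full simulation/direct experiment
```

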