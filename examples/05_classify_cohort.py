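"""End-to-end classification of a synthetic cohort.

Generates a cohort, extracts the 183-variable feature table, and
evaluates the gradient-boosted classifier with repeated stratified
5-fold cross-validation (variable filtering and imputation nested in
each training fold).
"""

import gazemarkers as gm
from gazemarkers.classify import CVConfig, run_repeated_cv
from gazemarkers.features import feature_matrix
from gazemarkers.pipeline import synthetic_feature_table

config = gm.CohortConfig(n_td=30, n_adhd=30, seed=5)
table = synthetic_feature_table(config)
X, y = feature_matrix(table)
print(f"feature table: {X.shape[0]} participants x {X.shape[1]} variables, "
      f"{int(y.sum())} labeled ADHD-like")

report = run_repeated_cv(X, y, CVConfig(n_repeats=20, seed=5))
print("\nrepeated 5-fold cross-validation (20 repeats), mean [95% CI]:")
for metric in ("auc", "accuracy", "sensitivity", "specificity", "precision", "f1"):
    row = report.summary.loc[metric]
    print(f"  {metric:12s} {row['mean']:.3f} [{row['ci_low']:.3f}, {row['ci_high']:.3f}]")
# AUC near 1 reflects the generator's strongly separated phenotypes, not
# clinical performance; the CI spans the repeat-to-repeat partition noise.

print("\ntop variables by mean split gain:")
print(report.importance.head(5).round(2).to_string())
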