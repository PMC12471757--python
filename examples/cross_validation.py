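"""Evaluate the classifier with LOOCV and repeated stratified 10-fold CV.

Generates a synthetic dataset of 30 diazotroph-like cyclic peptides and 30
halogenated non-diazotroph scaffolds, then reports leave-one-out accuracy and
ROC-AUC, the repeated-CV means with 95% confidence intervals, and the
one-sided t-test of AUC against chance (0.5).
"""

from diazopred import (
    SimConfig,
    generate_dataset,
    loocv,
    majority_baseline,
    repeated_stratified_kfold,
)

dataset = generate_dataset(SimConfig(n_pos=30, n_neg=30, separation=1.0, seed=1))

print(f"majority-class baseline accuracy: {majority_baseline(dataset.labeled()):.3f}")

report = loocv(dataset)
cm = report.confusion
print(f"\nLOOCV on {report.metadata['n']} labeled metabolites:")
print(f"  accuracy {report.mean['accuracy']:.3f} "
      f"({cm.tp + cm.tn}/{cm.n} correct), ROC-AUC {report.mean['auc']:.3f}")
print(f"  confusion: tp={cm.tp} fp={cm.fp} tn={cm.tn} fn={cm.fn}")

cv = repeated_stratified_kfold(dataset, k=10, repeats=10, seed=1)
print(f"\n10x stratified 10-fold CV (per-repeat pooled holdouts):")
for name in ("accuracy", "precision", "recall", "f1", "auc"):
    print(f"  {name:9s} {cv.mean[name]:.3f} "
          f"(95% CI {cv.ci_lower[name]:.3f}-{cv.ci_upper[name]:.3f})")
print(f"  one-sided p(AUC > 0.5) = {cv.auc_p_value:.3g}")
print("\nAt full chemotype separation the classes are structurally disjoint,")
print("so every holdout finds a same-class neighbor and metrics saturate.")
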