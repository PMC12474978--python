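"""Random-forest ensemble over per-method scores.

Combines all simulated VEP scores into one classifier: z-scored features,
75:25 grouped stratified split, mtry tuned by 5-fold CV AUROC, and a
paired DeLong comparison against the best single method on the held-out
test set.
"""
import pandas as pd

import vepbench as vb
from vepbench.types import ONCOGENIC_CLASSES

cohort = vb.generate_cohort(vb.default_config(n_patients=1500, seed=11))
scores = cohort.scores
truth = cohort.truth.variant_class.set_index("variant_key")["latent_class"]

onco_keys = sorted(
    {m.variant_key for m in cohort.mutations if m.oncokb_class in ONCOGENIC_CLASSES}
)
neg_keys = sorted(k for k in scores.variant_keys if truth[k] == "passenger")
frame = scores.frame.loc[onco_keys + neg_keys].dropna()
y = pd.Series([1] * len(onco_keys) + [0] * len(neg_keys),
               index=onco_keys + neg_keys).loc[frame.index].to_numpy()

tr, te = vb.split_train_test(frame.index, y, seed=11)
train_std, test_std, _ = vb.zscore_preprocess(frame.iloc[tr], frame.iloc[te])
model, cv = vb.train_ensemble(train_std, y[tr], cv_scheme="kfold5",
                              n_trees=300, seed=11)
print(f"tuned mtry: {cv.mtry}  (CV AUROC by mtry: "
      + ", ".join(f"{m}:{a:.3f}" for m, a in cv.cv_auroc_by_mtry.items()) + ")")
print("feature importances:")
for name, imp in sorted(cv.importances.items(), key=lambda kv: -kv[1]):
    print(f"  {name:8s} {imp:.3f}")

baseline = {k: float(v) for k, v in frame["am"].items()}
res, cmp_ = vb.evaluate_and_compare(
    model, test_std, y[te], baseline_scores=baseline, baseline_name="am"
)
print(f"\ntest AUROC {res.auroc:.3f}, accuracy {res.accuracy:.3f}, "
      f"sensitivity {res.sensitivity:.3f}, specificity {res.specificity:.3f}")
if cmp_ is not None:
    print(f"ensemble vs best single method: dAUC {cmp_.delta_auc:+.4f}, p {cmp_.p:.3g}")
# The forest pools complementary methods; importances show which scores
# drive its decisions.
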