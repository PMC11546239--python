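"""Distil the phenotypes into a compact classifier: JMIM feature ranking,
boosted-tree training, one-vs-rest AUC and decision-curve net benefit."""

import numpy as np

from icufluid import (
    default_phenotypes,
    default_trajectory,
    default_units,
    discretize_table,
    generate_cohort,
    jmim_rank,
    net_benefit,
    train_phenotype_classifier,
)
from icufluid.features import SplitSpec, scores_frame

baseline, _ = generate_cohort(
    default_phenotypes(), default_trajectory(), n=4000, seed=10, units=default_units()
)
labels = baseline.df.set_index("patient_id")["true_phenotype"]

disc = discretize_table(baseline, bins=5)
scores = jmim_rank(disc, labels.to_numpy())
print("JMIM ranking (importance = criterion value / top criterion value):")
print(scores_frame(scores).head(10).round(3).to_string(index=False))

selected = [s.feature for s in scores[:9]]  # nine-variable distilled model
model, auc, (lo, hi) = train_phenotype_classifier(
    baseline, labels, selected, SplitSpec(test_size=0.3), seed=10
)
print(f"\nper-phenotype one-vs-rest AUC: { {k: round(v, 3) for k, v in auc.items()} }")
print(f"AUC range {lo:.3f}-{hi:.3f} on the held-out 30%")

# decision curve for "is this patient phenotype D?" (the highest-risk group)
import pandas as pd
from sklearn.model_selection import train_test_split

X = baseline.df[selected].copy()
for c in selected:
    if X[c].dtype == object:
        X[c] = (X[c] == "yes").astype(float)
y = (labels == "D").astype(int).to_numpy()
X_tr, X_te, y_tr, y_te = train_test_split(X.to_numpy(float), y, test_size=0.3,
                                          random_state=0, stratify=y)
from xgboost import XGBClassifier

clf = XGBClassifier(n_estimators=200, max_depth=4, eval_metric="logloss", random_state=0)
clf.fit(X_tr, y_tr)
prob = clf.predict_proba(X_te)[:, 1]
curve = net_benefit(prob, y_te, thresholds=[0.1, 0.2, 0.3, 0.5])
print("\ndecision curve (net benefit above treat-all/none means clinical value):")
print(curve.round(4).to_string(index=False))
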