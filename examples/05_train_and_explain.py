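"""Train a Random Forest severity model on a 3-batch study and interpret it.

The feature vector of a sepal is its mean spectrum concatenated with its
spectral standard deviation over the kept bands.  Hyperparameters are tuned
by grid search under 10-fold CV on an 80% training split; the 20% hold-out
is scored with RMSE / R2 / Pearson; sepal predictions are averaged per
tomato.  Impurity importances and exact TreeSHAP attributions identify which
wavelengths drive the prediction — by construction, the water-absorption dip
near 1400 nm.
"""

import numpy as np
import pandas as pd

import sepalnir as sn
from sepalnir.model import ModelConfig, shap_explain, split_train_test, tune_and_fit, evaluate

study = sn.generate_study(3, seed=7)
results, wavelengths = sn.process_study(study)
combined = pd.concat([t.sepal_table for _, _, _, t in study], ignore_index=True)
fused = sn.fuse_grades_pca(
    sn.GradePanel.from_frame(sn.generate_panel(combined, seed=7))
)
records = sn.attach_severities([r for res in results for r in res.records], fused)
feats = sn.FeatureMatrix.from_records(records, wavelengths)
print(f"{len(feats.y)} sepals x {feats.X.shape[1]} features "
      f"({feats.X.shape[1] // 2} bands x 2 families)")

cfg = ModelConfig(algorithm="rf", cv_scheme="kfold10", seed=7,
                  grid={"n_estimators": [200], "max_depth": [None]})
train_idx, test_idx = split_train_test(len(feats.y), cfg)
model, cv_metrics, _ = tune_and_fit(feats.X[train_idx], feats.y[train_idx], cfg)
test = evaluate(model, feats.X[test_idx], feats.y[test_idx])
print(f"CV   R2 {cv_metrics['r2']:.3f}  RMSE {cv_metrics['rmse']:.3f}")
print(f"test R2 {test['r2']:.3f}  RMSE {test['rmse']:.3f}  Pearson {test['pearson']:.3f}")

_, tomato_r = sn.aggregate_to_tomato(
    feats.sepal_ids[test_idx], feats.y[test_idx], model.predict(feats.X[test_idx])
)
print(f"tomato-level Pearson {tomato_r:.3f}")

imp = sn.global_importance(model, feats.feature_names)
top5 = sorted(imp, key=imp.get, reverse=True)[:5]
print("top-5 important features:", ", ".join(f"{f} ({imp[f]:.2f})" for f in top5))

shap_matrix, baseline, explanations = shap_explain(
    model, feats.X[test_idx][:1], feats.feature_names, top_k=3
)
pred = model.predict(feats.X[test_idx][:1])[0]
print(f"\nexample sepal: predicted severity {pred:.2f} (baseline {baseline:.2f})")
for name, contrib in explanations[0]:
    print(f"  {name}: {contrib:+.3f} ({'raises' if contrib > 0 else 'lowers'} the prediction)")
print("-> the dominant contributions cluster around the 1400 nm water-absorption")
print("   dip: dry (infection-prone) sepals reflect more there.")
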