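"""Stacked generalization through Isomap confidence regions.

Base classifiers are trained on the train split; on the validation split each
model's true-class probability becomes a signed confidence s = 2(p - 0.5).
The validation descriptors are embedded in 2-D with Isomap; each embedded
point stores its locally best model, and new samples inherit the stored class
of their nearest validation point (the Voronoi-cell rule).
"""

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from laccoxkit.preprocess import apply_plan, fit_transform
from laccoxkit.stacking import (
    confidence_scores,
    fit_meta,
    isomap_embed,
    predict_meta,
    split_triple,
    voronoi_regions,
)
from laccoxkit.synth import GeneratorConfig, generate_panel

panel = generate_panel(GeneratorConfig(n=250, prevalence_target=0.6, seed=6))
train, val, test, triple = split_triple(panel, seed=0)
print(f"train/validation/test = {train.n}/{val.n}/{test.n} (the 180/49/21 proportions)")

plan, X_tr = fit_transform(train, "A")
X_val, X_te = apply_plan(plan, val), apply_plan(plan, test)
models = [
    LogisticRegression(max_iter=2000, random_state=0),
    RandomForestClassifier(n_estimators=100, random_state=0),
]
for m in models:
    m.fit(X_tr, train.y)

prob_val = np.column_stack([m.predict_proba(X_val)[:, 1] for m in models])
prob_true = np.where(val.y[:, None] == 1, prob_val, 1 - prob_val)
conf = confidence_scores(prob_true)

emb, ref = isomap_embed(X_val, k_neighbors=10)
meta = fit_meta(emb, conf, (prob_val >= 0.5).astype(int))
share = np.bincount(meta.best_model_index, minlength=2) / val.n
print(f"locally best model share: logreg {share[0]:.2f}, rfc {share[1]:.2f}")

preds = np.array([predict_meta(x, meta, ref) for x in X_te])
print(f"stacked test accuracy: {(preds == test.y).mean():.3f}")
regions = voronoi_regions(meta)
print(f"exported {len(regions['regions'])} Voronoi confidence cells for plotting")
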