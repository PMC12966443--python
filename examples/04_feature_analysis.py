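"""Two complementary feature-relevance analyses.

Gini (mean-decrease-impurity) importances from a random forest, and the
Markov blanket of the oxidation label in a Bayesian network learned on
MDLP-discretized descriptors — the minimal variable set rendering the label
conditionally independent of everything else.
"""

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from laccoxkit.features import (
    discretize_dataset,
    gini_importance,
    hill_climb,
    markov_blanket,
)
from laccoxkit.preprocess import near_constant_filter
from laccoxkit.synth import GeneratorConfig, generate_panel

panel = generate_panel(GeneratorConfig(n=400, prevalence_target=0.6, seed=4))
panel, removed = near_constant_filter(panel)
print(f"near-constant features removed: {removed}")

rf = RandomForestClassifier(n_estimators=100, random_state=0).fit(panel.X, panel.y)
rep = gini_importance(rf)
order = np.argsort(rep.importances)[::-1]
print("top-5 Gini importances (sum to 1):")
for j in order[:5]:
    print(f"  {panel.feature_names[j]:>22}: {rep.importances[j]:.3f}")

table, scheme = discretize_dataset(panel)
cut_counts = {k: len(v) for k, v in scheme.cuts.items() if v}
print(f"MDLP accepted cuts: {cut_counts}")
net = hill_climb(table)
print(f"learned network: {len(net.edges)} edges")
print(f"Markov blanket of Oxd: {sorted(markov_blanket(net, 'Oxd'))}")
print("(blanket features are the probabilistically sufficient predictors)")
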