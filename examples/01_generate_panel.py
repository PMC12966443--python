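"""Generate a synthetic benzenoid substrate panel and inspect it.

Every molecule is a benzene core with 1-3 substituents; the oxidation label
follows a logistic model in the summed substituent electronics, calibrated to
a target positive prevalence.
"""

from laccoxkit.synth import GeneratorConfig, generate_panel
from laccoxkit.data import write_dataset

panel = generate_panel(GeneratorConfig(n=200, prevalence_target=0.74, seed=1))

print(f"records: {panel.n}, descriptors: {len(panel.features)}")
print(f"positive prevalence: {panel.y.mean():.3f}  (target 0.74, the imbalanced regime)")
print("first three substrates:")
for r in panel.records[:3]:
    print(f"  {r.id}  {r.smiles:>28}  Oxd={r.label}")

path = write_dataset(panel, "scratch_panel.csv")
print(f"written to {path} — a descriptor CSV consumable by every other example")
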