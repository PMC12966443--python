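"""Training-set augmentation: Gaussian descriptor noise and SMILES variants.

Noise injection perturbs continuous descriptors by N(0, eta*sigma) and
rounds/clips ordinal ones; SMILES enumeration writes the same molecule many
valid ways.  Both apply to training data only and never change labels.
"""

from laccoxkit.augment import NoiseConfig, enumerate_smiles, gaussian_augment
from laccoxkit.data import split_train_test
from laccoxkit.synth import GeneratorConfig, generate_panel

panel = generate_panel(GeneratorConfig(n=120, seed=5))
train, test = split_train_test(panel, 0.2, seed=0)

aug = gaussian_augment(train, NoiseConfig(eta=0.1, seed=1))
print(f"train {train.n} -> {aug.n} records after eta=0.1 noise append")
print(f"labels preserved: {bool((aug.y[: train.n] == aug.y[train.n :]).all())}")

smi = train.records[0].smiles
variants = enumerate_smiles(smi, max_variants=8, seed=2)
print(f"{smi} has {len(variants)} enumerated writings, e.g.:")
for v in variants[:4]:
    print(f"  {v}")
print("each re-canonicalizes to the same molecule, so the label carries over")
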