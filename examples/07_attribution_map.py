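"""Map token-level attribution scores onto a molecular graph.

Synthetic attributions (ground truth: phenolic OH positive, nitro negative)
are aligned to SMILES characters, aggregated per atom conservatively, and
classified blue/red/yellow for rendering.
"""

from laccoxkit.attribution import atom_attributions, render_annotation
from laccoxkit.synth import generate_token_attributions

smiles = "O=[N+]([O-])c1ccc(O)cc1"  # 4-nitrophenol
attrs = generate_token_attributions(smiles, noise_sd=0.05, seed=0)

print(f"{smiles}: {len(attrs)} tokens")
print("token scores:", " ".join(f"{a.token}:{a.score:+.2f}" for a in attrs))

atoms = atom_attributions(smiles, attrs, neutral_band=0.15)
print("per-atom attributions (positive=blue, negative=red, neutral=yellow):")
for a in atoms:
    print(f"  atom {a.atom_index:2d}: {a.score:+.3f}  {a.cls.value}")

total_tokens = sum(a.score for a in attrs if a.score != 0)
print(f"conservation: atom total {sum(a.score for a in atoms):+.3f}")

svg = render_annotation(smiles, atoms, "scratch_attribution.svg", "svg")
gml = render_annotation(smiles, atoms, "scratch_attribution.graphml", "graphml")
print(f"rendered {svg} and {gml}")
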