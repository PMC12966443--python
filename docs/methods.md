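# Methods

This note documents the models and procedures implemented in laccoxkit, the
assumptions behind them, the defaults that matter, and what the synthetic
benchmark does and does not establish.

## The prediction problem

Given a substrate panel `D = {(xᵢ, yᵢ)}` with descriptor vectors `x ∈ ℝᵖ`
(or SMILES strings) and binary oxidation outcomes `y ∈ {0, 1}`, learn a
classifier minimizing empirical risk. Real panels have three awkward
properties the toolkit is built around: small n (hundreds of records), mixed
descriptor types (continuous, ordinal, binary), and class imbalance ranging
from near-balanced (~53% positive) to strongly imbalanced (~74% positive).
Ambiguous "±" assay outcomes are preserved at read time and excluded before
modelling (`binarize`); their experimental treatment is not standardized, so
dropping them is the only defensible default and is logged.

## Synthetic panels: the stated world

The generator emulates benzenoid-dominated screening panels. Each molecule
is a benzene core with 1–3 substituents sampled uniformly (positions without
replacement over the six ring carbons — the simplest exchangeable scheme).
Each substituent `g` carries a signed weight `e_g` mirroring its
electron-donating (+) or withdrawing (−) character:

| group | OH | NH₂ | OCH₃ | CH₃ | Cl | SO₂NH₂ | COOH | CF₃ | NO₂ |
|-------|----|-----|------|-----|----|--------|------|-----|-----|
| effect | +1.0 | +0.9 | +0.8 | +0.2 | −0.4 | −0.7 | −0.8 | −0.9 | −1.2 |

These are **generator parameters, not literature constants**: only their
qualitative ordering (donors positive, withdrawers negative) is
domain-motivated, matching the chemistry of one-electron laccase oxidation.
Labels are Bernoulli with `P(y=1) = logistic(β₀ + β₁ Σ e_g)`; the default
slope β₁ = 3 makes the signal strong but noisy. β₀ is calibrated by
bisection (200 iterations on [−50, 50]) so the expected prevalence matches a
target in the experimentally observed range [0.53, 0.74]; at n = 5000 the
empirical prevalence lands within ±0.03 of the target. Default panel size
for recovery experiments is n = 600 at prevalence 0.6 — comfortably above
the real panels' 172–250 records so that recovery failures indicate method
bugs rather than sampling noise, while staying desk-scale.

Descriptors are a minimal open constitutional set (molecular weight,
heteroatom/rotatable-bond/multiple-bond/aromatic-atom/ring/HBD/HBA/halogen/
nitro counts, Crippen logP). They stand in for proprietary descriptor-suite
output; they are *not* a reimplementation of any commercial descriptor set.

What a green test on this world establishes: the protocol machinery
(splitting, tuning, oversampling placement, scoring) and the
interpretability chain recover a known planted signal. What it does not
establish: performance numbers on real enzyme panels, scaffold-level
generalization (every synthetic molecule shares the benzene scaffold —
stricter than the real 80–87% top-3 coverage), or any claim about which
motifs real laccases prefer.

## Chemical-space characterization

Fingerprints are 2048-bit hashed Morgan fingerprints of radius 2 (the ECFP4
convention; 2048 bits is the community default, the width being otherwise
unspecified). Tanimoto similarity is `|A∩B| / |A∪B|` on on-bit sets with
the documented convention `T(∅, ∅) = 1` (two featureless molecules are
identical). Internal diversity is defined as `1 − mean pairwise Tanimoto`;
the complementary published ranges (0.167 ↔ 0.833) confirm this reading and
the identity holds to machine precision by construction. Nearest-neighbor
similarity is the per-molecule maximum over all others. Scaffolds are
Bemis–Murcko frameworks (RDKit); functional-group classes for the Jaccard
overlap analysis are defined by a shippable SMARTS table (alcohol, ketone,
aldehyde, amine) and two classes with no scaffolds at all count as fully
overlapping, consistent with the empty-fingerprint convention.

## Preprocessing

*Near-constant filter*: a feature is removed iff its modal count / n is
**strictly** greater than the threshold (default 0.95), so a 95-of-100
column survives.

*Strategy A* standardizes continuous features ((x−μ)/σ, zeros when σ = 0),
one-hot encodes ordinal/categorical features over training categories
(unseen test categories encode as all-zeros), and passes binary features
through. *Strategy B* min-max scales continuous features and label-encodes
discrete ones, first coarse-binning any with more than 10 distinct training
values into 5 equal-frequency bins (the cutoff and bin count are our
defaults; only "coarse binning" is prescribed). All statistics are fitted on
training data and frozen.

*Borderline-SMOTE1* (Han et al.): a minority point is DANGER iff `m' ` of
its m = 5 nearest neighbors (any class, Euclidean metric on the transformed
space, distance ties broken by lowest index) are majority with
`m/2 ≤ m' < m`; points with `m' = m` are NOISE and generate nothing.
Synthetics are `danger + u·(minority neighbor − danger)`, `u ~ U(0, 1)`,
drawn from the k = 5 minority neighbors, until classes balance 1:1 (the
target ratio being otherwise unspecified). No DANGER points at all triggers
a logged fallback to plain interpolation over all minority points. m = k = 5
follow the cited method's own experiments. Variant 1, not 2, is
implemented — the cited default.

## Evaluation protocol

Per seed: stratified 80/20 outer split; inner stratified 5-fold grid search
on the training portion; refit on the full training portion with the best
hyperparameters; evaluation on the untouched outer test; 10 seeds by
default, summarized mean ± sample sd. The inner selection criterion is F1 —
the tuning criterion is not prescribed anywhere, and F1 is the natural
balanced headline metric; this is our design choice. Borderline-SMOTE runs
inside each inner-training fold and on the outer-training portion only, so
no synthetic point ever reaches a validation or test fold. Tree ensembles
consume raw mixed-type descriptors (they handle heterogeneity natively);
linear/kernel models get strategy A. Learner failures mark the (seed, model)
cell failed and the run continues.

Metrics: confusion-table accuracy/precision/recall/F1 at threshold 0.5 with
`p ≥ 0.5 → positive`; precision defined as 0 (logged) when nothing is
predicted positive; AUROC computed from average ranks (tie-aware) and
reported as missing — never 0 — for single-class truth. Class weights
`w₁ = n/(2n₁)`, `w₀ = n/(2n₀)` are provided for weighted-loss consumers.

Comparison: two-sided paired Wilcoxon signed-rank on per-seed F1, zero
differences dropped, exact distribution for ≤ 25 pairs, p = 1 when all
differences vanish; model ranking by mean AUROC with average-rank ties,
summed across datasets when several reports are supplied.

Grid defaults are deliberately small (2–4 combinations per model): the
contract under test is the protocol, not hyperparameter search breadth.

## Feature analysis

*Gini importances* are computed from tree structures directly: per node
splitting on feature j, the weighted impurity decrease
`(w·G − w_L·G_L − w_R·G_R)/w_root` is accumulated, per-tree importances
normalized, averaged over trees, and renormalized to sum to 1. (A displayed
averaging formula dividing by p−1 is internally inconsistent with
normalized per-feature importances; standard mean-decrease-impurity with
final normalization is implemented instead, which matches the accompanying
"normalized to sum to 1".) sklearn's `feature_importances_` serves as an
independent cross-check in the tests, not as the implementation.

*MDLP discretization*: candidate cuts are midpoints between adjacent
distinct sorted x values; because "adjacent labels differ" is ill-defined
under tied x values, the implemented rule is that a boundary qualifies
unless both adjacent value-groups are pure with the same label. The best
cut maximizes information gain `IG(t) = H(Y) − (n_L/n)H(Y_L) −
(n_R/n)H(Y_R)` (entropy in bits; IG ties resolve to the smallest t) and is
accepted iff `IG > log₂(n−1)/n + Δ/n` with the Fayyad–Irani
`Δ = log₂(3ᶜ − 2) − [c·H(Y) − c_L·H(Y_L) − c_R·H(Y_R)]`, recursing on both
sides. An independent exhaustive-search implementation of the same rule
agrees on 100 random instances in the acceptance suite.

*Bayesian network*: BIC score `Σ_families [MLE log-likelihood] −
(ln n / 2)·(r−1)·q` (natural log), decomposable per family. Hill-climbing
starts from the empty graph, greedily applies the best single add / delete /
reverse move preserving acyclicity, breaks score ties lexicographically on
(add < delete < reverse, source, target) for determinism, and stops at a
local optimum; no restarts (restart policy unspecified; learned on
train-only data by the caller's choice, logged). CPTs are
`(count + pseudo)/(parent count + pseudo·arity)` with pseudo = 0 (pure MLE)
by default and uniform rows, logged, for unseen parent configurations. The
Markov blanket is parents ∪ children ∪ co-parents of children; the
acceptance suite verifies it against brute-force d-separation (networkx) on
every 5-node DAG up to relabeling.

## Augmentation

Gaussian noise: continuous feature j receives `ξ ~ N(0, η·σⱼ)` (η·σⱼ is the
standard deviation; the Monte-Carlo acceptance check measures the sd of the
injected noise against η·σⱼ), ordinal features additionally round to the
nearest integer and clip to the observed training range, binary features
receive no noise (only continuous and ordinal handling is prescribed), and
labels never change. Perturbed copies are **appended** (doubling n); whether
augmentation replaces or extends the training set is unspecified upstream,
and append is the reading consistent with the reported training-set growth.

SMILES enumeration: "all valid SMILES" is unbounded for symmetric molecules,
so the implementation enumerates one non-canonical rooted traversal per atom
plus up to `50·n_atoms` seeded random traversals, deduplicates as strings in
deterministic order and caps at `max_variants` — making the output monotone
in the cap. Every variant re-canonicalizes to the parent, so labels
propagate.

## Stacked generalization

Confidence `s = 2(p_true − 0.5) ∈ [−1, 1]`. The Isomap implementation is
explicit: symmetrized k-NN graph (k = 10, a connectivity-safe small-n
default) with Euclidean edge weights, all-pairs shortest-path geodesics (a
disconnected graph raises an error naming the component sizes), classical
MDS on the double-centered squared-distance matrix, axes scaled by
√eigenvalue with a deterministic sign convention. Out-of-sample projection
uses the standard Nyström extension: geodesics to the new point are
approximated through its k nearest references, and a point coinciding with
a reference snaps exactly to that reference's embedding (the documented
self-consistency contract). The meta-model stores, per embedded validation
point, the base model with the highest local confidence (ties → lowest model
index) and that model's predicted class; prediction is 1-nearest-neighbor
in the plane (ties → lowest point id), whose decision regions are exactly
the exported Voronoi cells (coincident embedded points share one site;
fewer than 3 distinct sites or collinear sites return a degenerate
half-plane description instead of polygons). Default train/validation/test
proportions are 72/19.6/8.4%, back-computed from a 180/49/21 triple over
n = 250.

## Attribution mapping

Tokens are aligned greedily left-to-right and must partition the SMILES
string. The character→atom map numbers atoms in traversal order (matching
RDKit's numbering for a molecule built from the same string): bracket atoms
own every character between `[` and `]` (stereo markers and bracket
hydrogens inherit the atom), Cl/Br own both letters, and ring-closure
digits, `%nn` closures, parentheses, bond symbols and dots map to no atom.
Each token's score is divided **equally among the distinct atoms its span
touches** — the upstream aggregation rule is unspecified ("not perfectly
precise"), and the equal-share sum is our contract because it is
conservative: the atom total equals the total of atom-touching token
scores to 1e-9. Purely syntactic tokens are known string-representation
artefacts; their scores are dropped by default, with
`syntax_to_neighbors=True` smearing them onto the flanking atoms as the
alternative. Classification uses a relative neutral band: `|score| ≤
0.15·max|score|` → neutral (no published threshold exists for "neutral";
0.15 is our default), otherwise the sign decides.

## Numerical and degenerate-input choices

* Probability threshold ties (`p = 0.5`) predict positive, everywhere.
* Constant columns transform to zeros rather than dividing by zero.
* `tanimoto(∅, ∅) = 1`; Jaccard of two empty scaffold sets = 1.
* Hill-climb improvement threshold 1e-9; BIC tie-break is lexicographic.
* All randomness flows through explicit integer seeds (numpy Generator);
  no global RNG state is touched.

## Known limitations

* The generator produces single-scaffold benzenoid panels only; no
  heteroaromatic or fused-ring chemistry, so scaffold-split generalization
  cannot be studied on it.
* Transformer training (tokenizer pretraining, fine-tuning, layer
  integrated gradients) is out of scope; the attribution consumer is
  model-agnostic and tested with synthetic attributions.
* The Bayesian network is discrete-only and used for blanket extraction,
  not general inference.
* `fit_cpts` iterates rows in Python; adequate for panel-scale data, not
  for large tables.
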