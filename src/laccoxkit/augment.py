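"""Training-set augmentation: Gaussian descriptor noise and SMILES enumeration.

Gaussian-noise injection perturbs each continuous descriptor j by
xi_j ~ N(0, eta * sigma_j), with sigma_j the training sample sd and eta the
noise intensity (the studied levels are 0.1 and 0.2).  Ordinal descriptors
additionally round to the nearest integer and clip to the observed training
range; binary descriptors are left untouched; labels never change.  The
perturbed copies are appended to the originals, doubling n.

SMILES enumeration exploits the many valid linear writings of one molecular
graph: distinct traversal variants (one rooted traversal per atom plus seeded
random traversals) are deduplicated as strings and capped; every variant
re-canonicalizes to the parent molecule, so labels propagate unchanged.
Both augmentations are caller-contracted to touch training data only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from rdkit import Chem

from .data import FeatureKind, SubstrateDataset

__all__ = ["NoiseConfig", "gaussian_augment", "enumerate_smiles"]


@dataclass(frozen=True)
class NoiseConfig:
    """Noise intensity eta (>= 0; studied defaults 0.1 / 0.2) and seed."""

    eta: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be non-negative")


def _inject_noise(
    X: np.ndarray, features, eta: float, rng: np.random.Generator
) -> np.ndarray:
    out = X.astype(float).copy()
    for j, meta in enumerate(features):
        if meta.kind == FeatureKind.CONTINUOUS:
            sigma = float(X[:, j].std(ddof=1)) if len(X) > 1 else 0.0
            out[:, j] += rng.normal(0.0, eta * sigma, size=len(X)) if eta * sigma > 0 else 0.0
        elif meta.kind in (FeatureKind.ORDINAL, FeatureKind.CATEGORICAL):
            sigma = float(X[:, j].std(ddof=1)) if len(X) > 1 else 0.0
            noisy = X[:, j] + (rng.normal(0.0, eta * sigma, size=len(X)) if eta * sigma > 0 else 0.0)
            out[:, j] = np.clip(np.round(noisy), meta.observed_min, meta.observed_max)
        # binary features receive no noise
    return out


def gaussian_augment(ds_train: SubstrateDataset, cfg: NoiseConfig) -> SubstrateDataset:
    """Append one Gaussian-perturbed copy of every training record.

    eta=0 appends exact copies.  Seed-reproducible; labels and SMILES carry
    over to the perturbed copies.
    """
    rng = np.random.default_rng(cfg.seed)
    X = ds_train.X
    noisy = _inject_noise(X, ds_train.features, cfg.eta, rng)
    augmented = [
        replace(r, id=f"{r.id}#gn", descriptors=noisy[i])
        for i, r in enumerate(ds_train.records)
    ]
    return SubstrateDataset(
        [replace(r) for r in ds_train.records] + augmented, list(ds_train.features)
    )


def enumerate_smiles(smiles: str, max_variants: int = 10, seed: int = 0) -> list[str]:
    """Distinct SMILES writings of one molecule, capped at ``max_variants``.

    Candidates are one (non-canonical) rooted traversal per atom plus seeded
    random traversals, deduplicated as strings in deterministic order, so the
    result is monotone non-decreasing in ``max_variants``.  Every variant
    re-canonicalizes to the input's canonical form.
    """
    if max_variants < 1:
        raise ValueError("max_variants must be at least 1")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    seen: dict[str, None] = {}
    for root in range(mol.GetNumAtoms()):
        seen.setdefault(Chem.MolToSmiles(mol, rootedAtAtom=root, canonical=False), None)
    n_random = min(500, 50 * mol.GetNumAtoms())
    # seed folded into RDKit's 32-bit randomization seed
    for variant in Chem.MolToRandomSmilesVect(mol, n_random, (seed % (2**31 - 1)) + 1):
        seen.setdefault(variant, None)
    return list(seen)[:max_variants]
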