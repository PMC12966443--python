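"""Chemical-space characterization of a substrate panel.

Quantifies how structurally diverse a panel is before any modelling:
ECFP4 (radius-2 hashed circular fingerprint) Tanimoto similarities, internal
diversity (one minus the mean pairwise similarity), the nearest-neighbor
similarity distribution (local analog series), Bemis-Murcko scaffold
concentration, and Jaccard overlap of scaffold sets across functional-group
classes.  Laccase panels typically score mean Tanimoto ~0.17 (internal
diversity ~0.83) while their top-3 scaffolds cover >80% of records — high
substituent-level diversity on a narrow benzenoid core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

from .data import SubstrateDataset

__all__ = [
    "Fingerprint",
    "DiversityReport",
    "ecfp4",
    "tanimoto",
    "mean_pairwise_tanimoto",
    "nearest_neighbor_similarities",
    "diversity_report",
    "murcko_scaffold",
    "scaffold_stats",
    "DEFAULT_FG_CLASSES",
]


@dataclass(frozen=True)
class Fingerprint:
    """A hashed circular fingerprint as a set of on-bits."""

    on_bits: frozenset[int]
    n_bits: int = 2048
    radius: int = 2

    def __post_init__(self) -> None:
        if self.on_bits and max(self.on_bits) >= self.n_bits:
            raise ValueError("on_bit index exceeds n_bits")


def ecfp4(smiles: str, n_bits: int = 2048) -> Fingerprint:
    """ECFP4 (Morgan radius 2) fingerprint of a molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(frozenset(bv.GetOnBits()), n_bits=n_bits, radius=2)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A ∩ B| / |A ∪ B|; two empty fingerprints count as identical (1.0)."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint widths differ: {a.n_bits} vs {b.n_bits}")
    union = len(a.on_bits | b.on_bits)
    if union == 0:
        return 1.0
    return len(a.on_bits & b.on_bits) / union


def mean_pairwise_tanimoto(fps: Sequence[Fingerprint]) -> float:
    """Mean Tanimoto over all unordered pairs."""
    n = len(fps)
    if n < 2:
        raise ValueError("need at least 2 fingerprints")
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += tanimoto(fps[i], fps[j])
    return total / (n * (n - 1) / 2)


def nearest_neighbor_similarities(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Per molecule, the maximum Tanimoto similarity to any other molecule."""
    n = len(fps)
    if n < 2:
        raise ValueError("need at least 2 fingerprints")
    sims = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sims[i, j] = sims[j, i] = tanimoto(fps[i], fps[j])
    np.fill_diagonal(sims, -np.inf)
    return sims.max(axis=1)


@dataclass
class DiversityReport:
    mean_tanimoto: float
    internal_diversity: float
    nn_similarities: np.ndarray
    scaffold_coverage: list[tuple[str, float]]
    jaccard_matrix: pd.DataFrame | None


# Functional-group classes used for scaffold-overlap analysis; substructure
# SMARTS are deliberately simple and shippable.
DEFAULT_FG_CLASSES: dict[str, str] = {
    "alcohol": "[OX2H][#6]",
    "ketone": "[#6][CX3](=O)[#6]",
    "aldehyde": "[CX3H1]=O",
    "amine": "[NX3;H2,H1;!$(N-C=O);!$(N~[!#6])]",
}


def murcko_scaffold(smiles: str) -> str:
    """Bemis-Murcko framework (ring systems + linkers), canonical SMILES.

    Acyclic molecules have an empty scaffold.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)


def scaffold_stats(
    ds: SubstrateDataset,
    k: int = 3,
    fg_classes: dict[str, str] | None = None,
) -> tuple[list[tuple[str, float]], float, pd.DataFrame]:
    """Scaffold fractions (descending), top-k cumulative coverage, and the
    Jaccard matrix of scaffold sets across functional-group classes.

    Two classes with no scaffolds at all count as fully overlapping (J=1),
    consistent with the empty-fingerprint Tanimoto convention.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if ds.n < 1:
        raise ValueError("need at least 1 record")
    smiles = [s for s in ds.smiles if s is not None]
    if len(smiles) != ds.n:
        raise ValueError("every record needs a SMILES for scaffold analysis")
    scaffolds = [murcko_scaffold(s) for s in smiles]
    counts: dict[str, int] = {}
    for s in scaffolds:
        counts[s] = counts.get(s, 0) + 1
    fractions = sorted(
        ((scaf, c / len(scaffolds)) for scaf, c in counts.items()),
        key=lambda t: (-t[1], t[0]),
    )
    coverage = sum(f for _, f in fractions[:k])

    fg_classes = DEFAULT_FG_CLASSES if fg_classes is None else fg_classes
    class_scaffolds: dict[str, set[str]] = {}
    for name, smarts in fg_classes.items():
        patt = Chem.MolFromSmarts(smarts)
        members = {
            scaffolds[i]
            for i, smi in enumerate(smiles)
            if Chem.MolFromSmiles(smi).HasSubstructMatch(patt)
        }
        class_scaffolds[name] = members
    names = list(fg_classes)
    jac = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            sa, sb = class_scaffolds[a], class_scaffolds[b]
            union = sa | sb
            jac.iloc[i, j] = 1.0 if not union else len(sa & sb) / len(union)
    return fractions, coverage, jac


def diversity_report(
    data: SubstrateDataset | Sequence[Fingerprint],
    n_bits: int = 2048,
    k: int = 3,
) -> DiversityReport:
    """Full diversity characterization of a panel (or raw fingerprints).

    ``internal_diversity`` is exactly ``1 - mean_tanimoto``.  Scaffold and
    functional-group statistics require a dataset with SMILES and are omitted
    for raw fingerprint input.
    """
    if isinstance(data, SubstrateDataset):
        if data.n < 2:
            raise ValueError("need at least 2 records")
        fps = [ecfp4(s, n_bits=n_bits) for s in data.smiles]
        fractions, _, jac = scaffold_stats(data, k=k)
    else:
        fps = list(data)
        if len(fps) < 2:
            raise ValueError("need at least 2 fingerprints")
        fractions, jac = [], None
    mean = mean_pairwise_tanimoto(fps)
    return DiversityReport(
        mean_tanimoto=mean,
        internal_diversity=1.0 - mean,
        nn_similarities=nearest_neighbor_similarities(fps),
        scaffold_coverage=fractions,
        jaccard_matrix=jac,
    )
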