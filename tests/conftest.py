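import numpy as np
import pytest

from laccoxkit.data import SubstrateDataset, SubstrateRecord, infer_feature_meta
from laccoxkit.synth import GeneratorConfig, generate_panel


@pytest.fixture(scope="session")
def small_panel() -> SubstrateDataset:
    """An 80-molecule synthetic benzenoid panel (session-cached)."""
    return generate_panel(GeneratorConfig(n=80, seed=11))


@pytest.fixture(scope="session")
def medium_panel() -> SubstrateDataset:
    """A 200-molecule panel for evaluation-level tests."""
    return generate_panel(GeneratorConfig(n=200, seed=7))


def make_descriptor_dataset(X, y, smiles=None, feature_names=None) -> SubstrateDataset:
    """Build a dataset directly from arrays (test helper)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = feature_names or [f"f{j}" for j in range(p)]
    features = [infer_feature_meta(names[j], X[:, j]) for j in range(p)]
    records = [
        SubstrateRecord(
            f"r{i}", smiles[i] if smiles else None, int(y[i]) if y[i] in (0, 1) else y[i], X[i]
        )
        for i in range(n)
    ]
    return SubstrateDataset(records, features)


def make_smiles_dataset(smiles, labels=None) -> SubstrateDataset:
    labels = labels if labels is not None else [1] * len(smiles)
    records = [
        SubstrateRecord(f"m{i}", s, int(l), np.empty(0)) for i, (s, l) in enumerate(zip(smiles, labels))
    ]
    return SubstrateDataset(records, [])
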