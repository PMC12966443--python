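"""Substrate datasets: records, feature metadata, readers/writers, splits.

A substrate panel couples, per molecule, a SMILES string, a mixed-type
molecular-descriptor vector and a binary oxidation outcome ("Oxd": did the
substrate show a spectral change under a given laccase).  Ambiguous assay
outcomes are kept as a third label state until :func:`binarize` removes them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from sklearn.model_selection import train_test_split

__all__ = [
    "AMBIGUOUS",
    "FeatureKind",
    "FeatureMeta",
    "SubstrateRecord",
    "SubstrateDataset",
    "infer_feature_meta",
    "read_dataset",
    "write_dataset",
    "binarize",
    "split_train_test",
]

#: Sentinel label for an ambiguous / partial assay response ("±").
AMBIGUOUS = "ambiguous"

#: Distinct integer values at or below which an integer feature is ordinal.
ORDINAL_MAX_CARDINALITY = 20


class FeatureKind(str, Enum):
    CONTINUOUS = "continuous"
    ORDINAL = "ordinal"
    BINARY = "binary"
    CATEGORICAL = "categorical"


@dataclass(frozen=True)
class FeatureMeta:
    """Name, type and observed range of one molecular descriptor."""

    name: str
    kind: FeatureKind
    observed_min: float
    observed_max: float

    def __post_init__(self) -> None:
        if self.observed_min > self.observed_max:
            raise ValueError(
                f"feature {self.name!r}: observed_min {self.observed_min} "
                f"> observed_max {self.observed_max}"
            )


@dataclass
class SubstrateRecord:
    """One substrate: id, SMILES, oxidation label and descriptor vector.

    ``label`` is 0, 1 or :data:`AMBIGUOUS`.  ``smiles`` may be ``None`` for
    descriptor-only tables.
    """

    id: str
    smiles: str | None
    label: int | str
    descriptors: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class SubstrateDataset:
    """Parallel records plus the feature metadata indexing their descriptors."""

    records: list[SubstrateRecord]
    features: list[FeatureMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("record ids are not unique")
        p = len(self.features)
        for r in self.records:
            if len(r.descriptors) != p:
                raise ValueError(
                    f"record {r.id!r}: descriptor length {len(r.descriptors)} "
                    f"!= feature count {p}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def smiles(self) -> list[str | None]:
        return [r.smiles for r in self.records]

    @property
    def X(self) -> np.ndarray:
        """Descriptor matrix, shape (n, p)."""
        if not self.records:
            return np.empty((0, len(self.features)))
        return np.vstack([np.asarray(r.descriptors, dtype=float) for r in self.records])

    @property
    def y(self) -> np.ndarray:
        """Binary label vector; raises if any record is still ambiguous."""
        labels = [r.label for r in self.records]
        if any(l == AMBIGUOUS for l in labels):
            raise ValueError("dataset contains ambiguous labels; call binarize() first")
        return np.asarray(labels, dtype=int)

    def subset(self, indices: Iterable[int]) -> "SubstrateDataset":
        return SubstrateDataset(
            records=[replace(self.records[i]) for i in indices],
            features=list(self.features),
        )


def infer_feature_meta(name: str, values: Sequence[float]) -> FeatureMeta:
    """Infer a feature's kind from its observed values.

    {0,1}-valued -> binary; integer-valued with at most
    :data:`ORDINAL_MAX_CARDINALITY` distinct values -> ordinal; anything else
    -> continuous.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"feature {name!r}: no observations")
    uniq = np.unique(arr)
    if set(uniq.tolist()) <= {0.0, 1.0}:
        kind = FeatureKind.BINARY
    elif np.allclose(arr, np.round(arr)) and uniq.size <= ORDINAL_MAX_CARDINALITY:
        kind = FeatureKind.ORDINAL
    else:
        kind = FeatureKind.CONTINUOUS
    return FeatureMeta(name, kind, float(arr.min()), float(arr.max()))


_AMBIGUOUS_TOKENS = {"±", "+-", "+/-", "ambiguous", "amb"}


def _parse_label(raw: str, record_id: str) -> int | str:
    token = raw.strip()
    if token == "":
        raise ValueError(f"record {record_id!r}: missing label")
    if token.lower() in _AMBIGUOUS_TOKENS:
        return AMBIGUOUS
    try:
        value = float(token)
    except ValueError as exc:
        raise ValueError(f"record {record_id!r}: unrecognized label {raw!r}") from exc
    if value not in (0.0, 1.0):
        raise ValueError(f"record {record_id!r}: label must be 0, 1 or ambiguous, got {raw!r}")
    return int(value)


def read_dataset(
    path: str | Path,
    format: str = "descriptor_csv",
    label_col: str = "Oxd",
    smiles_col: str = "smiles",
    id_col: str = "id",
) -> SubstrateDataset:
    """Read a substrate panel from CSV.

    ``descriptor_csv``: header row names the columns; ``label_col`` is
    mandatory, ``id_col`` and ``smiles_col`` are optional, every other column
    is a descriptor.  ``smiles_csv``: only id/smiles/label columns are used.
    Ambiguous ("±") labels are retained; SMILES that RDKit cannot parse raise
    a record-level error naming the id.
    """
    if format not in ("descriptor_csv", "smiles_csv"):
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        if label_col not in reader.fieldnames:
            raise ValueError(f"{path}: missing label column {label_col!r}")
        rows = list(reader)

    has_id = id_col in rows[0] if rows else False
    has_smiles = smiles_col in rows[0] if rows else False
    descriptor_names = [
        c
        for c in (rows[0].keys() if rows else [])
        if c not in (id_col, smiles_col, label_col)
    ]
    if format == "smiles_csv":
        descriptor_names = []

    records: list[SubstrateRecord] = []
    columns: dict[str, list[float]] = {name: [] for name in descriptor_names}
    for i, row in enumerate(rows):
        rid = row[id_col] if has_id else str(i)
        smiles = row.get(smiles_col) if has_smiles else None
        if smiles is not None:
            if Chem.MolFromSmiles(smiles) is None:
                raise ValueError(f"record {rid!r}: unparseable SMILES {smiles!r}")
        if row.get(label_col) is None:
            raise ValueError(f"record {rid!r}: missing label")
        label = _parse_label(row[label_col], rid)
        values = []
        for name in descriptor_names:
            try:
                v = float(row[name])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"record {rid!r}: non-numeric value {row[name]!r} in column {name!r}"
                ) from exc
            values.append(v)
            columns[name].append(v)
        records.append(SubstrateRecord(rid, smiles, label, np.asarray(values)))

    features = [infer_feature_meta(name, columns[name]) for name in descriptor_names]
    return SubstrateDataset(records, features)


def write_dataset(ds: SubstrateDataset, path: str | Path) -> Path:
    """Write a panel as descriptor CSV (round-trips with :func:`read_dataset`)."""
    path = Path(path)
    has_smiles = any(r.smiles is not None for r in ds.records)
    header = ["id"] + (["smiles"] if has_smiles else []) + ["Oxd"] + ds.feature_names
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in ds.records:
            label = AMBIGUOUS if r.label == AMBIGUOUS else int(r.label)
            row = [r.id] + ([r.smiles or ""] if has_smiles else []) + [label]
            row += [repr(float(v)) for v in r.descriptors]
            writer.writerow(row)
    return path


def binarize(ds: SubstrateDataset, policy: str = "drop_ambiguous") -> SubstrateDataset:
    """Drop ambiguous records so every label is 0/1; errors on empty result."""
    if policy != "drop_ambiguous":
        raise ValueError(f"unknown policy {policy!r}")
    kept = [replace(r) for r in ds.records if r.label != AMBIGUOUS]
    if not kept:
        raise ValueError("binarize: all records are ambiguous, empty result")
    return SubstrateDataset(kept, list(ds.features))


def split_train_test(
    ds: SubstrateDataset, test_fraction: float, seed: int
) -> tuple[SubstrateDataset, SubstrateDataset]:
    """Stratified, exact, seed-reproducible train/test partition."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    labels = [r.label for r in ds.records]
    for lab in set(labels):
        if labels.count(lab) < 2:
            raise ValueError(f"label {lab!r} has fewer than 2 members; cannot stratify")
    idx = np.arange(ds.n)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=labels
    )
    return ds.subset(sorted(train_idx)), ds.subset(sorted(test_idx))
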