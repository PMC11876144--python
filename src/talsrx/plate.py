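"""Data model for KASP genotyping plates.

A KASP (kompetitive allele-specific PCR) assay is read out as a two-channel
endpoint fluorescence signal per well: a relative HEX value ``x`` reporting one
allele and a relative FAM value ``y`` reporting the other.  One plate record
covers a 96-well motherboard layout with 94 DNA wells and 2 no-template
controls (NTC), and optionally carries an expert typing-effect score in
{0, 10, ..., 100}.

The model consumes each plate as a flat 192-dimensional feature vector: the
(x, y) pair of every well, interleaved, DNA wells first in plate order and the
two NTC wells last.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

N_WELLS = 96
N_DNA = 94
N_NTC = 2
N_FEATURES = 2 * N_WELLS
N_CLASSES = 11
SCORES = tuple(range(0, 101, 10))

DNA = "DNA"
NTC = "NTC"
GENOTYPES = ("AA", "BB", "AB")
UNKNOWN = "unknown"


class PlateError(ValueError):
    """Structural problem with a plate record or plate table."""


@dataclass(frozen=True)
class Well:
    """One well: relative HEX signal ``x``, relative FAM signal ``y``."""

    x: float
    y: float
    role: str = DNA
    genotype: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.role not in (DNA, NTC):
            raise PlateError(f"well role must be DNA or NTC, got {self.role!r}")
        if self.genotype not in GENOTYPES + (UNKNOWN,):
            raise PlateError(f"unknown genotype {self.genotype!r}")
        if not (self.x >= 0 and self.y >= 0):
            raise PlateError(
                f"fluorescence signals must be non-negative, got ({self.x}, {self.y})"
            )


@dataclass(frozen=True)
class PlateRecord:
    """One KASP assay: 96 wells (94 DNA + 2 NTC) and an optional score label."""

    snp_id: str
    wells: tuple[Well, ...]
    label: int | None = None

    def __post_init__(self) -> None:
        if len(self.wells) != N_WELLS:
            raise PlateError(
                f"plate {self.snp_id!r}: expected {N_WELLS} wells, got {len(self.wells)}"
            )
        n_ntc = sum(1 for w in self.wells if w.role == NTC)
        if n_ntc != N_NTC:
            raise PlateError(
                f"plate {self.snp_id!r}: expected {N_NTC} NTC wells, got {n_ntc}"
            )
        if self.label is not None:
            validate_score(self.label)

    def dna_wells(self) -> tuple[Well, ...]:
        return tuple(w for w in self.wells if w.role == DNA)

    def ntc_wells(self) -> tuple[Well, ...]:
        return tuple(w for w in self.wells if w.role == NTC)


def validate_score(score: int) -> int:
    """Check that a typing-effect score is one of {0, 10, ..., 100}."""
    if score not in SCORES:
        raise PlateError(
            f"score must be a multiple of 10 in [0, 100], got {score!r}"
        )
    return int(score)


def encode_label(score: int) -> int:
    """Map a typing-effect score to its class index (score / 10)."""
    return validate_score(score) // 10


def decode_label(class_index: int) -> int:
    """Inverse of :func:`encode_label`: class index to score."""
    idx = int(class_index)
    if not 0 <= idx <= 10:
        raise PlateError(f"class index must be in 0..10, got {class_index!r}")
    return idx * 10


def build_feature_vector(plate: PlateRecord) -> np.ndarray:
    """Flatten a plate into its 192-value feature vector.

    Ordering: interleaved (x, y) per well, DNA wells first in plate order,
    the two NTC wells in positions 95-96.
    """
    ordered = plate.dna_wells() + plate.ntc_wells()
    out = np.empty(N_FEATURES, dtype=float)
    out[0::2] = [w.x for w in ordered]
    out[1::2] = [w.y for w in ordered]
    return out


def plate_from_features(
    values: Sequence[float], snp_id: str = "", label: int | None = None
) -> PlateRecord:
    """Rebuild a plate from a 192-value feature vector (genotypes unknown)."""
    vals = np.asarray(values, dtype=float)
    if vals.shape != (N_FEATURES,):
        raise PlateError(
            f"plate {snp_id!r}: expected {N_FEATURES} feature values, got {vals.shape}"
        )
    wells = [
        Well(x=vals[2 * i], y=vals[2 * i + 1], role=DNA if i < N_DNA else NTC)
        for i in range(N_WELLS)
    ]
    return PlateRecord(snp_id=snp_id, wells=tuple(wells), label=label)


@dataclass
class Dataset:
    """A collection of plate records sharing the 96-well layout."""

    records: list[PlateRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labeled(self) -> bool:
        return len(self.records) > 0 and all(r.label is not None for r in self.records)

    def feature_matrix(self) -> np.ndarray:
        """(n_records, 192) matrix of interleaved well signals."""
        if not self.records:
            return np.empty((0, N_FEATURES))
        return np.vstack([build_feature_vector(r) for r in self.records])

    def class_indices(self) -> np.ndarray:
        """Integer class indices 0..10; raises if any record is unlabeled."""
        labels = []
        for r in self.records:
            if r.label is None:
                raise PlateError(f"plate {r.snp_id!r} has no label")
            labels.append(encode_label(r.label))
        return np.asarray(labels, dtype=int)

    def scores(self) -> np.ndarray:
        return np.asarray([r.label for r in self.records])

    def subset(self, indices: Iterable[int]) -> "Dataset":
        return Dataset(records=[self.records[i] for i in indices])


def _feature_columns() -> list[str]:
    return [f"f{i:03d}" for i in range(1, N_FEATURES + 1)]


def write_plate_table(dataset: Dataset, path) -> None:
    """Write a dataset as a comma-delimited plate table.

    Columns: ``snp_id``, ``f001`` ... ``f192`` and, when every record carries a
    score, ``label``.
    """
    cols = _feature_columns()
    df = pd.DataFrame(dataset.feature_matrix(), columns=cols)
    df.insert(0, "snp_id", [r.snp_id for r in dataset.records])
    if dataset.labeled:
        df["label"] = [r.label for r in dataset.records]
    df.to_csv(path, index=False, float_format="%.9g")


def read_plate_table(path) -> Dataset:
    """Read a plate table written by :func:`write_plate_table`.

    A missing ``label`` column yields unlabeled records.  Non-numeric feature
    cells and wrong column counts raise :class:`PlateError` naming the
    offending row/column.
    """
    df = pd.read_csv(path, dtype={"snp_id": str})
    cols = _feature_columns()
    expected = set(cols) | {"snp_id"}
    has_label = "label" in df.columns
    actual = set(df.columns) - {"label"}
    if actual != expected:
        n_feat = len([c for c in df.columns if c not in ("snp_id", "label")])
        raise PlateError(
            f"{path}: expected {N_FEATURES} feature columns f001..f{N_FEATURES}, "
            f"found {n_feat}"
        )
    records = []
    for row_i, row in df.iterrows():
        vals = row[cols]
        numeric = pd.to_numeric(vals, errors="coerce")
        if numeric.isna().any():
            bad = numeric.index[numeric.isna()][0]
            raise PlateError(
                f"{path}: non-numeric feature value at row {row_i}, column {bad}"
            )
        label = None
        if has_label and not pd.isna(row["label"]):
            label = validate_score(int(row["label"]))
        records.append(
            plate_from_features(numeric.to_numpy(float), snp_id=row["snp_id"], label=label)
        )
    return Dataset(records=records)


def split_dataset(
    dataset: Dataset, train_frac: float = 0.84, rng_seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Split into disjoint, exhaustive train/test subsets.

    The train size is round-half-up of ``n * train_frac``.  When labels are
    present the split is stratified by score; a class with fewer than 2
    members triggers a warning and an unstratified fallback.
    """
    if not 0 < train_frac < 1:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    n = len(dataset)
    n_train = int(math.floor(n * train_frac + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    indices = np.arange(n)

    stratify = None
    if dataset.labeled:
        y = dataset.class_indices()
        counts = np.bincount(y, minlength=N_CLASSES)
        present = counts[counts > 0]
        if (present >= 2).all():
            stratify = y
        else:
            warnings.warn(
                "a score class has fewer than 2 members; falling back to an "
                "unstratified split",
                stacklevel=2,
            )
    train_idx, test_idx = train_test_split(
        indices, train_size=n_train, random_state=rng_seed, stratify=stratify
    )
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))


def standardize(X: np.ndarray, mean: np.ndarray | None = None,
                std: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optional feature standardization (off by default in the pipeline:
    relative fluorescence values are already on a common scale)."""
    if mean is None:
        mean = X.mean(axis=0)
    if std is None:
        std = X.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    return (X - mean) / std, mean, std
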