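"""Domain types and file I/O for the drug-repurposing pipeline.

The pipeline works on three kinds of matrices, all exchanged as plain
CSV/TSV with a header row and an identifier column:

* binary entity x feature profiles (drugs: chemical structure, side
  effects, target proteins; diseases: phenotype, target proteins),
* a binary drug x disease association matrix ``Y``,
* square symmetric similarity matrices over one entity class, either
  ``raw`` (cosine, entries in [0, 1], unit diagonal) or ``fused``
  (output of similarity network fusion, non-negative and finite).

Entity order is canonical within a run: the association matrix fixes it,
and profiles are re-indexed to match (see :func:`align_profile`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DdafuseError",
    "DataFormatError",
    "ValidationError",
    "AlignmentError",
    "ParameterError",
    "EntityIndex",
    "FeatureProfile",
    "AssociationMatrix",
    "SimilarityMatrix",
    "VIEW_NAMES",
    "read_binary_profile",
    "read_association_matrix",
    "write_association_matrix",
    "read_similarity",
    "write_similarity",
    "roundtrip_similarity",
    "align_profile",
]

#: the five similarity views of the method: three drug-side, two disease-side
VIEW_NAMES = (
    "chemical_structure",
    "side_effect",
    "drug_target",
    "phenotype",
    "disease_target",
)

SYMMETRY_TOL = 1e-9


class DdafuseError(Exception):
    """Base class for all package errors."""


class DataFormatError(DdafuseError):
    """A file could not be parsed in the expected tabular dialect."""


class ValidationError(DdafuseError):
    """Parsed data violates a domain invariant (non-binary cell, duplicate ID...)."""


class AlignmentError(DdafuseError):
    """Two pipeline objects disagree on entity identity or order."""


class ParameterError(DdafuseError):
    """A configuration value is out of its admissible range."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EntityIndex:
    """Ordered collection of unique entity identifiers (drugs or diseases)."""

    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if list(self.ids).count(i) > 1})
            raise ValidationError(f"duplicate entity IDs: {dupes}")

    @classmethod
    def from_ids(cls, ids: Sequence[str]) -> "EntityIndex":
        return cls(tuple(str(i) for i in ids))

    def __len__(self) -> int:
        return len(self.ids)

    def position(self, entity_id: str) -> int:
        return self.ids.index(entity_id)


@dataclass
class FeatureProfile:
    """Binary entity x feature matrix for one similarity view."""

    entities: EntityIndex
    feature_ids: tuple[str, ...]
    values: np.ndarray  # (n_entities, n_features), entries in {0, 1}
    view_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.entities):
            raise ValidationError(
                f"profile shape {self.values.shape} does not match "
                f"{len(self.entities)} entities"
            )
        if self.values.shape[1] != len(self.feature_ids):
            raise ValidationError("feature ID count does not match value columns")
        if self.values.shape[1] == 0:
            raise ValidationError("no features")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError(f"profile {self.view_name!r} has non-binary entries")
        self.values = self.values.astype(np.int8)


@dataclass
class AssociationMatrix:
    """Binary m x n drug x disease association matrix Y."""

    drugs: EntityIndex
    diseases: EntityIndex
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y)
        if self.Y.shape != (len(self.drugs), len(self.diseases)):
            raise ValidationError(
                f"Y shape {self.Y.shape} does not match "
                f"({len(self.drugs)}, {len(self.diseases)})"
            )
        if not np.isin(self.Y, (0, 1)).all():
            raise ValidationError("association matrix has non-binary entries")
        self.Y = self.Y.astype(np.int8)

    @property
    def n_positive(self) -> int:
        return int(self.Y.sum())


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over one entity class.

    ``kind`` is ``"raw"`` for cosine matrices (entries in [0, 1], unit
    diagonal) and ``"fused"`` for SNF outputs (non-negative, finite).
    """

    entities: EntityIndex
    S: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.entities)
        if self.S.shape != (n, n):
            raise ValidationError(f"similarity shape {self.S.shape} is not ({n}, {n})")
        if self.kind not in ("raw", "fused"):
            raise ValidationError(f"unknown similarity kind {self.kind!r}")
        if not np.isfinite(self.S).all():
            raise ValidationError("similarity matrix has non-finite entries")
        if np.abs(self.S - self.S.T).max() > SYMMETRY_TOL:
            raise ValidationError("similarity matrix is not symmetric")
        if (self.S < 0).any():
            raise ValidationError("similarity matrix has negative entries")
        if self.kind == "raw":
            if (self.S > 1 + 1e-12).any():
                raise ValidationError("raw similarity entries must lie in [0, 1]")
            if np.abs(np.diag(self.S) - 1.0).max() > 1e-12:
                raise ValidationError("raw similarity diagonal must equal 1")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SIG_DIGITS = 12  # serialization precision for similarity matrices


def _read_table(path: str | Path, sep: str | None) -> pd.DataFrame:
    """Read an ID-column + header CSV/TSV into a DataFrame; index = first column."""
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"file not found: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise DataFormatError(f"{path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise DataFormatError(f"{path}: empty file") from exc
    if df.isna().any().any():
        row, col = next(zip(*np.where(df.isna().to_numpy())))
        raise DataFormatError(
            f"{path}: missing/ragged value at row {df.index[row]!r}, "
            f"column {df.columns[col]!r}"
        )
    return df


def _require_binary(df: pd.DataFrame, path: str | Path) -> np.ndarray:
    values = df.to_numpy()
    try:
        numeric = values.astype(float)
    except ValueError as exc:
        raise DataFormatError(f"{path}: non-numeric cell ({exc})") from exc
    bad = ~np.isin(numeric, (0.0, 1.0))
    if bad.any():
        i, j = next(zip(*np.where(bad)))
        raise ValidationError(
            f"{path}: non-binary value {numeric[i, j]!r} at row "
            f"{df.index[i]!r}, column {df.columns[j]!r}"
        )
    return numeric.astype(np.int8)


def read_binary_profile(path: str | Path, view_name: str, sep: str | None = None) -> FeatureProfile:
    """Read a binary entity x feature profile from CSV (or TSV).

    The header row carries feature IDs; the first column carries entity
    IDs. Every cell must parse as 0 or 1.
    """
    df = _read_table(path, sep)
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no features")
    values = _require_binary(df, path)
    return FeatureProfile(
        entities=EntityIndex.from_ids(df.index),
        feature_ids=tuple(str(c) for c in df.columns),
        values=values,
        view_name=view_name,
    )


def read_association_matrix(path: str | Path, sep: str | None = None) -> AssociationMatrix:
    """Read the binary drug x disease association matrix Y.

    Header = disease IDs, first column = drug IDs. Fixes the canonical
    entity order for the run.
    """
    df = _read_table(path, sep)
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no diseases")
    values = _require_binary(df, path)
    return AssociationMatrix(
        drugs=EntityIndex.from_ids(df.index),
        diseases=EntityIndex.from_ids(df.columns),
        Y=values,
    )


def write_association_matrix(path: str | Path, assoc: AssociationMatrix) -> None:
    df = pd.DataFrame(assoc.Y, index=list(assoc.drugs.ids), columns=list(assoc.diseases.ids))
    df.to_csv(path)


def write_profile(path: str | Path, profile: FeatureProfile) -> None:
    df = pd.DataFrame(
        profile.values, index=list(profile.entities.ids), columns=list(profile.feature_ids)
    )
    df.to_csv(path)


def write_similarity(path: str | Path, sim: SimilarityMatrix) -> None:
    """Serialize a similarity matrix with 12 significant digits.

    Raises :class:`ValidationError` if the matrix is asymmetric (checked
    again on write so a mutated array cannot slip through).
    """
    if np.abs(sim.S - sim.S.T).max() > SYMMETRY_TOL:
        raise ValidationError("refusing to write asymmetric similarity matrix")
    df = pd.DataFrame(sim.S, index=list(sim.entities.ids), columns=list(sim.entities.ids))
    df.to_csv(path, float_format=f"%.{_SIG_DIGITS}g")


def read_similarity(path: str | Path, kind: str = "raw", sep: str | None = None) -> SimilarityMatrix:
    df = _read_table(path, sep)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row and column entity IDs differ")
    return SimilarityMatrix(
        entities=EntityIndex.from_ids(df.index), S=df.to_numpy(dtype=float), kind=kind
    )


def roundtrip_similarity(path: str | Path, sim: SimilarityMatrix) -> SimilarityMatrix:
    """Write ``sim`` to ``path`` and read it back (entries preserved to 1e-12)."""
    write_similarity(path, sim)
    return read_similarity(path, kind=sim.kind)


def align_profile(profile: FeatureProfile, index: EntityIndex) -> FeatureProfile:
    """Re-index a profile to the canonical entity order.

    Entities present in the profile but absent from ``index`` are
    rejected; entities missing from the profile likewise. Avoids silent
    misalignment between views and the association matrix.
    """
    have = set(profile.entities.ids)
    want = set(index.ids)
    extra = sorted(have - want)
    if extra:
        raise AlignmentError(
            f"view {profile.view_name!r}: entities not in the association matrix: {extra[:5]}"
        )
    missing = sorted(want - have)
    if missing:
        raise AlignmentError(
            f"view {profile.view_name!r}: entities missing from the profile: {missing[:5]}"
        )
    if profile.entities == index:
        return profile
    order = [profile.entities.position(i) for i in index.ids]
    return FeatureProfile(
        entities=index,
        feature_ids=profile.feature_ids,
        values=profile.values[order],
        view_name=profile.view_name,
    )
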