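"""Cosine similarity between binary feature profiles.

Binary fingerprints (chemical substructures, side-effect flags, target
proteins, phenotype terms) are long and sparse, so the angle between two
profile vectors is a better match signal than Euclidean distance: shared
zeros do not contribute. For entities ``x`` and ``y`` the score is

    cos(x, y) = x . y / (||x|| ||y||)

which lies in [0, 1] for non-negative vectors — 1 for identical non-zero
profiles, 0 for orthogonal (no shared feature) ones.
"""

from __future__ import annotations

import numpy as np

from .core_data import (
    FeatureProfile,
    SimilarityMatrix,
    ValidationError,
    DdafuseError,
)

__all__ = ["cosine", "profile_to_similarity"]


class DimensionError(DdafuseError):
    """Operands have incompatible shapes."""


def cosine(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity of two non-negative vectors.

    An all-zero vector has no direction; its similarity to anything is
    defined as 0 ("no evidence of similarity") rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise DimensionError("cosine expects 1-D vectors")
    if x.shape != y.shape:
        raise DimensionError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("cosine input contains NaN or infinity")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("cosine inputs must be non-negative")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.dot(x, y) / (nx * ny))


def profile_to_similarity(profile: FeatureProfile) -> SimilarityMatrix:
    """Pairwise cosine similarity matrix of a binary profile.

    The diagonal is forced to exactly 1 (including for all-zero rows) so
    no float jitter feeds the fusion step; the matrix is exactly
    symmetric by construction and entries are clipped into [0, 1].
    """
    if len(profile.entities) < 1:
        raise ValidationError("profile has no entities")
    X = profile.values.astype(float)
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms == 0.0, 1.0, norms)
    U = X / safe[:, None]  # zero rows stay zero => similarity 0 to others
    S = U @ U.T
    S = (S + S.T) / 2.0
    np.clip(S, 0.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(entities=profile.entities, S=S, kind="raw")
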