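"""Similarity network fusion (SNF) by iterative cross-diffusion.

Merges several similarity matrices over the same entities into one
comprehensive matrix. Each view ``v`` is represented twice:

* a *full kernel* ``P_v`` — the row-normalized status matrix carrying
  the view's global similarity information, with half the row mass kept
  on the diagonal:  P(i,j) = W(i,j) / (2 * sum_{k!=i} W(i,k)) for j != i,
  P(i,i) = 1/2 (every row sums to 1);
* a *local kernel* ``S_v`` — the row-normalized restriction of ``W`` to
  each entity's K nearest neighbours, which encodes the (more reliable)
  local topology and drives the diffusion.

The cross-diffusion update propagates each view's status through the
other views' local structure:

    P_v  <-  S_v @ mean_{u != v}(P_u) @ S_v.T

followed by symmetrization and (by default) re-normalization, for T
iterations; the fused matrix is the average of the final status
matrices. Here the three drug views fuse into the unified drug
similarity (UDRS) and the two disease views into the unified disease
similarity (UDIS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_data import (
    AlignmentError,
    ParameterError,
    SimilarityMatrix,
    ValidationError,
)

__all__ = ["SNFConfig", "full_kernel_normalize", "knn_kernel", "snf"]

logger = logging.getLogger(__name__)


@dataclass
class SNFConfig:
    """Hyperparameters of the fusion.

    K : int
        neighbourhood size of the local kernel; clamped to n_entities - 1
        for small problems.
    T : int
        number of cross-diffusion iterations (0 = no diffusion, the
        output is the mean of the normalized views).
    convergence_tol : float | None
        optional early stop once max |P_t - P_{t-1}| over all views
        falls below this value.
    renormalize : bool
        re-apply the full-kernel normalization after every iteration
        (keeps the matrices row-stochastic and prevents drift).
    rescale : bool
        divide the fused matrix by its maximum entry so it lies in
        [0, 1] before merging with the association labels.
    """

    K: int = 20
    T: int = 20
    convergence_tol: float | None = None
    renormalize: bool = True
    rescale: bool = False

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ParameterError(f"K must be >= 1, got {self.K}")
        if self.T < 0:
            raise ParameterError(f"T must be >= 0, got {self.T}")
        if self.convergence_tol is not None and self.convergence_tol < 0:
            raise ParameterError("convergence_tol must be >= 0")


def _check_square_symmetric(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValidationError(f"expected a square matrix, got shape {W.shape}")
    if not np.isfinite(W).all():
        raise ValidationError("matrix has non-finite entries")
    if (W < 0).any():
        raise ValidationError("matrix has negative entries")
    if np.abs(W - W.T).max() > 1e-9:
        raise ValidationError("matrix is not symmetric")
    return W


def full_kernel_normalize(W: np.ndarray | SimilarityMatrix) -> np.ndarray:
    """Row-normalize ``W`` into a status matrix with diagonal 1/2.

    Rows with zero off-diagonal mass (isolated entities) become identity
    rows and a warning is logged.
    """
    if isinstance(W, SimilarityMatrix):
        W = W.S
    W = _check_square_symmetric(W)
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    row_mass = off.sum(axis=1)
    isolated = row_mass == 0.0
    if isolated.any():
        logger.warning(
            "full_kernel_normalize: %d isolated entit%s (zero off-diagonal mass)",
            int(isolated.sum()),
            "y" if isolated.sum() == 1 else "ies",
        )
    denom = np.where(isolated, 1.0, 2.0 * row_mass)
    P = off / denom[:, None]
    np.fill_diagonal(P, 0.5)
    P[isolated] = 0.0
    P[isolated, np.nonzero(isolated)[0]] = 1.0
    return P


def knn_kernel(W: np.ndarray | SimilarityMatrix, K: int) -> np.ndarray:
    """Sparse local kernel: each row renormalized over its K nearest neighbours.

    Neighbour sets exclude self; ties are broken by the smallest entity
    index so the kernel is deterministic. A row whose K neighbours all
    have similarity 0 stays all-zero.
    """
    if isinstance(W, SimilarityMatrix):
        W = W.S
    W = _check_square_symmetric(W)
    n = W.shape[0]
    if not 1 <= K < n:
        raise ParameterError(f"K must satisfy 1 <= K < {n}, got {K}")
    S = np.zeros_like(W)
    idx = np.arange(n)
    for i in range(n):
        row = W[i]
        # sort by descending similarity, then ascending index; drop self
        order = np.lexsort((idx, -row))
        order = order[order != i][:K]
        mass = row[order].sum()
        if mass > 0.0:
            S[i, order] = row[order] / mass
    return S


def snf(
    views: list[SimilarityMatrix],
    cfg: SNFConfig | None = None,
) -> SimilarityMatrix:
    """Fuse several similarity views over the same entities.

    With a single view the result is its full-kernel normalized,
    symmetrized form; with several views the cross-diffusion iteration
    described in the module docstring runs for ``cfg.T`` steps (or until
    ``cfg.convergence_tol``). Deterministic for fixed inputs and config.
    """
    if cfg is None:
        cfg = SNFConfig()
    if not views:
        raise ValidationError("snf requires at least one view")
    entities = views[0].entities
    for v in views[1:]:
        if v.entities != entities:
            raise AlignmentError("snf views must share one entity index")
    n = len(entities)
    if n < 2:
        raise ValidationError("snf requires at least 2 entities")

    if len(views) == 1:
        P = full_kernel_normalize(views[0].S)
        P = (P + P.T) / 2.0
        if cfg.rescale and P.max() > 0:
            P = P / P.max()
        return SimilarityMatrix(entities=entities, S=P, kind="fused")

    K = min(cfg.K, n - 1)
    P = [full_kernel_normalize(v.S) for v in views]
    S = [knn_kernel(v.S, K) for v in views]
    nv = len(views)

    for t in range(1, cfg.T + 1):
        P_prev = P
        P_new = []
        for v in range(nv):
            mean_others = sum(P_prev[u] for u in range(nv) if u != v) / (nv - 1)
            Pv = S[v] @ mean_others @ S[v].T
            Pv = (Pv + Pv.T) / 2.0
            if cfg.renormalize:
                Pv = full_kernel_normalize(Pv)
            P_new.append(Pv)
        delta = max(np.abs(P_new[v] - P_prev[v]).max() for v in range(nv))
        logger.debug("snf iteration %d: max |dP| = %.3e", t, delta)
        P = P_new
        if cfg.convergence_tol is not None and delta < cfg.convergence_tol:
            logger.info("snf converged after %d iterations (dP=%.3e)", t, delta)
            break

    fused = sum(P) / nv
    fused = (fused + fused.T) / 2.0
    if cfg.rescale and fused.max() > 0:
        fused = fused / fused.max()
    return SimilarityMatrix(entities=entities, S=fused, kind="fused")
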