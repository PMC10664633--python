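"""Class balancing of the pair table by synthetic minority oversampling.

Observed drug-disease pair tables are imbalanced; SMOTE appends
interpolated minority points until the minority/majority count ratio
(the *balance rate*) reaches a target, 0.9 by default. Each synthetic
point is x + lambda * (x_nn - x) for a uniformly chosen minority row x,
one of its k nearest minority neighbours x_nn (Euclidean distance in the
m+n feature space, ties broken by index) and lambda ~ Uniform(0, 1).

The minority class is detected from the counts rather than hard-coded:
real association data is typically short on negatives, but synthetic
datasets may invert the imbalance. Balancing belongs inside each
training fold only; applying it before the split leaks synthetic
neighbours of test points into training.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import pairwise_distances

from .core_data import ParameterError, ValidationError
from .pair_features import PROV_SYNTHETIC, PairFeatureTable

__all__ = ["BalanceConfig", "minority_target_count", "smote"]

logger = logging.getLogger(__name__)


@dataclass
class BalanceConfig:
    """SMOTE settings: target minority/majority ratio, neighbour count, seed."""

    target_ratio: float = 0.9
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_ratio <= 1.0:
            raise ParameterError(f"target_ratio must be in (0, 1], got {self.target_ratio}")
        if self.k_neighbors < 1:
            raise ParameterError(f"k_neighbors must be >= 1, got {self.k_neighbors}")


def minority_target_count(n_minority: int, n_majority: int, ratio: float) -> int:
    """Number of synthetic rows needed to lift the balance rate to ``ratio``.

    max(0, ceil(ratio * n_majority) - n_minority), with the ceiling
    evaluated with a small slack so decimal ratios behave as written
    (0.9 * 500 must give 450, not 451).
    """
    if n_minority < 0 or n_majority < 0:
        raise ParameterError("class counts must be non-negative")
    target = math.ceil(ratio * n_majority - 1e-9)
    return max(0, target - n_minority)


def smote(table: PairFeatureTable, cfg: BalanceConfig) -> PairFeatureTable:
    """Append synthetic minority rows to reach the target balance rate.

    Observed rows are never modified or dropped; synthetic rows carry
    ``provenance == "synthetic"`` and the minority label. Deterministic
    for a fixed seed.
    """
    labels = table.labels
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("smote requires both classes present (minority class empty)")
    minority_label = 0 if n_neg < n_pos else 1
    n_minority = min(n_pos, n_neg)
    n_majority = max(n_pos, n_neg)
    if n_minority <= cfg.k_neighbors:
        raise ParameterError(
            f"minority class size {n_minority} must exceed k_neighbors={cfg.k_neighbors}"
        )

    n_new = minority_target_count(n_minority, n_majority, cfg.target_ratio)
    if n_new == 0:
        return table

    minority_idx = np.flatnonzero(labels == minority_label)
    X_min = table.features[minority_idx]

    # k nearest minority neighbours per minority row, ties by ascending index
    dists = pairwise_distances(X_min)
    order_keys = np.arange(len(minority_idx))
    neighbours = np.empty((len(minority_idx), cfg.k_neighbors), dtype=int)
    for i in range(len(minority_idx)):
        order = np.lexsort((order_keys, dists[i]))
        order = order[order != i][: cfg.k_neighbors]
        neighbours[i] = order

    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, len(minority_idx), size=n_new)
    nn_choice = rng.integers(0, cfg.k_neighbors, size=n_new)
    lam = rng.random(n_new)
    x = X_min[base]
    x_nn = X_min[neighbours[base, nn_choice]]
    synthetic = x + lam[:, None] * (x_nn - x)

    achieved = (n_minority + n_new) / n_majority
    logger.info(
        "smote: appended %d synthetic label-%d rows (balance rate %.4f -> %.4f)",
        n_new, minority_label, n_minority / n_majority, achieved,
    )

    syn_ids = np.array([f"syn{i}" for i in range(n_new)], dtype=object)
    return PairFeatureTable(
        drug_ids=np.concatenate([table.drug_ids, syn_ids]),
        disease_ids=np.concatenate([table.disease_ids, syn_ids]),
        labels=np.concatenate([table.labels, np.full(n_new, minority_label, dtype=np.int8)]),
        features=np.vstack([table.features, synthetic]),
        provenance=np.concatenate(
            [table.provenance, np.full(n_new, PROV_SYNTHETIC, dtype=object)]
        ),
        feature_names=table.feature_names,
    )
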