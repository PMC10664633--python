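"""Evaluation: confusion metrics, ROC/PR areas, (repeated) k-fold
cross-validation, and the new-drug leave-one-association-out ranking
experiment.

Metric definitions are the standard ones:

    Acc  = (TP + TN) / (TP + TN + FP + FN)
    Prec = TP / (TP + FP)
    Rec  = TP / (TP + FN)
    F1   = 2 * Prec * Rec / (Prec + Rec)

with precision/recall/F1 defined as 0 when their denominator vanishes.
Cross-validation splits the observed (drug, disease) pairs; SMOTE runs
on the training portion of each fold only, so synthetic rows never reach
a test fold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import (
    auc as _trapezoid_auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)
from sklearn.model_selection import KFold

from .balance import BalanceConfig, smote
from .classifier import MLPModel, NetworkConfig, build_model, predict_scores, train
from .core_data import (
    AssociationMatrix,
    ParameterError,
    SimilarityMatrix,
    ValidationError,
)
from .pair_features import PROV_SYNTHETIC, PairFeatureTable, build_pair_table

__all__ = [
    "ConfusionCounts",
    "FoldResult",
    "EvaluationReport",
    "NewDrugResult",
    "confusion_counts",
    "classification_metrics",
    "curve_auc",
    "kfold_split",
    "cross_validate",
    "singleton_drugs",
    "new_drug_precision_at_1",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# confusion counts and threshold metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_counts(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Confusion matrix at a score threshold (score >= threshold => positive)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise ValidationError("confusion_counts: empty input")
    if labels.shape != scores.shape:
        raise ValidationError("labels and scores must have equal length")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from confusion counts."""
    if c.total == 0:
        raise ValidationError("classification_metrics: zero total count")
    accuracy = (c.TP + c.TN) / c.total
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else 0.0
    recall = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


# ---------------------------------------------------------------------------
# ranking curves
# ---------------------------------------------------------------------------


def curve_auc(
    labels: np.ndarray, scores: np.ndarray, mode: str = "roc"
) -> tuple[float, np.ndarray, np.ndarray]:
    """Area under the ROC or precision-recall curve, plus the curve points.

    ROC uses the trapezoidal rule over all score thresholds (tied scores
    grouped); PR uses the step-wise average-precision rule. Returns
    ``(area, x, y)`` with x/y = (fpr, tpr) or (recall, precision).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValidationError("curve_auc requires both classes present")
    if mode == "roc":
        fpr, tpr, _ = roc_curve(labels, scores)
        return float(_trapezoid_auc(fpr, tpr)), fpr, tpr
    if mode == "pr":
        precision, recall, _ = precision_recall_curve(labels, scores)
        area = float(average_precision_score(labels, scores))
        return area, recall[::-1], precision[::-1]
    raise ParameterError(f"unknown curve mode {mode!r}")


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def kfold_split(num_rows: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle split into k disjoint folds with sizes differing by <= 1."""
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > num_rows:
        raise ParameterError(f"k={k} exceeds the number of rows ({num_rows})")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.arange(num_rows))]


@dataclass
class FoldResult:
    round_index: int
    fold_index: int
    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f1: float
    auroc: float
    aupr: float
    roc_points: tuple[np.ndarray, np.ndarray] | None = None
    pr_points: tuple[np.ndarray, np.ndarray] | None = None


_METRICS = ("accuracy", "precision", "recall", "f1", "auroc", "aupr")


@dataclass
class EvaluationReport:
    """Per-fold results plus aggregate mean/std for each metric."""

    folds: list[FoldResult]
    k: int
    rounds: int
    seed: int

    def aggregate(self) -> dict[str, dict[str, float]]:
        out = {}
        for name in _METRICS:
            vals = np.array([getattr(f, name) for f in self.folds])
            out[name] = {"mean": float(vals.mean()), "std": float(vals.std())}
        return out

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "rounds": self.rounds,
            "seed": self.seed,
            "aggregate": self.aggregate(),
            "folds": [
                {
                    "round": f.round_index,
                    "fold": f.fold_index,
                    "counts": asdict(f.counts),
                    **{name: getattr(f, name) for name in _METRICS},
                }
                for f in self.folds
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _evaluate_fold(
    labels: np.ndarray,
    scores: np.ndarray,
    threshold: float,
    round_index: int,
    fold_index: int,
    keep_curves: bool,
) -> FoldResult:
    counts = confusion_counts(labels, scores, threshold)
    metrics = classification_metrics(counts)
    auroc, fpr, tpr = curve_auc(labels, scores, "roc")
    aupr, rec, prec = curve_auc(labels, scores, "pr")
    return FoldResult(
        round_index=round_index,
        fold_index=fold_index,
        counts=counts,
        auroc=auroc,
        aupr=aupr,
        roc_points=(fpr, tpr) if keep_curves else None,
        pr_points=(rec, prec) if keep_curves else None,
        **metrics,
    )


def cross_validate(
    table: PairFeatureTable,
    net_cfg: NetworkConfig | None = None,
    bal_cfg: BalanceConfig | None = None,
    k: int = 5,
    rounds: int = 1,
    seed: int = 0,
    threshold: float = 0.5,
    validation_fraction: float = 0.0,
    keep_curves: bool = False,
) -> EvaluationReport:
    """Repeated k-fold cross-validation of the full train/score cycle.

    Each round reshuffles the folds with a fresh seed. Within a fold the
    training rows are SMOTE-balanced, a model is trained from scratch,
    and the untouched test fold is scored. The input table must contain
    observed rows only.
    """
    net_cfg = net_cfg or NetworkConfig()
    bal_cfg = bal_cfg or BalanceConfig()
    if (table.provenance == PROV_SYNTHETIC).any():
        raise ValidationError("cross_validate expects an unbalanced (observed-only) table")
    folds_out: list[FoldResult] = []
    for r in range(rounds):
        fold_indices = kfold_split(table.n_rows, k, seed + r)
        for fi, test_idx in enumerate(fold_indices):
            train_mask = np.ones(table.n_rows, dtype=bool)
            train_mask[test_idx] = False
            train_table = table.subset(np.flatnonzero(train_mask))
            test_table = table.subset(test_idx)
            fold_bal = BalanceConfig(
                target_ratio=bal_cfg.target_ratio,
                k_neighbors=bal_cfg.k_neighbors,
                seed=bal_cfg.seed + 1000 * r + fi,
            )
            balanced = smote(train_table, fold_bal)
            assert not (test_table.provenance == PROV_SYNTHETIC).any()
            fold_net = NetworkConfig(**{**asdict(net_cfg), "seed": net_cfg.seed + 1000 * r + fi})
            model = build_model(table.n_features, fold_net)
            train(model, balanced, fold_net, validation_fraction)
            scores = predict_scores(model, test_table.features)
            result = _evaluate_fold(
                test_table.labels, scores, threshold, r, fi, keep_curves
            )
            logger.info(
                "round %d fold %d: acc=%.3f auroc=%.3f aupr=%.3f",
                r, fi, result.accuracy, result.auroc, result.aupr,
            )
            folds_out.append(result)
    return EvaluationReport(folds=folds_out, k=k, rounds=rounds, seed=seed)


# ---------------------------------------------------------------------------
# new-drug experiment
# ---------------------------------------------------------------------------


def singleton_drugs(assoc: AssociationMatrix) -> list[int]:
    """Indices of drugs with exactly one known associated disease."""
    return [int(i) for i in np.flatnonzero(assoc.Y.sum(axis=1) == 1)]


@dataclass
class NewDrugResult:
    successes: int
    total: int
    per_drug: list[dict] = field(default_factory=list)

    @property
    def fraction(self) -> float:
        return self.successes / self.total if self.total else 0.0


def _rank_first(scores: np.ndarray) -> int:
    """Index ranked first: highest score, ties broken by ascending index."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    return int(order[0])


def new_drug_precision_at_1(
    udrs: SimilarityMatrix | None,
    udis: SimilarityMatrix | None,
    assoc: AssociationMatrix,
    drugs: Sequence[int] | None = None,
    net_cfg: NetworkConfig | None = None,
    bal_cfg: BalanceConfig | None = None,
    seed: int = 0,
    mode: str = "shared",
    score_matrix: np.ndarray | None = None,
    validation_fraction: float = 0.0,
) -> NewDrugResult:
    """Leave-one-association-out ranking for drugs with a single association.

    For each singleton drug its only known disease is withheld, every
    disease is ranked by predicted score, and the drug counts as a
    success iff the withheld disease ranks first (ties broken by
    ascending disease index) — the "maximum precision 1.0" criterion.

    ``mode="shared"`` trains one model with all the subset's labels
    removed and scores every subset drug with it; ``mode="per_drug"``
    retrains with only the current drug's label removed (slower, closer
    to a literal per-drug protocol). Supplying ``score_matrix`` (m x n)
    skips training and ranks from the given scores — used for oracle
    and random-baseline controls.
    """
    if drugs is None:
        drugs = singleton_drugs(assoc)
    drugs = list(drugs)
    if not drugs:
        raise ValidationError("no drugs with exactly one association")
    row_sums = assoc.Y.sum(axis=1)
    for d in drugs:
        if row_sums[d] != 1:
            raise ValidationError(
                f"drug index {d} has {int(row_sums[d])} associations, expected exactly 1"
            )
    held_out = {d: int(np.flatnonzero(assoc.Y[d])[0]) for d in drugs}
    m, n = assoc.Y.shape

    def rank_and_score(d: int, scores: np.ndarray) -> dict:
        first = _rank_first(scores)
        return {
            "drug_index": d,
            "drug_id": assoc.drugs.ids[d],
            "held_out_disease": assoc.diseases.ids[held_out[d]],
            "top_disease": assoc.diseases.ids[first],
            "success": first == held_out[d],
        }

    per_drug: list[dict] = []
    if score_matrix is not None:
        score_matrix = np.asarray(score_matrix, dtype=float)
        if score_matrix.shape != (m, n):
            raise ValidationError(f"score matrix shape {score_matrix.shape} != ({m}, {n})")
        for d in drugs:
            per_drug.append(rank_and_score(d, score_matrix[d]))
    else:
        if udrs is None or udis is None:
            raise ValidationError("model-based ranking needs UDRS and UDIS")
        net_cfg = net_cfg or NetworkConfig()
        bal_cfg = bal_cfg or BalanceConfig()

        def train_and_score(masked_rows: Sequence[int]) -> MLPModel:
            Y2 = assoc.Y.copy()
            Y2[list(masked_rows), :] = 0
            masked = AssociationMatrix(drugs=assoc.drugs, diseases=assoc.diseases, Y=Y2)
            table = build_pair_table(udrs, udis, masked)
            balanced = smote(table, BalanceConfig(
                target_ratio=bal_cfg.target_ratio,
                k_neighbors=bal_cfg.k_neighbors,
                seed=bal_cfg.seed + seed,
            ))
            model = build_model(table.n_features, net_cfg)
            return train(model, balanced, net_cfg, validation_fraction)

        if mode == "shared":
            model = train_and_score(drugs)
            for d in drugs:
                feats = np.hstack([np.tile(udrs.S[d], (n, 1)), udis.S])
                per_drug.append(rank_and_score(d, predict_scores(model, feats)))
        elif mode == "per_drug":
            for d in drugs:
                model = train_and_score([d])
                feats = np.hstack([np.tile(udrs.S[d], (n, 1)), udis.S])
                per_drug.append(rank_and_score(d, predict_scores(model, feats)))
        else:
            raise ParameterError(f"unknown mode {mode!r}")

    successes = sum(1 for rec in per_drug if rec["success"])
    logger.info(
        "new-drug experiment: %d/%d drugs ranked their held-out disease first",
        successes, len(per_drug),
    )
    return NewDrugResult(successes=successes, total=len(per_drug), per_drug=per_drug)
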