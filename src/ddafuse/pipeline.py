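"""End-to-end orchestration: config file -> artifacts on disk.

Stage order: read or generate the five profiles and Y; cosine
similarity per view; SNF-fuse the three drug views into UDRS and the
two disease views into UDIS; assemble the pair table F; repeated k-fold
cross-validation with per-fold SMOTE; optionally the new-drug ranking
experiment and a comprehensive prediction pass (train on all known
associations, rank every unknown pair per disease).

Every random behaviour is keyed to a named seed in the config, so a
re-run with the same config reproduces every artifact byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .balance import BalanceConfig, smote
from .classifier import NetworkConfig, build_model, history_to_csv, predict_scores, train
from .core_data import (
    AssociationMatrix,
    DdafuseError,
    FeatureProfile,
    ParameterError,
    SimilarityMatrix,
    align_profile,
    read_association_matrix,
    read_binary_profile,
    write_similarity,
)
from .evaluation import (
    EvaluationReport,
    NewDrugResult,
    cross_validate,
    new_drug_precision_at_1,
    singleton_drugs,
)
from .pair_features import PairFeatureTable, build_pair_table
from .similarity import profile_to_similarity
from .snf import SNFConfig, snf
from .synthetic import DRUG_VIEWS, DISEASE_VIEWS, SyntheticConfig, generate

__all__ = ["RunConfig", "RunResult", "run", "load_config"]

logger = logging.getLogger(__name__)

INPUT_KEYS = DRUG_VIEWS + DISEASE_VIEWS + ("associations",)


@dataclass
class RunConfig:
    """Full pipeline configuration; exactly one of inputs / synthetic."""

    inputs: dict[str, str] | None = None
    synthetic: SyntheticConfig | None = None
    snf: SNFConfig = field(default_factory=SNFConfig)
    balance: BalanceConfig = field(default_factory=BalanceConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    k: int = 5
    rounds: int = 1
    threshold: float = 0.5
    seed: int = 0
    new_drug: bool = False
    new_drug_mode: str = "shared"
    predict: bool = False
    export_pair_table: bool = True
    output_dir: str = "ddafuse_run"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ParameterError(
                "exactly one of 'inputs' and 'synthetic' must be configured"
            )
        if self.inputs is not None:
            missing = [k for k in INPUT_KEYS if k not in self.inputs]
            if missing:
                raise ParameterError(f"missing input paths: {missing}")


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration."""
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict[str, Any] = {}
    if "inputs" in raw:
        kwargs["inputs"] = dict(raw["inputs"])
    if "synthetic" in raw:
        kwargs["synthetic"] = SyntheticConfig(**(raw["synthetic"] or {}))
    if "snf" in raw:
        kwargs["snf"] = SNFConfig(**(raw["snf"] or {}))
    if "balance" in raw:
        kwargs["balance"] = BalanceConfig(**(raw["balance"] or {}))
    if "network" in raw:
        kwargs["network"] = NetworkConfig(**(raw["network"] or {}))
    for key in (
        "k", "rounds", "threshold", "seed", "new_drug", "new_drug_mode",
        "predict", "export_pair_table", "output_dir",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    unknown = set(raw) - set(kwargs) - {"inputs", "synthetic", "snf", "balance", "network"}
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**kwargs)


@dataclass
class RunResult:
    udrs: SimilarityMatrix
    udis: SimilarityMatrix
    table: PairFeatureTable
    report: EvaluationReport
    new_drug: NewDrugResult | None = None
    output_dir: Path | None = None


def _load_inputs(cfg: RunConfig) -> tuple[list[FeatureProfile], list[FeatureProfile], AssociationMatrix]:
    if cfg.synthetic is not None:
        data = generate(cfg.synthetic)
        return data.drug_profiles, data.disease_profiles, data.assoc
    assert cfg.inputs is not None
    assoc = read_association_matrix(cfg.inputs["associations"])
    drug_profiles = [
        align_profile(read_binary_profile(cfg.inputs[v], v), assoc.drugs)
        for v in DRUG_VIEWS
    ]
    disease_profiles = [
        align_profile(read_binary_profile(cfg.inputs[v], v), assoc.diseases)
        for v in DISEASE_VIEWS
    ]
    return drug_profiles, disease_profiles, assoc


def fuse_views(profiles: list[FeatureProfile], snf_cfg: SNFConfig) -> SimilarityMatrix:
    """Cosine similarity per view, then SNF across the views."""
    return snf([profile_to_similarity(p) for p in profiles], snf_cfg)


def comprehensive_prediction(
    udrs: SimilarityMatrix,
    udis: SimilarityMatrix,
    assoc: AssociationMatrix,
    net_cfg: NetworkConfig,
    bal_cfg: BalanceConfig,
) -> pd.DataFrame:
    """Train on all known associations and rank every unknown pair.

    Returns a table of (disease, drug, score) rows covering only pairs
    with Y = 0, sorted by descending score within each disease.
    """
    table = build_pair_table(udrs, udis, assoc)
    balanced = smote(table, bal_cfg)
    model = build_model(table.n_features, net_cfg)
    train(model, balanced, net_cfg)
    scores = predict_scores(model, table.features).reshape(assoc.Y.shape)
    rows = []
    for j, disease in enumerate(assoc.diseases.ids):
        unknown = np.flatnonzero(assoc.Y[:, j] == 0)
        order = unknown[np.lexsort((unknown, -scores[unknown, j]))]
        for rank, i in enumerate(order, start=1):
            rows.append(
                {
                    "disease": disease,
                    "rank": rank,
                    "drug": assoc.drugs.ids[i],
                    "score": scores[i, j],
                }
            )
    return pd.DataFrame(rows)


def run(cfg: RunConfig) -> RunResult:
    """Execute the configured pipeline and write all artifacts."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("ddafuse")
    root.addHandler(log_handler)
    previous_level = root.level
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)
    try:
        logger.info("run config: %s", json.dumps(asdict(cfg), default=str))
        drug_profiles, disease_profiles, assoc = _load_inputs(cfg)
        if assoc.n_positive == 0:
            logger.warning("association matrix has zero positives")
        m, n = assoc.Y.shape
        logger.info("%d drugs x %d diseases, %d known associations", m, n, assoc.n_positive)

        udrs = fuse_views(drug_profiles, cfg.snf)
        udis = fuse_views(disease_profiles, cfg.snf)
        write_similarity(outdir / "UDRS.csv", udrs)
        write_similarity(outdir / "UDIS.csv", udis)

        table = build_pair_table(udrs, udis, assoc)
        if cfg.export_pair_table:
            table.to_csv(outdir / "F.csv")

        report = cross_validate(
            table,
            net_cfg=cfg.network,
            bal_cfg=cfg.balance,
            k=cfg.k,
            rounds=cfg.rounds,
            seed=cfg.seed,
            threshold=cfg.threshold,
            keep_curves=True,
        )
        report.to_json(outdir / "metrics.json")
        first = report.folds[0]
        if first.roc_points is not None:
            pd.DataFrame({"fpr": first.roc_points[0], "tpr": first.roc_points[1]}).to_csv(
                outdir / "roc_fold0.csv", index=False
            )
            pd.DataFrame(
                {"recall": first.pr_points[0], "precision": first.pr_points[1]}
            ).to_csv(outdir / "pr_fold0.csv", index=False)

        nd_result = None
        if cfg.new_drug:
            cohort = singleton_drugs(assoc)
            if cohort:
                nd_result = new_drug_precision_at_1(
                    udrs, udis, assoc,
                    drugs=cohort,
                    net_cfg=cfg.network,
                    bal_cfg=cfg.balance,
                    seed=cfg.seed,
                    mode=cfg.new_drug_mode,
                )
                (outdir / "new_drug.json").write_text(
                    json.dumps(
                        {
                            "successes": nd_result.successes,
                            "total": nd_result.total,
                            "fraction": nd_result.fraction,
                            "per_drug": nd_result.per_drug,
                        },
                        indent=2,
                    )
                )
            else:
                logger.warning("new-drug experiment skipped: no singleton drugs")

        if cfg.predict:
            ranked = comprehensive_prediction(udrs, udis, assoc, cfg.network, cfg.balance)
            ranked.to_csv(outdir / "ranked_candidates.csv", index=False)

        logger.info("aggregate metrics: %s", json.dumps(report.aggregate()))
        return RunResult(
            udrs=udrs, udis=udis, table=table, report=report,
            new_drug=nd_result, output_dir=outdir,
        )
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
        root.setLevel(previous_level)
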