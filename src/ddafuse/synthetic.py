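"""Synthetic multi-view drug/disease data with planted group structure.

Stands in for curated association benchmarks so the whole pipeline is
testable offline. Drugs are assigned round-robin to G groups and
diseases to H groups; each group draws one random binary prototype per
view and every entity's profile is its prototype with independent
per-bit noise. A random G x H binary compatibility table decides which
(drug group, disease group) cells are enriched: compatible pairs are
associated with probability ``p_hi``, incompatible ones with ``p_lo``.
The cell-wise probabilities are returned as the ground-truth affinity
matrix, which upper-bounds what any classifier can recover.

A configurable fraction of drugs is post-processed to retain exactly
one association (their highest-affinity disease, ties by index), which
guarantees a populated cohort for the new-drug ranking experiment.

What this emulates: multi-source binary fingerprints whose within-group
similarity exceeds between-group similarity, and an association matrix
driven by latent compatibility. What it does not emulate: real
fingerprint sparsity patterns, correlated views, or the marginal
statistics of curated datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_data import (
    AssociationMatrix,
    EntityIndex,
    FeatureProfile,
    ParameterError,
    write_association_matrix,
    write_profile,
)

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "permute_labels"]

DRUG_VIEWS = ("chemical_structure", "side_effect", "drug_target")
DISEASE_VIEWS = ("phenotype", "disease_target")


@dataclass
class SyntheticConfig:
    """Study conditions of the planted-structure generator.

    Defaults are the package's documented fixture: 60 drugs in 4 groups,
    40 diseases in 4 groups, 5% bit noise, association probability 0.9
    in compatible group cells vs 0.02 elsewhere.
    """

    m: int = 60
    n: int = 40
    G: int = 4
    H: int = 4
    drug_features: tuple[int, int, int] = (64, 48, 32)
    disease_features: tuple[int, int] = (48, 32)
    p_hi: float = 0.9
    p_lo: float = 0.02
    bit_noise: float = 0.05
    singleton_fraction: float = 0.1
    seed: int = 7

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ParameterError("m and n must be >= 1")
        if not (1 <= self.G <= self.m and 1 <= self.H <= self.n):
            raise ParameterError("need 1 <= G <= m and 1 <= H <= n")
        if not 0.0 <= self.p_lo < self.p_hi <= 1.0:
            raise ParameterError("need 0 <= p_lo < p_hi <= 1")
        if not 0.0 <= self.bit_noise < 0.5:
            raise ParameterError("bit_noise must be in [0, 0.5)")
        if not 0.0 <= self.singleton_fraction <= 1.0:
            raise ParameterError("singleton_fraction must be in [0, 1]")
        if len(self.drug_features) != 3 or len(self.disease_features) != 2:
            raise ParameterError("expected 3 drug views and 2 disease views")


@dataclass
class SyntheticDataset:
    drug_profiles: list[FeatureProfile]
    disease_profiles: list[FeatureProfile]
    assoc: AssociationMatrix
    drug_groups: np.ndarray
    disease_groups: np.ndarray
    compatibility: np.ndarray  # (G, H) binary
    affinity: np.ndarray  # (m, n) cell-wise association probability

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for p in self.drug_profiles + self.disease_profiles:
            write_profile(outdir / f"{p.view_name}.csv", p)
        write_association_matrix(outdir / "associations.csv", self.assoc)
        np.savetxt(outdir / "affinity.csv", self.affinity, delimiter=",", fmt="%.6g")
        np.savetxt(outdir / "drug_groups.csv", self.drug_groups, delimiter=",", fmt="%d")
        np.savetxt(outdir / "disease_groups.csv", self.disease_groups, delimiter=",", fmt="%d")


def _noisy_profiles(
    rng: np.random.Generator,
    groups: np.ndarray,
    n_groups: int,
    n_features: int,
    eps: float,
) -> np.ndarray:
    prototypes = rng.integers(0, 2, size=(n_groups, n_features))
    base = prototypes[groups]
    flips = rng.random(base.shape) < eps
    return np.where(flips, 1 - base, base).astype(np.int8)


def generate(cfg: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate the five profiles, Y, and the ground truth; seed-deterministic."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    drug_ids = EntityIndex.from_ids([f"dr{i+1:03d}" for i in range(cfg.m)])
    disease_ids = EntityIndex.from_ids([f"di{j+1:03d}" for j in range(cfg.n)])
    drug_groups = np.arange(cfg.m) % cfg.G
    disease_groups = np.arange(cfg.n) % cfg.H

    drug_profiles = [
        FeatureProfile(
            entities=drug_ids,
            feature_ids=tuple(f"{view[:2]}f{k}" for k in range(nf)),
            values=_noisy_profiles(rng, drug_groups, cfg.G, nf, cfg.bit_noise),
            view_name=view,
        )
        for view, nf in zip(DRUG_VIEWS, cfg.drug_features)
    ]
    disease_profiles = [
        FeatureProfile(
            entities=disease_ids,
            feature_ids=tuple(f"{view[:2]}f{k}" for k in range(nf)),
            values=_noisy_profiles(rng, disease_groups, cfg.H, nf, cfg.bit_noise),
            view_name=view,
        )
        for view, nf in zip(DISEASE_VIEWS, cfg.disease_features)
    ]

    compatibility = rng.integers(0, 2, size=(cfg.G, cfg.H))
    affinity = np.where(
        compatibility[drug_groups][:, disease_groups] == 1, cfg.p_hi, cfg.p_lo
    )
    Y = (rng.random((cfg.m, cfg.n)) < affinity).astype(np.int8)

    n_singletons = int(round(cfg.singleton_fraction * cfg.m))
    if n_singletons > 0:
        chosen = rng.choice(cfg.m, size=n_singletons, replace=False)
        for d in chosen:
            j = int(np.argmax(affinity[d]))  # highest affinity, ties by index
            Y[d] = 0
            Y[d, j] = 1

    assoc = AssociationMatrix(drugs=drug_ids, diseases=disease_ids, Y=Y)
    return SyntheticDataset(
        drug_profiles=drug_profiles,
        disease_profiles=disease_profiles,
        assoc=assoc,
        drug_groups=drug_groups,
        disease_groups=disease_groups,
        compatibility=compatibility,
        affinity=affinity,
    )


def permute_labels(assoc: AssociationMatrix, seed: int) -> AssociationMatrix:
    """Uniformly shuffle Y's entries over all m*n cells (negative control).

    Preserves the total number of ones; deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    flat = assoc.Y.ravel().copy()
    rng.shuffle(flat)
    return AssociationMatrix(
        drugs=assoc.drugs,
        diseases=assoc.diseases,
        Y=flat.reshape(assoc.Y.shape),
    )
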