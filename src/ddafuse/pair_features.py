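"""Assembly of the merged pair-feature matrix F.

Every (drug, disease) pair becomes one row: the association label,
followed by the drug's row of the fused drug similarity (UDRS, m
columns) and the disease's row of the fused disease similarity (UDIS, n
columns). With the two identifier columns the table has m*n rows and
m + n + 3 columns; rows are enumerated drug-major (all diseases for the
first drug, then the second drug, ...). The identifier columns are
carried as metadata only — the classifier consumes the m + n feature
columns and the label, never the IDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import AlignmentError, AssociationMatrix, SimilarityMatrix, ValidationError

__all__ = ["PairFeatureTable", "build_pair_table"]

PROV_OBSERVED = "observed"
PROV_SYNTHETIC = "synthetic"


@dataclass
class PairFeatureTable:
    """One row per (drug, disease) pair: IDs, label, m+n similarity features.

    ``provenance`` distinguishes observed pairs from synthetic minority
    rows appended by SMOTE; synthetic rows must never leak into a test
    fold.
    """

    drug_ids: np.ndarray      # (rows,) str
    disease_ids: np.ndarray   # (rows,) str
    labels: np.ndarray        # (rows,) int {0,1}
    features: np.ndarray      # (rows, m+n) float
    provenance: np.ndarray    # (rows,) str, "observed" | "synthetic"
    feature_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        r = len(self.labels)
        if not (
            len(self.drug_ids) == len(self.disease_ids) == len(self.provenance) == r
            and self.features.shape[0] == r
        ):
            raise ValidationError("pair table columns disagree on row count")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("pair table labels must be binary")
        if not self.feature_names:
            self.feature_names = tuple(f"f{i}" for i in range(self.features.shape[1]))

    @property
    def n_rows(self) -> int:
        return len(self.labels)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def observed_mask(self) -> np.ndarray:
        return self.provenance == PROV_OBSERVED

    def subset(self, indices: np.ndarray) -> "PairFeatureTable":
        indices = np.asarray(indices)
        return PairFeatureTable(
            drug_ids=self.drug_ids[indices],
            disease_ids=self.disease_ids[indices],
            labels=self.labels[indices],
            features=self.features[indices],
            provenance=self.provenance[indices],
            feature_names=self.feature_names,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(self.feature_names))
        df.insert(0, "interaction", self.labels)
        df.insert(0, "disease", self.disease_ids)
        df.insert(0, "drug", self.drug_ids)
        df["provenance"] = self.provenance
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def build_pair_table(
    udrs: SimilarityMatrix,
    udis: SimilarityMatrix,
    assoc: AssociationMatrix,
) -> PairFeatureTable:
    """Join UDRS, UDIS and the association labels into the F table.

    Row (i, j) carries label Y(i, j) and features
    [UDRS(i, :), UDIS(j, :)]; rows run drug-major. Deterministic.
    """
    if udrs.entities != assoc.drugs:
        raise AlignmentError("UDRS entities do not match the association drugs")
    if udis.entities != assoc.diseases:
        raise AlignmentError("UDIS entities do not match the association diseases")
    m, n = assoc.Y.shape
    features = np.hstack(
        [np.repeat(udrs.S, n, axis=0), np.tile(udis.S, (m, 1))]
    )
    names = tuple(f"dr_{d}" for d in assoc.drugs.ids) + tuple(
        f"di_{d}" for d in assoc.diseases.ids
    )
    return PairFeatureTable(
        drug_ids=np.repeat(np.array(assoc.drugs.ids, dtype=object), n),
        disease_ids=np.tile(np.array(assoc.diseases.ids, dtype=object), m),
        labels=assoc.Y.ravel().astype(np.int8),
        features=features,
        provenance=np.full(m * n, PROV_OBSERVED, dtype=object),
        feature_names=names,
    )
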