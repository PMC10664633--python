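# ddafuse

Drug–disease association prediction by multi-view similarity network
fusion and a deep binary classifier.

## The problem

Drug repurposing asks whether an already-approved drug can treat a
disease it was not developed for. A data-driven way to answer it is to
treat the known drug–disease associations as a binary matrix
`Y ∈ {0,1}^{m×n}` (m drugs, n diseases) and to predict the unknown
entries from how similar each drug/disease is to the ones with known
associations. No single data source describes a drug well, so `ddafuse`
integrates several: three drug-side binary feature profiles (chemical
substructures, side effects, target proteins) and two disease-side
profiles (phenotype terms, target proteins).

## The method

1. **Cosine similarity per view.** Each view's binary profiles give a
   similarity matrix with entries `cos(x, y) = x·y / (‖x‖‖y‖)` — well
   suited to long sparse fingerprints, since shared zeros do not count.
2. **Similarity network fusion (SNF).** The three drug matrices are
   fused into one unified drug similarity `UDRS` and the two disease
   matrices into `UDIS` by iterative cross-diffusion: each view's
   row-normalized *status* matrix `P_v` is propagated through the other
   views' K-nearest-neighbour *local* kernels `S_v`,
   `P_v ← S_v · mean_{u≠v}(P_u) · S_vᵀ`, for `T` iterations, then
   averaged.
3. **Pair features.** Every (drug i, disease j) pair becomes one row of
   the merged matrix `F`: label `Y(i,j)` plus the feature vector
   `[UDRS(i,·), UDIS(j,·)]` — m·n rows, m+n+3 columns counting the two
   ID columns and the label.
4. **Class balancing.** The minority class is oversampled with SMOTE
   (interpolation between minority nearest neighbours) to a balance
   rate — minority/majority count ratio — of 0.9, inside each training
   fold only.
5. **Deep classifier.** A fully-connected network with 5 hidden layers
   of 300 rectified units, dropout 0.3, a sigmoid output and binary
   cross-entropy loss, trained with Nadam at batch size 64.
6. **Evaluation.** Fivefold cross-validation (optionally repeated with
   reshuffled folds), accuracy/precision/recall/F1 at threshold 0.5,
   ROC and PR areas, plus a new-drug experiment: for every drug with
   exactly one known association, withhold it and check whether the
   classifier ranks that disease first among all candidates.

A seeded synthetic generator with planted group structure (drug groups
× disease groups with a latent compatibility table) stands in for
curated association benchmarks, so the whole pipeline runs and is
tested entirely offline.

## Worked example

```python
import ddafuse as d
from ddafuse.pipeline import fuse_views

data = d.generate(d.SyntheticConfig(m=30, n=20, G=3, H=3, seed=7))
udrs = fuse_views(data.drug_profiles, d.SNFConfig(K=8, T=20))
udis = fuse_views(data.disease_profiles, d.SNFConfig(K=8, T=20))
table = d.build_pair_table(udrs, udis, data.assoc)
print(f"pair table: {table.n_rows} rows, {table.n_features} features, "
      f"{int(table.labels.sum())} known associations")

net = d.NetworkConfig(epochs=30, seed=0)
report = d.cross_validate(table, net, d.BalanceConfig(seed=0), k=5, rounds=1, seed=0)
for name, stats in report.aggregate().items():
    print(f"{name:>9}: {stats['mean']:.3f} +/- {stats['std']:.3f}")
```

prints

```
pair table: 600 rows, 50 features, 169 known associations
 accuracy: 0.933 +/- 0.005
precision: 0.866 +/- 0.027
   recall: 0.903 +/- 0.056
       f1: 0.883 +/- 0.021
    auroc: 0.950 +/- 0.026
     aupr: 0.890 +/- 0.042
```

The planted compatibility structure is recoverable from the fused
similarities: held-out pairs are ranked far above chance (AUROC 0.95),
while permuting the labels before training (`d.permute_labels`) drops
the AUROC to ≈ 0.5 — the leakage control.

The same pipeline runs from the shell against CSV inputs or a synthetic
block in a YAML config:

```bash
ddafuse generate --out data/ --m 30 --n 20 --groups 3 --seed 7
ddafuse run-all --config config.yaml
```

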