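"""Cross-validated CNN classification of pathway images.

Runs stratified k-fold cross-validation in fold-safe mode: within each fold
the PCA embedding is refitted on the training samples only, so no test
information (values or labels) leaks into the images the model is judged on.
Reports per-fold and pooled accuracy, precision, recall, F1 and ROC AUC.
"""

import numpy as np

from pathimage.classifier import CnnConfig, cross_validate
from pathimage.data_io import assign_survival_labels, harmonize
from pathimage.synthetic import PlantedEffect, SyntheticConfig, generate_multiomics

config = SyntheticConfig(
    n_samples_per_class=(40, 60),
    n_pathways=40,
    planted=[PlantedEffect(p, o, 2.5) for p in (5, 20) for o in range(3)],
    seed=3,
)
matrices, pathways, clinical, _ = generate_multiomics(config)
dataset = harmonize(matrices, assign_survival_labels(clinical))

cnn = CnnConfig(epochs=40, seed=0)
result = cross_validate(dataset, pathways, cnn, n_pcs=2, k=3,
                        mode="fold-safe", seed=1)

for i, rep in enumerate(result.fold_reports):
    print(f"fold {i}: acc={rep.accuracy:.3f} auc={rep.auc_roc:.3f}")
p = result.pooled
print(f"pooled: acc={p.accuracy:.3f} precision={p.precision:.3f} "
      f"recall={p.recall:.3f} f1={p.f1:.3f} auc={p.auc_roc:.3f}")
print(f"confusion (positive = non-LTS): TP={p.confusion.tp} TN={p.confusion.tn} "
      f"FP={p.confusion.fp} FN={p.confusion.fn}")

# Sanity check: destroying the labels should push AUC back to chance.
rng = np.random.default_rng(0)
perm = {s: dataset.labels.labels[t] for s, t in
        zip(dataset.sample_ids, rng.permutation(dataset.sample_ids))}
shuffled = harmonize(dataset.omics, type(dataset.labels)(perm, dataset.labels.threshold_years))
null = cross_validate(shuffled, pathways, cnn, n_pcs=2, k=3, mode="fold-safe", seed=1)
print(f"label-permuted pooled AUC: {null.pooled.auc_roc:.3f} (expect ~0.5)")
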