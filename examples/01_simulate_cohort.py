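"""Simulate a small multi-omics survival cohort and inspect its pieces.

The generator plants known class-discriminative pathway effects and known
survival-associated genes, so every downstream capability can be checked
against ground truth.
"""

from pathimage.data_io import assign_survival_labels
from pathimage.synthetic import PlantedEffect, SyntheticConfig, generate_multiomics

config = SyntheticConfig(
    n_samples_per_class=(20, 30),        # (LTS, non-LTS)
    n_pathways=30,
    genes_per_pathway=(8, 15),
    # pathway 5 is shifted by 2 noise-SDs in every omics layer for non-LTS
    planted=[PlantedEffect(pathway_index=5, omics_index=o, delta=2.0) for o in range(3)],
    survival_betas={0: 0.7},             # first gene drives hazard
    seed=7,
)
matrices, pathways, clinical, truth = generate_multiomics(config)

for om in matrices:
    print(f"{om.omics_name}: {om.values.shape[0]} samples x {om.values.shape[1]} genes")
sizes = [len(genes) for _, genes in pathways.pathways]
print(f"pathways: {len(pathways)} (sizes {min(sizes)}-{max(sizes)} genes)")

labels = assign_survival_labels(clinical, threshold_years=2.0)
print("label counts:", labels.counts())
print("planted effects:",
      [(p.pathway_index, p.omics_index, p.delta) for p in truth.planted])
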