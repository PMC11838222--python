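"""Cox proportional-hazards gene selection within pathways.

For each pathway of interest, genes are tested for survival association
with a Breslow-ties Cox model fitted by Newton's method; Wald tests give
hazard ratios (e^beta), 95% CIs and p-values, and genes with p < 0.01 are
selected.  The example also shows recovery of a known coefficient on clean
simulated survival data.
"""

import numpy as np

from pathimage.data_io import assign_survival_labels, harmonize
from pathimage.survival import fit_coxph, run_pathway_survival, wald_test
from pathimage.synthetic import SyntheticConfig, generate_multiomics, generate_survival_data

# --- calibration on clean exponential proportional-hazards data ------------
clin, x = generate_survival_data(n=2000, betas=np.array([0.7, -0.4]),
                                 censoring_rate=0.2, seed=4)
fit = fit_coxph(clin.time_years, clin.event, x, ["gene_a", "gene_b"],
                standardize=False)
for rec in wald_test(fit, alpha=0.01):
    print(f"{rec.gene}: beta={rec.beta:+.3f} HR={rec.hr:.3f} "
          f"[{rec.ci_low:.3f}, {rec.ci_high:.3f}] p={rec.p_value:.2e}")
print("true betas were +0.7 and -0.4\n")

# --- pathway-level screening on a synthetic cohort --------------------------
config = SyntheticConfig(
    n_samples_per_class=(40, 60),
    n_pathways=20,
    survival_betas={0: 0.8, 1: -0.8},   # first two genes drive hazard
    censoring_rate=0.1,
    seed=9,
)
matrices, pathways, clinical, truth = generate_multiomics(config)
dataset = harmonize(matrices, assign_survival_labels(clinical))

per_pathway, table = run_pathway_survival(
    dataset, pathways.pathway_ids[:3], pathways, clinical,
    omics_for_cox="EXP", alpha=0.01,
)
print(f"significant genes (p < 0.01) in first 3 pathways: {len(table)}")
print(table.head().to_string(index=False))
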