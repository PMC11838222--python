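# pathimage

Pathway-image multi-omics survival classification: integrate several omics
layers into per-sample "pathway-PC images", classify long-term vs
non-long-term cancer survivors with a small CNN, explain the classifier at
the pathway level with Gradient-SHAP, and screen the implicated pathways
for survival-associated genes with Cox proportional-hazards models.

## The science

Cohorts of cancer patients split into long-term survivors (LTS, alive
beyond 2 years) and non-long-term survivors (non-LTS, observed death at or
before 2 years; short censored follow-ups are excluded as unknowable).
Individual genes are noisy and high-dimensional; pathways are the natural
unit of interpretation. The pipeline therefore:

1. **Embeds** each (survival class, omics layer, pathway) triple with its
   own PCA — with 2 classes, 3 layers and 146 pathways that is 876 small
   models — and arranges each sample's top-PC scores as a 2-D grid: one
   row per pathway, one column per (omics layer, principal component).
   A 2-PC image over 3 layers is 146 x 6.
2. **Classifies** the images with a small CNN (NumPy, explicit
   backpropagation) under stratified k-fold cross-validation. The default
   *fold-safe* mode refits the PCA bank inside each training fold and
   embeds every sample under both classes' models, so no test label or
   value leaks into the images; the original class-specific procedure
   (*paper-faithful* mode) is also available, with its leakage documented.
3. **Explains** predictions with Gradient-SHAP (Monte-Carlo path-integral
   attributions against noisy training-image baselines), aggregates
   |attributions| per class, reports each class's top-10
   (pathway, omics, PC) cells, and compares the classes' pathway sets
   (common vs unique).
4. **Screens** the implicated pathways for genes whose expression
   associates with survival: Cox proportional hazards (Breslow ties,
   Newton's method), Wald tests, hazard ratios e^beta with 95% CIs, and a
   p < 0.01 selection threshold.

A synthetic-cohort generator with planted discriminative pathways and
known hazard coefficients makes every stage verifiable against ground
truth. See `docs/methods.md` for the full methods note.

## Worked example

Simulate a cohort with two planted pathways (shifted by 2 noise-SDs in
every omics layer for the non-LTS class), run the full pipeline, and
recover them:

```python
from pathimage.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    n_samples_per_class=(60, 90),          # LTS, non-LTS
    n_pathways=146,
    planted=[(p, o, 2.0) for p in (10, 80) for o in range(3)],
    seed=0,
)
result = run_pipeline(cfg, outdir="run_out")
print(f"pooled CV AUC: {result.cv.pooled.auc_roc:.3f}")
print(f"pooled accuracy: {result.cv.pooled.accuracy:.3f}  F1: {result.cv.pooled.f1:.3f}")
for c, paths in result.report.per_class_pathways.items():
    print(f"top pathways ({c}):", paths[:5])
print("common:", result.report.common)
print(f"significant survival genes (p<0.01): {len(result.gene_table)}")
print(result.gene_table.head().to_string())
```

Output (about 11 minutes on one CPU core; bit-identical on reruns):

```
pooled CV AUC: 0.940
pooled accuracy: 0.840  F1: 0.878
top pathways (LTS): ['PW0010', 'PW0080']
top pathways (non-LTS): ['PW0080', 'PW0010']
common: ['PW0010', 'PW0080']
significant survival genes (p<0.01): 4
  pathway_id    gene      beta        se      wald         p        hr    ci_low   ci_high
0     PW0010  G00231  0.474827  0.131729  3.604582  0.000313  1.607737  1.241901  2.081339
1     PW0010  G00212  0.483205  0.150714  3.206112  0.001345  1.621263  1.206606  2.178418
2     PW0010  G00214  0.351380  0.123262  2.850682  0.004363  1.421027  1.116045  1.809351
3     PW0010  G00223  0.398943  0.145615  2.739719  0.006149  1.490249  1.120241  1.982469
```

Both planted pathways are recovered as the top attributed pathways of
*both* classes (they are the classes' common set), and the gene screen
pulls out individual genes of one of them with hazard ratios around 1.4–1.6.

## Command line

Every stage is also a subcommand of the `pathimage` CLI; all take a YAML
`RunConfig`, a master seed and an output directory:

```bash
pathimage simulate  --config cfg.yaml --seed 5 --out sim/     # write TSV/GMT inputs
pathimage prepare   --config cfg.yaml --out prep/             # harmonize + labels
pathimage embed     --config cfg.yaml --out emb/              # pathway-PC images
pathimage cv        --config cfg.yaml --out cv/               # k-fold CV metrics
pathimage explain   --config cfg.yaml --out shap/             # attributions + sets
pathimage cox       --config cfg.yaml --out cox/              # gene survival tables
pathimage run-all   --config cfg.yaml --out run/              # everything
pathimage sweep-pcs --config cfg.yaml --pcs 1,2,3,4 --out pc/ # PC-count sweep
```

Real data enters through `source: files` in the config, pointing at one
TSV/CSV matrix per omics layer, a GMT pathway file (plus optional
exclusion list) and a clinical table; `pathimage simulate` writes files in
exactly these formats.

## Examples

`examples/` contains one short narrative script per capability:

| script | shows |
| --- | --- |
| `01_simulate_cohort.py` | synthetic multi-omics cohorts with ground truth |
| `02_build_pathway_images.py` | PCA banks and image assembly, both modes |
| `03_train_and_evaluate.py` | fold-safe CV metrics + label-permutation control |
| `04_explain_predictions.py` | Gradient-SHAP top-10 and common/unique sets |
| `05_survival_genes.py` | Cox calibration and per-pathway gene screening |
| `06_full_pipeline.py` | one-config end-to-end run with artifacts |

## Reproduction

Runs are deterministic: one master seed fans out to per-stage seeds, and
rerunning any stage with the same config and seed is bit-identical.
Artifact directories record the config and its hash.

```bash
# full test suite (unit + acceptance)
python -m pytest -q tests/

# acceptance run: recompute headline quantities, write JSON
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script reruns the structural checks, the PCA and
Gradient-SHAP oracles, Cox calibration (including a 1000-replicate type-I
error simulation), the end-to-end planted-signal pipeline with a
label-permutation control, and a bit-identity determinism check.
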