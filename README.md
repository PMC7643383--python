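# ecgcn

Effective-connectivity estimation and population-graph GCN classification
for resting-state fMRI cohorts.

`ecgcn` implements a complete diagnostic pipeline for two-group rs-fMRI
studies (major depressive disorder vs healthy controls): it estimates
directed *effective connectivity* (EC) from ROI time series by group-sparse
multi-subject regression, screens connections with LASSO, classifies
subjects with a Chebyshev spectral graph convolutional network (GCN) over a
subject-similarity *population graph* that fuses imaging and phenotypic
information, and interprets the trained classifier with gradient
sensitivity analysis to report the discriminant connections.  A seeded
synthetic-cohort simulator makes every stage testable end to end without
any clinical data.

## The model in brief

**Effective connectivity.**  For each destination ROI `r`, every subject's
signal `x_n^r` is regressed on the remaining ROIs, jointly across subjects
with an l2,1 (group-LASSO) penalty that groups one directed connection
across the cohort:

    min  1/2 Σ_n ‖x_n^r − X_n^{\r} w_n^{\r}‖²  +  α Σ_j ‖(w_{1,j}, …, w_{N,j})‖₂

so all subjects share one sparse connection skeleton while keeping
individual weights.  Solved by monotone FISTA with group soft-thresholding.

**Population graph.**  Subjects are vertices; edges combine a Gaussian
kernel on the selected connectivity features with phenotype agreement:
`W_ij = exp(−‖f_i − f_j‖²/(2σ²)) · Σ_h δ_h(p_i, p_j)` (gender match, age
within γ years).

**Classifier.**  A spectral GCN with K-th order Chebyshev filters of the
rescaled normalised Laplacian, trained transductively (all subjects'
features join the convolutions; only training labels enter the loss), with
hand-written reverse-mode gradients.

**Interpretation.**  Per-subject relevance of feature `d` is
`|∂ p_MDD / ∂ f_{n,d}|`; subject- and fold-averaged scores above
`μ + 1.5 σ` are reported as discriminant source→destination connections.

## Worked example

```python
from ecgcn import PipelineConfig, run_pipeline, simulate_cohort

# synthetic cohort at the study scale: 29 patients, 44 controls,
# T=170 time points; 20 ROIs with a known sparse reciprocal skeleton
# and 8 directed edges whose weights are shifted in the patient group
manifest, series, truth = simulate_cohort(
    n_mdd=29, n_hc=44, R=20, T=170, density=0.1, effect_size=2.0, seed=0
)
report = run_pipeline(PipelineConfig(seed=0), manifest, series)

m = report["metrics"]
print(f"ACC {m['acc']['mean']:.3f} +- {m['acc']['sd']:.3f}")
print(f"AUC {m['auc']['mean']:.3f} +- {m['auc']['sd']:.3f}")
print("features kept (union over folds):", report["n_selected_union"])
top = report["interpretation"]["selected"][0]
print(f"top discriminant connection: ROI {top['source']} -> ROI {top['destination']}")
```

prints

```
ACC 1.000 +- 0.000
AUC 1.000 +- 0.000
features kept (union over folds): 39
top discriminant connection: ROI 11 -> ROI 14
```

With this strong planted effect the stratified 10-fold cross-validation is
error-free, the LASSO screen keeps 39 of the 400 directed-connection
features across folds, and the one connection whose fold-averaged relevance
exceeds `μ + 1.5σ` — ROI 11 → ROI 14 — is a true planted effect pair
(14 → 11 in the ground truth; an instantaneous model cannot orient edges,
so recovering the pair is the attainable target).  At `effect_size=0` the
same pipeline performs at chance (AUC ≈ 0.5).

The same experiment from the shell:

```bash
ecgcn simulate --out cohort/ --rois 20 --effect-size 2.0 --seed 0
ecgcn run-all cohort/manifest.csv --out report.json --seed 0
```

Subcommands `preprocess`, `connectivity` and `graph` expose the individual
stages; `ecgcn run-all --config config.yaml ...` drives everything from a
YAML file.

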