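# Methods

This note documents the models, estimators, numerical choices and known
limitations of the `ecgcn` pipeline.

## Problem setting

The pipeline classifies subjects of a resting-state fMRI cohort into major
depressive disorder (MDD) patients versus healthy controls (HC) from
parcellated ROI time series, and reports which directed inter-regional
connections drive the classification.  It operates downstream of voxel-level
preprocessing: its input is one `T x R` matrix of mean ROI signals per
subject (nominally `T = 170` volumes at TR = 2 s over `R = 114` cortical
parcels of a 17-network functional atlas), plus a manifest of diagnostic
labels and phenotypes (age, gender).

## ROI-level preprocessing

`signals.preprocess_series` applies, in order: (1) OLS residualisation
against user-supplied confound regressors plus an intercept; (2) zero-phase
band-pass filtering, 4th-order Butterworth run forward-backward
(`scipy.signal.sosfiltfilt`) with default band 0.01-0.1 Hz — zero phase
matters because phase shifts would distort the contemporaneous regressions
downstream; (3) per-column standardisation to mean 0 and unit sample SD.
The order (confounds before filter before scaling) follows standard rs-fMRI
practice.  Global-signal regression and motion scrubbing are deliberately
not implemented; head-motion exclusion is left to cohort curation.

## Group-sparse effective connectivity

Each ROI's signal is modelled as a linear combination of all other ROIs at
the same time points (a structural-equation-style instantaneous model).
For destination ROI `r` the solver minimises, jointly over subjects
`n = 1..N`,

    0.5 * sum_n ||x_n^r - X_n^{\r} w_n^{\r}||^2  +  alpha * sum_j ||(w_{1,j}, ..., w_{N,j})||_2

where the l2,1 penalty groups one directed connection `j -> r` across all
subjects.  A group is pruned for everybody or kept for everybody — a shared
cohort skeleton with subject-specific weights.

Numerics: proximal gradient (FISTA) with group soft-thresholding; step
`1/L` with `L` the largest per-subject Gram eigenvalue (the smooth term is
block-diagonal across subjects); relative objective-change tolerance 1e-6,
cap 1000 iterations.  Plain FISTA is non-monotone, so a step that would
increase the objective is replaced by an ISTA step from the previous
iterate and the momentum restarts, giving a provably non-increasing
trajectory.  The null threshold `alpha_max(r) = max_j sqrt(sum_n (x_n^j .
x_n^r)^2)` follows from the subgradient condition at zero and is verified
against the solver in tests.

ROI columns are z-scored per subject before solving (configurable), making
one alpha comparable across destination ROIs.  The pipeline default is
`alpha = 0.1 * median_r alpha_max(r)`; the regularisation level of the
original analysis is not recoverable, so this scale-free default was fixed
once and is exposed in the config.

Pearson FC (correlation matrices) and pairwise Granger causality
(`ln(RSS_restricted / RSS_full)` at lag order 1, with intercepts, clipped
at 0) are provided as alternative feature types.  The Granger statistic is
used as a connectivity strength, not as a test; no p-values are attached.

## Feature vectorisation and LASSO screening

Directed EC matrices are flattened destination-major to length `R**2`
vectors keeping the structural diagonal zeros, so feature index <->
connection remains a fixed bijection (`R = 114` gives 12,996 entries); FC
uses the strict upper triangle row-major (6,441 entries).

Within every cross-validation fold an l1-penalised least-squares regression
of the 0/1 label on the column-standardised training features screens the
features; nonzero coefficients are kept.  `lambda` is chosen by internal
5-fold cross-validation on the training subjects (scikit-learn `LassoCV`,
30-point alpha path, loose coordinate-descent tolerance — the surviving
feature set stabilises long before full convergence).  When the CV choice
degenerates to the empty model (as it does on null cohorts with no class
signal), the screen steps down the alpha path to the largest value keeping
at least one feature, so downstream stages always have an input.
Standardisation means/SDs are frozen from the training fold; test subjects
never influence selection or scaling.

## Population graph and spectral operators

Subjects are vertices; the edge weight combines imaging similarity and
phenotype agreement:

    W_ij = exp(-||f_i - f_j||^2 / (2 sigma^2)) * sum_h delta_h(p_i, p_j)

with `delta` an exact-match indicator for gender and the indicator of
`|age_i - age_j| < gamma` for age (defaults `sigma = 1`, `gamma = 2`; an
optional categorical education measure is supported).  Self-weights are
zeroed.  The graph is built transductively from the fold's selected
features of *all* subjects — test features (never labels) participate, by
design.

Convolution uses the symmetric normalised Laplacian
`L = I - D^{-1/2} W D^{-1/2}` (spectrum in `[0, 2]`; isolated vertices get
identity rows rather than a division by zero, making them fixed points of
the filter), rescaled to `(2/lambda_max) L - I` with spectrum in `[-1, 1]`
for the Chebyshev basis.

## Chebyshev spectral GCN

Each layer filters the `N x F` vertex-feature matrix with a K-th order
Chebyshev polynomial of the rescaled Laplacian (recurrence `T_0 = I`,
`T_1 = L~`, `T_k = 2 L~ T_{k-1} - T_{k-2}`), one `(F_in x F_out)`
coefficient matrix per polynomial order, plus a bias; ReLU between layers
and a row-wise softmax at the output.  Defaults: one hidden layer of 16
units (the original width is unreported; small N argues for small
capacity), `K = 3`, Glorot-uniform initialisation, zero biases.

Training is transductive and full-batch: every subject participates in the
convolutions, the mean cross-entropy is evaluated on the labelled training
vertices only, plus `weight_decay * sum(theta**2)` on filter weights (not
biases).  Defaults: vanilla gradient descent at learning rate 0.05,
inverted dropout 0.3 on the input and hidden activations (never on the
output, never at inference), weight decay 5e-4, 200 epochs.  Adam is
available by config.  All gradients are hand-written reverse-mode
differentiation of this forward graph; they are validated against central
finite differences and, for the degenerate `K = 0` single-layer case,
against the closed-form softmax-regression gradient.  Because the cohort
is small, the `K+1` dense `T_k` matrices are materialised once and shared
by training, inference and sensitivity analysis.  Every random draw
(initialisation, dropout, folds) derives from explicit integer seeds, so
trained parameters are bit-reproducible.

## Sensitivity analysis

The relevance of feature `d` for subject `n` is the absolute partial
derivative of the model's MDD softmax probability for that subject with
respect to that subject's own input feature (all other subjects held
fixed) — an l1-norm gradient saliency.  Scores are averaged over subjects;
per-fold score vectors are scattered back onto the full connectivity index
space and averaged over the folds.  Features whose fold-averaged mean score
strictly exceeds `mu + 1.5 sigma` — mean and *population* SD of the mean
scores (no Bessel correction is implied by the selection rule; configurable)
— are reported as discriminant connections, sorted descending and mapped
back to (source ROI, destination ROI) pairs, with atlas names when a label
table is given.

## Evaluation

Stratified 10-fold cross-validation (per-fold class counts within one
subject of proportional; seeded).  MDD is the positive class.  ACC, SEN and
SPE follow the confusion-matrix definitions; AUC is the normalised
Mann-Whitney U on the MDD-probability scores with averaged ties.  Paired
classifier comparison uses McNemar's test: continuity-corrected chi-square
`(|b-c|-1)^2/(b+c)` for `b+c >= 25` discordant pairs, exact two-sided
binomial otherwise.  Demographic utilities: Pearson chi-square without
continuity correction, and two-sample t from summary statistics in both
pooled and Welch variants (cohort age tables conventionally use pooled,
heavily heteroscedastic clinical scores Welch).  The classifier sensitivity
interval is the normal approximation `mean +- z * SD / sqrt(n)` over folds.
A formal diagnostic-power computation is not implemented: the published
procedure delegates to an external package whose algorithm is not specified
precisely enough to reproduce; the CI/marginal-error arithmetic it builds
on is the tested surface.

## Synthetic cohorts

`synthetic.simulate_cohort` generates the study conditions end to end:
29 MDD + 44 HC subjects, `T = 170` time points, ages uniform on 20-60,
gender Bernoulli(0.6 female).  Signals come from the instantaneous linear
model `x_t = (I - A_n^T)^{-1} eps_t`, `eps_t ~ N(0, noise_sd^2 I)` — the
same contemporaneous structure the EC estimator fits.  A `VAR(1)` mode with
the same coefficients exists for exercising the lag-based Granger
estimator.

The shared skeleton is drawn as *reciprocal* pairs: undirected pairs are
sampled at the requested density and both directions receive a weight
(shared sign, independent magnitudes uniform on 0.2-0.5).  This choice is
deliberate: cortico-cortical projections are predominantly bidirectional,
and an instantaneous Gaussian model carries no information about edge
orientation (its precision matrix is symmetric), so a benchmark skeleton
with generically oriented edges would conflate orientation error — which no
contemporaneous estimator can avoid — with genuine support-recovery error.
With reciprocal skeletons, recovery quality measures what the estimator can
control: pruning of indirect (co-parent) partial correlations.  Subject
weights add N(0, 0.1) jitter on the support; MDD subjects additionally have
a random 20% of skeleton edges shifted by `effect_size`.  Every mixing
matrix is rescaled to spectral radius at most 0.9, guaranteeing a valid
stationary model.

What the generator does *not* emulate: haemodynamic response convolution,
BOLD noise spectra (1/f, physiological), motion artifacts, site effects.
Passing tests therefore demonstrate correctness of the estimation and
classification machinery under the assumed model, not clinical performance
on real rs-fMRI.

## Problem sizes used in tests and the acceptance script

The full 114-ROI scale is exercised for arithmetic (vector lengths, index
maps).  Estimation and end-to-end benchmarks run at a reduced `R = 20` with
the full cohort size (29/44) and `T = 170`, the regime where the solver's
`T > R` assumptions hold comfortably and a complete cross-validated
pipeline run takes seconds.  Support-recovery F1 is reported as a mean over
three simulation seeds because the co-parent structure — hence precision —
depends on the skeleton draw.

## Known limitations

- Contemporaneous EC cannot orient edges; directionality in the estimates
  reflects asymmetric regression weights, not causal identification.
- The LASSO screen is marginal-least-squares based; strongly correlated
  connection features (ubiquitous under reciprocal coupling) make the
  selected index set unstable across folds, which is why interpretation
  aggregates over the fold union.
- With ~70 subjects the GCN is heavily regularised by construction; the
  defaults are sensible for this scale and not tuned per dataset.
- The null-cohort AUC sits slightly below 0.5 on some seeds: feature
  selection overfits fold-specific noise, a known behaviour of screening
  inside small-sample cross-validation, bounded here by the +-0.15 band
  around chance.
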