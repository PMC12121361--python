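# Methods

## The model

`synprop` predicts per-participant risks for four plasma biomarkers of
neurodegeneration — the amyloid ratio (reciprocal convention), GFAP, NfL
and pTau181 — from a panel of plasma protein measurements and a weighted
protein–protein interaction (PPI) network. The architecture is
deliberately shallow so that every parameter has a direct biological
reading.

**Graph propagation.** Let `X ∈ R^{d×n}` hold the preprocessed
expression of `d` target proteins across `n` participants (the
*independent effects*, each entry in (0, 1)), and let `W` be the
symmetric nonnegative PPI weight matrix with zero diagonal. With the
symmetric normalized Laplacian `L = I − D^{−1/2} W D^{−1/2}`
(`D_ii = Σ_k W_ik`; isolated nodes contribute identity rows), the
interaction-aware representation (*synergetic effects*) minimizes, per
participant column,

```
Σ_{i~j} W_ij (z_i − z_j)²  +  Σ_i φ_i (z_i − x_i)²
```

— a smoothness term over the graph plus a per-protein steadiness term.
The minimizer is the closed-form linear solve `Z = (Φ + L)^{−1} Φ X`,
`Φ = diag(φ)`, computed with one Cholesky factorization reused across
all participant columns. This single layer mixes information across all
hops at once; no layer stacking is needed, and propagation never mixes
information *across* participants, so prediction is leakage-free.

**Risk estimation.** Each biomarker `b` has a linear-logistic read-out
`P_b = σ(θ_bᵀ Z)` with no intercept. An optional demographic extension
adds standardized covariates to the logit, `σ(θ_bᵀ Z + β_bᵀ c)`;
covariates are never propagated through the graph.

**Training.** All tasks share `φ`; each task owns `θ_b`. The objective
is the summed mean binary cross-entropy plus an L2 complexity penalty
`δ(‖φ‖² + Σ_b ‖θ_b‖²)` (covariate weights included when enabled).
Gradients are analytic: `∇θ_b = (1/n) Z (P_b − Y_b) + 2δθ_b`, and for
`φ`, implicit differentiation of `(Φ + L) Z = Φ X` gives
`∂Z/∂φ_i = A^{−1} E_ii (X − Z)` with `A = Φ + L`, hence

```
∇φ_i = row_i(A^{−1} G) · row_i(X − Z) + 2δφ_i,
G = (1/n) Σ_b θ_b (P_b − Y_b)ᵀ.
```

The Cholesky factor from the forward solve is reused, so the φ-gradient
costs one extra triangular solve per epoch. Correctness is enforced by
tests against central finite differences (relative error ≤ 1e−5 over 20
seeded instances) rather than by any particular matrix layout.

## Numerical choices

- **φ positivity.** `(Φ + L)` is symmetric positive definite exactly
  when `φ > 0`; after every update `φ` is projected onto
  `[1e−6, ∞)`. The plain update rule is otherwise untouched.
- **Initialization.** `φ = 1`, `θ_b = 0` — this gives the analytically
  known starting loss `B·ln 2` (plus the φ-regularizer) for `B` tasks,
  which the tests assert. A seeded small-random θ start is available
  via `init_scale` for experiments where a symmetric start is degenerate.
- **Loss convention.** The implemented loss is the standard nonnegative
  binary cross-entropy `−(1/n)[Yᵀ log P + (1−Y)ᵀ log(1−P)]`; its
  gradient is exactly the `(1/n) Z (P − Y)` descent direction used above.
  Risks are clipped to `[1e−12, 1 − 1e−12]` before logs.
- **Optimizer.** Both plain full-batch gradient descent and ADAM are
  implemented; ADAM with step 0.001 is the default. The stopping rule is
  `max_epochs` (default 2000) or relative loss change below 1e−6.
- **δ.** Default 1e−3; results in the test suite are insensitive to an
  order of magnitude either way because correlation-based recovery
  checks are scale-free.
- **Solvers.** All `(Φ + L)` systems use one dense Cholesky
  factorization per epoch (d ≈ 30–113 makes this trivial and
  bit-stable). A fixed-point iteration
  `Z ← (Φ + I)^{−1}(ΦX + SZ)`, a contraction for any `φ > 0`, serves as
  an independent cross-check only.

## Surrounding pipeline

- **Preprocessing.** Proteins with more than 5% missing samples are
  removed (exactly 5% is retained — the exclusion is strict). Remaining
  gaps are imputed from the `k = 10` nearest samples, nearness being
  Euclidean distance over jointly observed proteins with lower sample
  index breaking ties; imputation never alters observed entries. Each
  protein row is then z-scored (sample sd, ddof = 1; constant rows map
  to 0.5) and passed through the logistic function so the model sees
  values in (0, 1). The kNN orientation (sample-space neighbors) and
  the ddof choice are our decisions where convention varies.
- **Target selection.** A Welch two-sample t-test per protein between
  biomarker-positive and -negative groups (two-sided,
  Welch–Satterthwaite df), unadjusted p-values thresholded at .05;
  proteins significant for *every* biomarker form the target set. The
  test function is pluggable — Welch is the documented default, run on
  the scaled matrix the model consumes. Empirical-Bayes moderated
  alternatives are intentionally out of scope.
- **Network construction.** STRING-style edges with combined score
  strictly above 0.4 are kept (scores serialized as 0–1000 integers are
  auto-divided); duplicates collapse to the maximum score; kept scores
  are z-scored over the kept set and logistic-mapped into (0, 1). With
  fewer than two distinct surviving scores all weights default to 0.5.
  Whether rescaling happens before or after thresholding is not fixed by
  convention; we rescale after. Density is reported both over connected
  (degree ≥ 1) nodes — the convention under which a 93-node, 234-edge
  network has density 5.47% and mean degree 5.03 — and over all nodes.
- **Labeling.** Positivity cutoffs come from a two-component normal
  mixture fitted by EM (deterministic tercile initialization, seeded
  jitter restarts on degeneracy) with the threshold at the equal
  weighted-density point between the component means, cross-checked
  against the closed-form quadratic root. Strictly above threshold is
  positive. The amyloid ratio is transformed `v → 1/v` upstream so
  higher always means riskier. Other component families (lognormal,
  gamma) are not implemented.
- **Evaluation.** AUROC (pairwise concordance), AUPRC
  (average-precision formulation, no linear interpolation — stated
  because implementations differ), accuracy and F1 at the 0.5 risk
  threshold (zero-denominator F1 is 0), and their mean as the overall
  metric. Cross-validation is repeated stratified k-fold with per-fold
  refits; folds balance the joint label pattern by round-robin dealing,
  so fold sizes differ by at most one. Stratification and the 0.5
  threshold are our choices where convention varies; an optional
  per-fold rescaling mode refits the z-score scaling on training
  columns only for use with raw inputs.
- **Explainability.** Protein importance is leave-one-protein-out
  ΔAUROC: the protein's row of `Z` is zeroed at prediction time (no
  refit, no re-propagation) and the drop in mean AUROC across
  biomarkers recorded; a "remove-node" mode that deletes the node and
  re-propagates is provided for sensitivity analysis. SHAP-style
  attributions are intentionally not implemented. "Major proteins" per
  biomarker are the intersection of the top-⌈10%·d⌉ by signed θ_b
  (positive values increase risk) and by importance, ties broken by
  protein-id order. Subset risk scores zero θ entries outside a chosen
  subset; because logits are linear in θ, disjoint subsets' logits add
  to the full-model logit.

## Synthetic data

The generator draws everything from the model's own generative chain:
a random weighted graph (uniform edges, or module-structured with a 5×
within-module preference, mirroring the modular organization of real
PPI maps), latent expression uniform in (0, 1) (logistic-of-normal as
an alternative), planted `φ` around 1.25 — the scale reported for
propagation intensities on real plasma panels — and planted `θ_b` with
unit scale, then `Z` by the closed-form solve and
`Y_b ~ Bernoulli(σ(θ_bᵀZ))`. Task logits are median-centered before
sampling so prevalence stays near 50%; the read-out has no intercept,
so this constant is a mild, deliberate mis-specification that
rank-based metrics are insensitive to. Defaults are d = 30, n = 2000,
graph density 0.055 (the density scale of real target-protein
networks); optional missingness punching and additive covariate effects
exercise the preprocessing and demographic paths.

What passing on this data shows: the estimator recovers the parameters
of a correctly specified model (held-out AUROC within 0.05 of the
true-logit oracle; Pearson r(θ̂, θ) ≥ 0.7 at d = 30, n = 2000) and the
pipeline is internally consistent. What it does not show: robustness to
assay batch effects, non-normal NPX distributions, label noise in
mixture-derived diagnoses, or misspecified networks — real cohorts
differ in all of these. `φ` is only weakly identified when estimation
weights are small; rank recovery of planted `φ` (Spearman ≥ 0.5) is
asserted only under strong signal, and this limitation is intrinsic,
not a defect of the optimizer.

## Problem sizes used in the test suite

Simulation-backed tests run at d = 8–30 proteins and n = 120–3000
participants, with 2–4 biomarker tasks; the density ablation uses three
edge fractions × three subsampled networks at n = 400. These sizes were
chosen so the full suite exercises every code path at desk scale while
each property remains statistically decisive.

## Known limitations

- The Welch test is a stand-in for moderated differential-expression
  statistics; DEP counts on small cohorts will differ from
  empirical-Bayes pipelines.
- The mixture cutoff assumes two normal components; heavy-tailed
  biomarker distributions may need a transformation first.
- Training is full-batch; the intended regime is panels of order 10²–10³
  proteins and cohorts of order 10³ participants, where a dense d × d
  factorization per epoch is cheap.
- No multiple-testing correction is applied in target selection (raw
  p < .05 by design); downstream interpretation should account for it.
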