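# synprop

PPI-aware risk prediction from plasma proteomics: a shallow, explainable
graph-propagation model plus the full surrounding pipeline
(preprocessing, differential-expression target selection, STRING-style
network construction, mixture-model positivity labeling, repeated
cross-validation, edge-density ablation, and parameter-level
explainability), together with a synthetic-data generator so every stage
is testable without access to a controlled cohort.

## Who this is for

Researchers modeling binary biomarker positivity (e.g. amyloid, GFAP,
NfL, pTau181 status) from plasma protein panels who want protein–protein
interactions in the model *without* giving up interpretability: the
model has exactly one propagation intensity per protein and one linear
weight per protein per biomarker, and nothing else.

## The model

Independent effects `X ∈ R^{d×n}` (proteins × participants, scaled into
(0,1)) are converted to interaction-aware *synergetic effects* by the
closed-form Laplacian-regularized solve

    Z = (Φ + L)⁻¹ Φ X,      L = I − D^{−1/2} W D^{−1/2},  Φ = diag(φ), φ > 0,

which minimizes a smoothness-plus-steadiness objective over the weighted
PPI graph `W` in a single global propagation step. Per-biomarker risks
are logistic read-outs `P_b = σ(θ_bᵀ Z)`. The shared `φ` and per-task
`θ_b` are trained jointly by full-batch gradient descent (plain or ADAM)
on summed binary cross-entropy with an L2 penalty, using analytic
gradients obtained by implicit differentiation of the linear solve. See
`docs/methods.md` for the derivation, numerical conventions and the
generator's assumptions.

## Worked example

```python
import numpy as np
import synprop as sp

# a synthetic cohort drawn from the model's own generative process
spec = sp.SyntheticSpec(d=30, n=3000, seed=7)
data = sp.make_dataset(spec)

tr, te = np.arange(2000), np.arange(2000, 3000)
X_tr = sp.ExpressionMatrix(data.X.values[:, tr], data.X.protein_ids,
                           [data.X.sample_ids[i] for i in tr])
X_te = sp.ExpressionMatrix(data.X.values[:, te], data.X.protein_ids,
                           [data.X.sample_ids[i] for i in te])
y_tr = sp.BiomarkerLabels({b: v[tr] for b, v in data.labels.labels.items()},
                          X_tr.sample_ids)

result = sp.fit(X_tr, data.network, y_tr,
                sp.TrainConfig(max_epochs=1000, eta=0.01, tol=0.0))
risks = sp.predict(result.params, X_te, data.network)

for b in data.labels.biomarkers:
    y = data.labels.labels[b][te]
    print(b, round(sp.auroc(risks.scores[b], y), 3),
          "| oracle", round(sp.auroc(data.true_logits[b][te], y), 3))
```

prints

```
Abeta 0.688 | oracle 0.712
GFAP 0.737 | oracle 0.74
NfL 0.682 | oracle 0.707
pTau 0.674 | oracle 0.716
```

i.e. on data generated by the model's own process, the fitted model's
held-out AUROC tracks the best achievable (true-logit oracle) AUROC to
within a few hundredths for every biomarker; the remaining gap is
finite-sample estimation error. The fitted `result.params.theta[b]`
correlate with the planted weights at Pearson r ≈ 0.87–0.92.

The same pipeline is scriptable from the shell:

```bash
synprop simulate --d 30 --n 2000 --seed 1 --out sim/
synprop fit      --expression sim/expression.tsv --edges sim/edges.tsv \
                 --labels sim/labels.csv --out fit/
synprop evaluate --expression sim/expression.tsv --edges sim/edges.tsv \
                 --labels sim/labels.csv --reps 5 --out eval/
synprop explain  --params fit/params.json --expression sim/expression.tsv \
                 --edges sim/edges.tsv --labels sim/labels.csv --out explain/
```

Every subcommand writes a `manifest.json` (config, seeds, input
checksums) so any artifact is reproducible from its manifest alone.

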