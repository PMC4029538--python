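# mammosrc

Margin-specific sparse representation classification (SRC) for
mammographic mass CAD.

Computer-aided detection pipelines for screening mammography produce many
candidate regions, most of which are false positives — normal tissue that
locally resembles a mass.  `mammosrc` implements a false-positive
reduction classifier that represents each candidate ROI by an
812-dimensional feature vector and decides mass vs normal by sparse coding
against class-structured dictionaries.  Its distinguishing idea: instead of
one dictionary whose positive block pools every kind of mass, a separate
two-class dictionary is learned for each radiological margin type
(circumscribed, obscured, micro-lobulated, ill-defined, spiculated), and
the per-dictionary class residuals are fused at score level.  Grouping the
positive atoms by margin makes each dictionary's mass block homogeneous,
which concentrates the sparse code on the true class and improves
discrimination.

## Model

A query feature vector y (standardized with training statistics) is coded
against each learned dictionary D_t = [D_t,mass, D_t,normal] by the lasso
problem

    x̂_t = argmin_x  ½‖D_t x − y‖₂² + λ‖x‖₁ ,

solved with FISTA.  Class residuals r_i = ‖y − D_t δ_i(x̂_t)‖₂ (δ_i keeps
class-i coefficients) are summed over the T margin dictionaries,

    Res_i = Σ_t ‖y − D_t δ_i(x̂_t)‖₂ ,   i ∈ {mass, normal},

and y is assigned to argmin_i Res_i, with confidence
Res_normal − Res_mass.  Each dictionary holds the masses of one margin
type plus an equally sized seeded random sample of normals (class
balancing) and is refined by Fisher discrimination dictionary learning
(FDDL): a discriminative-fidelity objective with an ℓ1 coding penalty and
a Fisher scatter term on the coefficients, minimized by monotone
alternating updates.  Dictionary sparsity quality is measured by the
sparsity concentration in the true class, SCTC(x̂) = ‖δ_true(x̂)‖₁/‖x̂‖₁ ∈
[0, 1]; classification performance by the rank-based AUC of the
confidence.

## Worked example

```python
import mammosrc as m

# Standard synthetic benchmark: 100 masses per margin type + 500
# mass-like normals in a 20-dim structured feature space.
fs = m.gen_feature_clusters(m.ClusterSpec.balanced(seed=0))

results = m.MassMarginSRC(fs).fit(seed=0)
print(results.summary())

rep = m.cross_validate(fs, k=5, runs=1, seed=0)
print({c: round(a, 3) for c, a in rep.mean_auc.items()})
```

prints:

```
Margin-specific SRC model
============================================
feature dimension      20
dictionaries (T)       5
training samples       1000
fit seed               0
lambda1 / lambda2      0.01 / 0.01
--------------------------------------------
dictionary          mass  normal   objective
circumscribed         40      40       59.77
obscured              40      40       60.29
micro_lobulated       40      40       60.33
ill_defined           40      40       59.62
spiculated            40      40       59.96
{'margin_specific': 0.934, 'single': 0.875}
```

The summary lists one balanced two-class dictionary per margin type (40
learned atoms per class) with its final FDDL objective.  The
cross-validation report compares the margin-specific configuration with
the conventional single pooled dictionary on identical folds: the
margin-specific configuration attains the higher AUC, and its per-margin
SCTC (in `rep.sctc_per_margin`) is higher as well — the sparse codes
concentrate better on the true class when each dictionary's mass block is
margin-homogeneous.

The same pipeline runs from the shell on rendered image phantoms:

```bash
mammosrc --seed 1 synth   --out rois --n-mass-per-margin 4 --n-normal 20
mammosrc           extract --manifest rois/manifest.csv --out features.csv
mammosrc --seed 1 train   --features features.csv --out model/
mammosrc           classify --model model/ --features features.csv --out predictions.csv
mammosrc --seed 1 eval    --features features.csv --out report.json
```

`predictions.csv` has columns `id, Res_mass, Res_normal, confidence,
predicted`.

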