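# Methods

`mammosrc` classifies segmented mammographic candidate regions (ROIs) as
mass versus normal tissue with sparse representation classification (SRC)
over margin-type-specific learned dictionaries.  This note records the
model, its assumptions, the numerical choices, what the synthetic
generators do and do not emulate, and known limitations.

## Problem setting

A mammographic CAD pipeline produces candidate ROIs, each a grayscale
patch with a binary segmentation mask.  Most candidates are false
positives — normal tissue that locally resembles a mass.  The classifier's
job is to separate true masses from these mass-like negatives.  Masses are
radiologically categorised by their margin: circumscribed, obscured,
micro-lobulated, ill-defined, or spiculated.  Pooling all margins into one
positive class makes the positive class heterogeneous and, for a sparse
coder, dilutes the number of atoms relevant to any particular query.

## Feature battery (812 dimensions)

Each ROI is reduced to a fixed 812-long vector of seven named blocks.
Texture statistics are computed strictly inside the mask (both endpoints
of a pixel pair, or every pixel of a run, must be foreground):

* **lbp (354)** — 59-bin uniform local binary pattern histograms at
  (P, R) = (8,1), (8,2), (8,3), each computed over two regions: the mask
  interior (mask eroded by R+2 px) and a margin band (mask dilated by R+2
  px minus the interior), i.e. 59 x 3 x 2.  Each histogram is
  l1-normalized.  The two-region split emphasises texture at the mass
  margin, the radiologically decisive zone.  If erosion empties the
  interior the mask itself is used, so histograms always sum to one.
* **sgld (312)** — 13 co-occurrence statistics (correlation, energy,
  entropy, inertia, inverse difference moment, sum average/variance/
  entropy, difference energy/variance/entropy, and the two information
  measures of correlation) from symmetric, normalized co-occurrence
  matrices at distances {1, 2, 4, 6, 8, 10} and directions
  {0, 45, 90, 135} degrees; 64 gray levels by uniform quantization of the
  in-mask range.  Degenerate conventions: logs base 2 with 0 log 0 := 0;
  correlation and the first information measure are 0 when a marginal
  variance or entropy vanishes, so every statistic is finite.
* **rls (20)** — Galloway's five run-length statistics per direction
  (4 directions), 16 gray levels, maximal in-mask runs.
* **glds (96)** — contrast, angular second moment, entropy and mean of
  the absolute gray-level-difference histogram at the same 24
  displacements as sgld.
* **nrl (5)** — normalized radial length of the mask boundary (longest
  sub-pixel iso-contour, ordered traversal): mean, sd, area ratio,
  zero-crossing count of the mean-centred profile, and entropy of a
  10-bin histogram.
* **intensity (5)** — contrast measure (mu_in − mu_band)/(mu_in + mu_band)
  against a 5-px outer band, mean, sd, skewness, excess kurtosis; the
  moment statistics are 0 under zero variance.
* **stellate (20)** — spiculation measures from two gradient maps
  (absolute radial alignment and signed radial derivative) over core /
  inner / outer regions: per-region means and sds, pairwise mean
  differences, plus the global mean and sd of the alignment map.

Quantization depths (64 for co-occurrence/difference statistics, 16 for
run lengths) keep the matrices populated on small ROIs; the literature on
these statistics conventionally uses values in this range.

## SRC core

Training vectors are z-scored per feature with training statistics and
stacked as unit-norm atoms, mass block first: `A = [A_mass, A_normal]`.
A query `y` (standardized with the same statistics) is coded by

    min_x 0.5 ||A x − y||_2^2 + lambda ||x||_1 ,

solved with FISTA (step 1/||A||_2^2, stop when every column's relative
objective change is below 1e−6, cap 1000 iterations; converged columns are
frozen, which makes batch coding cheap).  The epsilon-constrained coding
problem is equivalent to this Lagrangian for a matching multiplier;
`lambda = 0.01 ||A^T y||_inf` by default, which is self-scaling across
feature normalizations.  The class residual is
`r_i = ||y − A delta_i(x)||_2` and the decision is `argmin_i r_i`, ties to
normal.  On non-convergence the best iterate is returned with a flagged
diagnostic rather than an exception.

One consequence of the centering worth recording: coding is sign-agnostic,
so a purely symmetric mean offset between the two classes lies in both
class spans and carries little discriminative signal after
standardization.  What SRC discriminates well is class-specific *structure*
— differences in the low-dimensional subspaces the classes occupy.  The
synthetic generators are designed accordingly (below).

## Fisher discrimination dictionary learning

Each dictionary is compressed and sharpened by FDDL.  With per-class data
`A_i`, codes `X_i` (rows grouped by sub-dictionary) the objective is

    sum_i { ||A_i − D X_i||_F^2 + ||A_i − D_i X_i^i||_F^2
            + sum_{j≠i} ||D_j X_i^j||_F^2 }
    + lambda1 ||X||_1
    + lambda2 ( tr S_W(X) − tr S_B(X) + eta ||X||_F^2 ) ,

alternating (a) class-wise proximal-gradient coding with a step size that
majorizes the smooth curvature and (b) exact atom-by-atom dictionary
updates under the unit-norm constraint (`d = v/||v||` with `v` the
residual-weighted coefficient sum).  Both steps are non-increasing by
construction, so the objective trace is monotone to numerical precision —
this is audited, not assumed.

Defaults: `lambda1 = 0.01`, `lambda2 = 0.01`, `eta = 1` (keeps the Fisher
term well conditioned), `m_i = min(n_i, 40)` atoms per class, 15 outer
iterations, inner coding loop capped at 50 steps with a 1e−6 relative
early stop, relative tolerance 1e−4.  Fifteen outer iterations are enough:
at benchmark scale more than 99 % of the total objective decrease is
achieved well before then, and doubling the iterations leaves AUC and SCTC
unchanged to the third decimal while doubling runtime.  Atoms are
initialized from a seeded sample of each class's own vectors (with
replacement, and a warning, if a class has fewer samples than atoms).

## Margin-specific dictionaries and fusion

For each margin type `t` present in training, a two-class dictionary is
assembled from the margin-`t` masses plus an equally sized random sample
(drawn once, seeded, without replacement) of the normal pool — the
balancing step — and FDDL is run per dictionary.  At test time the query
is coded against every dictionary and residuals are fused by summation:

    Res_i = sum_t || y − D_t delta_i(x_t) ||_2 ,  i in {mass, normal},

decision `argmin_i Res_i` (ties to normal), confidence
`Res_normal − Res_mass` so that larger means more mass-like.  The
conventional single-dictionary configuration is the same code path with
all masses pooled into one pseudo-margin, which guarantees the two
configurations differ only in dictionary structure.  Margin types absent
from training are skipped with a logged warning.

## Evaluation

* **SCTC** — sparsity concentration in the true class,
  `||delta_true(x)||_1 / ||x||_1`, in [0, 1]; 0 by convention for an
  all-zero code.  For a margin-`t` mass it is evaluated against the
  margin-`t` dictionary (margin-specific configuration) or the pooled
  dictionary (single configuration); the true class is always the mass
  block.  It is computed for mass test samples only.
* **AUC** — rank-based (Mann–Whitney) area under the ROC curve of the
  confidence, ties counted half.
* **Cross-validation** — stratified k-fold (strata: margin type for
  masses, class for normals; falls back to class-only stratification when
  a margin stratum is smaller than k), repeated over independent runs;
  each run reshuffles folds and redraws the balanced negative samples.
  Defaults in the evaluation CLI are runs 3 / folds 5 for desk use; the
  library accepts the full 30 x 10 protocol.

## Synthetic data

Two generators make every stage testable without any image archive.

**Feature-space clusters** (`ClusterSpec.balanced`): dimension 20; all
mass margins share a common mean offset of (2/3)·separation along a seeded
direction `g` and a rank-4 shared variation subspace (sd 2); each margin
adds a mean offset (pairwise distance `separation`, default 6, orthogonal
to `g`) and its own rank-3 subspace (sd 2); ambient noise sd 0.5; normals
sit at separation/3 along `g` with broad isotropic sd 2.  Default counts:
100 masses per margin, 500 normals.  The geometry encodes three facts
about CAD data: masses of all margins share most of their appearance (a
bright core), each margin type has its own modes of variation (the
structure a dedicated dictionary can represent sparsely), and negatives
are mass-like false-positive candidates rather than arbitrary tissue.
Plain isotropic clusters would miss the second fact — and without
within-margin structure a dedicated dictionary has no representational
advantage, so the margin-specific configuration would not beat the pooled
one there.  The `separation` knob scales the whole mean structure and
raises AUC monotonically on average; near small separations AUC sits on a
floor set by the class-covariance structure, so monotonicity is only
visible across widely spaced separations.

**Image phantoms** (`PhantomSpec`): band-limited correlated background
("parenchyma-like", Gaussian-filtered white noise), a central blob of
configurable contrast, and one margin recipe per type — sharp sigmoid edge
(circumscribed), low-contrast soft edge with an extra texture veil
(obscured), sinusoidal boundary modulation (micro-lobulated), wide blurred
falloff (ill-defined), 6–14 tapered radial spikes (spiculated).  Normal
patches are background only with a central pseudo-mask.  Morphology
parameters are chosen for visual plausibility; no quantitative morphometry
of real masses is claimed.  The phantoms exercise the feature battery end
to end (the spiculated/circumscribed contrast is detectable in the NRL,
roughness and stellate features), but they are far cleaner than real
mammograms: passing tests demonstrates the pipeline's correctness, not
clinical performance.

## Numerical and degenerate-input conventions

0-based row-major coordinates; mask foreground is pixel value > 0; 16-bit
quantization only at file write; z-scoring uses unit scale for
zero-variance features; zero-norm dictionary columns are left unnormalized;
the zero query codes to the zero solution; empty morphological regions fall
back to the mask itself; matrix files store 17 significant digits and are
read back with round-trip float parsing, so a saved model classifies
bit-identically.

## Problem sizes used in the shipped checks

The direction-of-effect audit runs 10 generator seeds of the full
benchmark (1000 samples each) with 3 runs of 5-fold cross-validation;
the acceptance script reports a 3-seed version of the same benchmark plus
a 100-patch image-pipeline round trip, sizes chosen so the whole
recomputation stays comfortably desk-scale.

## Known limitations

* Real-data quantities (the published SCTC tables and AUCs on DDSM/FFDM)
  require those archives and are out of scope; the synthetic benchmark
  reproduces the direction and regime of the effect, not its published
  magnitudes.
* The LBP block's two-region composition and the 20-feature stellate
  composition are reasonable readings of the battery's stated sizes; other
  compositions of the same lengths exist.
* FDDL hyperparameters are not tuned per dataset; they are fixed defaults
  exposed in `FDDLParams`.
* Margin labels are inputs; the package does not infer a mass's margin
  type.
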