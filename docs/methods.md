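# Methods

## Problem and model

The package grades osteochondral histopathology specimens into four ordered
OA severity levels. Severity is defined by banding the averaged OARSI total
score (0–24). The published band edges overlap (early "< 3.4" versus mild
"2.4–8.6"); we resolve this with half-open bands in which the lower band
wins — early [0, 3.4), mild [3.4, 8.6), moderate [8.6, 15.4),
severe [15.4, 24] — giving a total, deterministic, monotone step function.

Classification operates on a fused feature table: each backbone network
contributes one 4-value class-descriptor block per image (its final 4-way
layer), and five backbones give 20 features per stain. The package treats
extraction as a contract — any callable mapping a resized RGB array to a
4-vector can be registered — because training or shipping pretrained
weights is out of scope. The built-in `mock` backbone (bilinear resize,
8×8 grey-block means, fixed seeded Gaussian projection) is pure and
deterministic, which is what the plumbing tests need.

## PCA subset selection

Features are standardized to zero mean and unit *sample* variance
(ddof = 1), so the covariance of the standardized table is the correlation
matrix and its eigenvalues sum to p. Zero-variance features are a hard
error: dividing by zero is undefined and a constant descriptor indicates an
upstream extraction fault (an explicit drop-and-go mode was considered and
rejected as silently data-dependent). Components are retained up to 95 %
cumulative explained variance.

Mapping retained components back to original features is genuinely open
design space. We score
`importance_j = Σ_m (λ_m/Σλ)·|L_jm|` over retained components *m* whose
eigenvalue exceeds the Marchenko–Pastur upper edge (1 + √(p/n))². The edge
restriction matters: for standardized data the eigenvalues of pure-noise
features scatter in roughly [(1−√(p/n))², (1+√(p/n))²], and at desk-scale
shapes (n = 160, p = 20) many of those sampling-noise components survive a
95 %-variance cut. Summing |loadings| over all retained components then
rewards features that spread mass across many weakly-weighted noise
components more than features concentrated in the leading structured
component — with 4 informative features among 20, the signal component's
variance fraction is capped at 0.2, and simulation shows noise features
outranking informative ones almost always. Thresholding at the noise edge
keeps exactly the components that explain more variance than sampling noise
can, and restores reliable recovery (all four planted features in the top
ten in 100/100 seeded tables). Fallbacks: if no retained component clears
the edge, components with λ > 1 are used; failing that, all retained
components. Ties in importance break toward the lower column index.

## Ant lion optimization of feature weights

The decision vector is (w_1…w_F, κ): one multiplicative weight per selected
feature in [0, 1] plus a continuous coordinate κ ∈ [1, k_max] decoded to the
nearest odd k (odd to reduce vote ties; k_max = 15 by default). The loss is
1 − stratified 5-fold CV accuracy of a weighted Euclidean k-NN, computed on
the training split only — fitness on the evaluation set would leak, and
training-set accuracy has a degenerate self-neighbour optimum at k = 1.
Fold assignment is fixed once per run from the stage seed, so the objective
is deterministic. Because the fitness sits in the optimizer's inner loop it
is evaluated by contracting cached per-feature squared-difference matrices
with the squared weights (d² = Σ_j w_j²Δ_j²), ~1 ms per candidate; a unit
test pins it exactly to an independent sklearn k-NN run on identical folds.

The optimizer is canonical ALO: per iteration, each ant takes the mean of
two cumulative ±1 random walks — one min–max-normalized into bounds centred
on a roulette-selected antlion (selection probability ∝ 1/(loss + 1e-12)),
one around the elite — with bounds shrunk by I = 1 + 10^w·t/T, where the
exponent w steps through 2, 3, 4, 5, 6 at 10 %, 50 %, 75 %, 90 %, 95 %
progress. The merged ant/antlion population is resorted each iteration, the
best-ever candidate (elite) is always retained, and positions are clipped
to the global box. Defaults: 20 ants, 20 antlions, 100 iterations. The
core box-constrained minimizer is exposed separately (`alo_minimize`) so
benchmark objectives can exercise it; on the 10-d sphere function it
reaches < 1e-2 in 20/20 seeded runs.

A caveat documented rather than hidden: when classes are nearly separable,
many weight vectors tie at the minimal CV loss, and at some seeds the fixed
folds make solutions that *retain* noise features strictly fitter than
noise-free ones (verified directly by evaluating oracle weightings); at
such seeds a perfect optimizer will not down-weight noise. Weight-recovery
rates therefore saturate below 100 % — we measure 22/25 seeded runs under
the default study conditions.

## SVM and metrics

The grader is an SVC with a cubic polynomial kernel (γ = "scale",
coef0 = 1, C = 1) behind a StandardScaler fitted on training data; linear
and RBF kernels and both multiclass score schemes (one-vs-rest shaped
decision values; one-vs-one pairwise margins summed per class) are
configurable. Predictions are the argmax of the per-class score matrix,
ties breaking toward the lower grade.

Evaluation collapses the 4×4 confusion matrix one-vs-rest per class into
TP/TN/FP/FN and reports sensitivity, precision, specificity,
F1 = 2PR/(P+R), and the per-class binary accuracy (TP+TN)/N — reported
separately from, and labelled distinctly to, the overall multiclass
accuracy trace/N. Ratios with empty denominators (plausible for a small
severe class) are reported as 0 and flagged in the report rather than
raising or propagating NaN. ROC curves sweep unique scores descending and
include (0,0) and (1,1); AUC is trapezoidal.

## Pipeline hygiene

Scenario order: stratified split → (fuse) → standardize + PCA select →
ALO weighting → SVM → evaluate, with every fitted statistic derived from
the training split and applied unchanged to test. One global seed fans out
to per-stage seeds via sha256(f"{seed}:{stage}") mod 2³¹ (Python's builtin
`hash` is salted per process and unusable for reproducibility). All
artifact files are written with fixed float formatting, so identical
configs give byte-identical files. The default split is stratified 80/20.

## Synthetic data

The generator emulates the fused representation: 20 features tagged
4-per-pseudo-backbone, four balanced classes, Gaussian noise of SD 1.
Class means sit on a 1-D severity axis spread uniformly over the
informative dimensions — grade g lies at g·separation·noise_sd along the
unit axis, so adjacent class means are exactly `separation` noise-SDs apart
in the informative subspace — mirroring the ordinal structure of OA
progression and giving weight/selection tests a ground truth. Informative
indices are spread evenly across the feature vector so selection crosses
backbone blocks. Defaults (40 per class, 4 informative + 16 noise,
separation 4) are the conditions used throughout the tests and the
acceptance script. What the generator does **not** model: stain-specific
color distributions, inter-feature correlations within a backbone block,
class imbalance (the real severe class is rare), or annotation noise —
so passing tests demonstrate algorithmic correctness and recovery of
planted structure, not clinical performance. Toy images (sine-profile
"articular surface" with grade-indexed amplitude plus grade-indexed dark
cell dots) exist purely to exercise the manifest/extractor plumbing.

## Problem sizes and numerical choices

Simulation-backed tests use 120–160 samples, 10–20 features, 5-fold CV,
25–100 seeds per property; Monte-Carlo assertions use 3–4 SE bands around
their null values. Eigenvector signs are fixed so each loading column's
largest-magnitude entry is positive. The roulette guard is ε = 1e-12;
PCA invariants are asserted at 1e-8.

## Known limitations

- Real backbone extraction is a plug-in contract, not shipped: reported
  numbers on synthetic tables say nothing about accuracy on real stained
  slides.
- The k-NN-fitness wrapper can prefer noise-bearing weightings at fixed CV
  folds (see above); averaging the fitness over multiple fold seeds would
  smooth this at proportional compute cost.
- A strong-separation SVM check uses a mean-over-seeds band (≥ 0.9 at
  separation 6) because single-seed CV accuracy fluctuates by several
  percent at 30 samples per class.
- Grade banding hard-codes the 4-level OARSI convention; sub-scores are
  not modelled.
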