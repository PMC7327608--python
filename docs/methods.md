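# Methods

## Problem setting

The package targets numeric biomedical feature tables in which (a) a small
to large fraction of cells is missing and (b) the class inventory is
heavily imbalanced. The canonical shape is the 452 × 279 arrhythmia
feature table: 13 populated classes whose counts are
245, 44, 15, 15, 13, 25, 3, 2, 9, 50, 4, 5, 22 (labels 1–10 and 14–16;
labels 11–13 are empty and play no role), with roughly 0.33% of feature
cells missing. Incomplete data are carried as a `MaskedMatrix`: a value
array plus a binary observation mask. Missing cells hold the placeholder 0
by convention, but every computation goes through the mask, and the test
suite enforces that arbitrary placeholder values leave all downstream
output bit-identical.

## Imputation

**Zero / mean.** Reference baselines. The mean imputer uses the observed
column mean (a column with no observed value falls back to 0).

**Masked PCA.** The masked scatter matrix

    S(k,l) = (1/N) Σ_j x_j^(k) x_j^(l) z_j^(k) z_j^(l) − x̄^(k) x̄^(l)

only accumulates co-observed entry pairs. Two divisor modes exist for the
masked mean x̄: `paper_literal` divides masked column sums by the total row
count N (the literal printed definition, default for the PCA path), while
`observed_count` divides by the per-column observation count (the
statistically standard mean, used by the mean imputer). With a complete
mask both modes coincide and S reduces exactly to the classical scatter.
The top-q eigenvectors W of S form the projector (q explicit, or "auto" =
smallest q covering 95% of the positive-eigenvalue mass — S can be
indefinite under heavy masking, so eigenvalues are clamped at zero for the
mass rule). Each row's coordinates solve the least-squares problem
restricted to that row's observed entries (least-norm solution if the
restricted system is singular); reconstruction is μ + W y with μ the
masked mean when centering is on (default) and 0 otherwise. Only missing
cells are filled — observed values are trusted and never overwritten, for
all four imputers. Rows with no observed cell take observed column means
and are flagged in the diagnostics.

A note on exactness: for exact rank-1 data under a *generic* random mask,
masked-PCA recovery is approximate, because the co-observation counts vary
across column pairs and the masked scatter is then not rank-1. The test
fixture for exact recovery therefore uses a balanced co-observation design
(one masked cell per row, cycling columns; sign- and magnitude-balanced
row coefficients; uniform loading vector), for which the masked scatter is
exactly (const)·vv′ + (const)·I and recovery is exact to machine
precision.

**SVT completion.** The completion problem `min rank(X) s.t. P_Ω(X) =
P_Ω(M)` is relaxed to nuclear-norm minimisation and solved by singular
value thresholding: starting from Y₀ = 0, alternate a singular-value
shrinkage X_k = shrink_τ(Y_{k−1}) with an observed-entry correction
Y_k = Y_{k−1} + δ·P_Ω(M − X_k), until the relative residual on observed
entries falls below ε or the iteration cap is hit (then the best iterate
is returned with a `converged: False` diagnostic, not an exception).

Defaults: ε = 10⁻⁴; δ = min(1.2·N·d/|Ω|, 1.9) (the classical 1.2/p step
capped below the δ < 2 stability bound); τ = 25·max(N, d); max_iter =
5000. The τ default deserves a note: the widely quoted heuristic is
τ = 5·max(N, d), but the SVT fixed point only approaches the exact
nuclear-norm minimiser as τ → ∞, and at τ = 5·max(N, d) the shrinkage
bias is visible on small matrices — on 100 × 100 rank-5 instances with
40% of entries observed, roughly one draw in six converges to a rank-10
fixed point with ~1% full-matrix error no matter how tight the residual
tolerance. At τ = 25·max(N, d) all twelve instances examined recover the
hidden entries to ≤ 5·10⁻⁴ relative error within a few thousand
iterations (a few seconds at this size), so that is the default; the cost
is roughly 2–3× more iterations than the smaller τ.

The benchmark harness passes its own SVT configuration with max_iter =
500: realistic tabular data are not exactly low-rank, the residual
tolerance is therefore never reached there, and the cap bounds the cost of
one grid cell (≈ 12 s at 452 × 279) while the resulting completion is
already stable for classification purposes. Column standardization before
SVT is available behind the imputer configuration but off by default: the
iteration operates on the raw observed matrix.

## Classifiers

All five classifiers use exact Euclidean neighbour search (stable argsort,
so distance ties break by training-row order and every prediction is
deterministic). Vote ties break by the nearest-member rule: among
top-scoring classes, the one owning the closest neighbour wins.

* **KNN** — majority vote.
* **DS-WKNN** — Dudani distance weights w_i = (d_k − d_i)/(d_k − d_1);
  all-equal distances degenerate to w ≡ 1.
* **DF-WKNN** — weights minimise ½‖x − w′X_NN‖² subject to Σw = 1.
  With D the k × d matrix of differences x − x_i^NN and G = DD′, the
  solution solves (G + η·tr(G)/k·I) w̃ = 1 followed by normalisation to
  Σw = 1 (equivalently the KKT closed form G̃⁻¹1/(1′G̃⁻¹1); the tests
  verify the equivalence against an explicit saddle-system solve).
  Weights may be negative — the constraint is sum-to-one, not
  non-negativity — and votes use signed sums. η defaults to 10⁻² (the
  reference range is 10⁰–10⁻³); tr(G) = 0 (query coincides with every
  neighbour) degenerates to uniform weights.
* **KDF-WKNN** — same solve with the Gram entry expanded in kernel space:
  G_ij = κ(x_i, x_j) − κ(x_i, x) − κ(x, x_j) + κ(x, x). The linear kernel
  reproduces DF-WKNN exactly (a tested identity). Default kernel is rbf
  exp(−‖a−b‖²/2h²) with h the median pairwise neighbour distance
  (fallback 1 when the median is 0); the kernel choice for the original
  method is not pinned anywhere, so the rbf/median default is the
  conventional one and the linear kernel is provided for the equivalence
  path.
* **MKDF-WKNN** — KDF-WKNN with the class correction factor

      γ_i = log(λ + n/φ(i) + ζ) / log(λ + 1),
      λ = round(max_i φ(i) / avg_i φ(i)) (≥ 1),

  the average taken over classes that actually occur in training (empty
  classes would make it meaningless). γ is strictly decreasing in the
  class count φ(i): for the arrhythmia profile λ = 7, the 245-member
  dominant class gets γ ≈ 1.048 and a two-member class γ ≈ 2.621
  (ζ = 10⁻⁴). The factor multiplies the per-neighbour weights inside the
  vote, after weight normalisation — so on a balanced training set all γ
  coincide and MKDF-WKNN predicts identically to KDF-WKNN. Any fixed
  logarithm base cancels in the ratio; natural log is used.

## Benchmark harness

`inject_missing` masks exactly round(target·N·d) − (already missing)
additional observed cells, drawn uniformly with a seeded generator; the
target proportion is interpreted as the overall missing fraction including
pre-existing missingness, newly masked placeholders are zeroed so no
imputer can see the deleted values, and existing missing cells are never
unmasked. `kfold_indices` is a seeded shuffle followed by a contiguous
split: disjoint folds covering all rows, sizes within 1. Folds are not
stratified (two-member classes cannot stratify into ten folds).

`cross_validate` follows the reference pipeline order: the imputer sees the
whole masked table once, then folds are split and each fold is scored by
the classifier trained on the remaining nine. This order leaks test-row
information into the imputation; it is kept as the default for fidelity,
and a `per_fold_imputation` flag provides the leakage-free variant (zero
and mean transfer trivially; PCA transfers its fitted basis and mean to
test rows; SVT is transductive with no out-of-sample rule, so the train
block is completed and test-row gaps take completed-train column means).
MKDF correction factors are always computed from the training folds only.
If k = 151 exceeds a training-fold size, `cross_validate` raises by
default; the grid runner clamps k to the fold size with a warning instead,
so one small dataset cannot abort a whole benchmark.

`benchmark_grid` draws one deletion pattern per proportion (seeded
deterministically from the master seed) and shares it across all imputers
and classifiers, so cells at a proportion are compared on identical
missingness; one imputation per (proportion, imputer) pair is shared by
all five classifiers, and the same fold partition is used everywhere. The
whole grid is bit-reproducible under a fixed master seed.

## Synthetic data

* `gen_lowrank` — ground truth AB′ with i.i.d. standard-normal factors,
  optional i.i.d. noise, and an exact-count uniform observation mask.
* `gen_imbalanced_blobs` — isotropic Gaussian classes with exact per-class
  counts; class centers sit on scaled coordinate axes at the requested
  pairwise separation (seeded random directions beyond the dimension).
  The imbalance-mechanism fixture is 190-vs-10 rows at separation 2 sd:
  overlapping enough that a k = 21 neighbourhood of a minority point is
  majority-dominated, which is exactly the failure mode the correction
  factor addresses.
* `gen_uci_like` — 452 × 279 with the exact arrhythmia class inventory,
  log-normal column scales spanning several orders of magnitude, a block
  of 75 binary columns, class-dependent mean shifts, and exactly
  round(0.0033·452·279) missing cells. The shift magnitude (0.3
  within-class sd per column, binary-probability spread 0.15) was set so
  the five classifiers' 10-fold accuracies occupy the band reported for
  the real table (KNN family mid-50s %, difference-weighted family
  65–80%); with k = 151 the plain KNN and DS-WKNN collapse to the
  majority class (54.2%), which the real table also nearly does. The
  generator emulates class imbalance, scale heterogeneity and missingness
  — not real ECG feature dependence structure — so passing benchmarks
  demonstrate the pipeline's mechanics and relative method behaviour, not
  clinical accuracy.

## Problem sizes and runtime

The shipped test-and-demo sizes are chosen to run in seconds-to-minutes on
one CPU: SVT recovery at 100 × 100 rank 5 with 40% observed; the benchmark
grid on the 452 × 279 table at proportions {baseline, 10%, 70%} (the full
10–70% sweep is a CLI flag away). The 2 × 4 × 5 reduced grid completes in
under a minute.

## Known limitations

* The masked scatter can be indefinite under heavy masking; eigenvalue
  clamping handles the component-count rule, but with very few co-observed
  pairs the PCA imputer degrades sharply (visible in the 70%-missing
  benchmark column, matching the instability the method is known for).
* SVT assumes the low-rank-plus-observed-entries model; on full-rank noisy
  tables it acts as an iteration-capped smoother rather than a solver.
* The default pipeline order imputes before fold-splitting (see above);
  published-style accuracies obtained this way are optimistic relative to
  the leakage-free variant.
* Class labels never inform imputation; demographic-style columns are not
  treated specially (all 279 columns are uniform numeric features).
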