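# Methods

This note records the scientific and numerical choices behind each stage of
the pipeline: what is computed, under which assumptions, which parameters
matter, and where the design was genuinely open.

## Synthetic fixtures

The fixture module generates the data every test and the acceptance script
run on. Two generators share one `FixtureSpec` and derive independent
seeded streams from a single integer seed (no global RNG state):

* **Images** are blob-texture fields: soft Gaussian blobs on a bright,
  faintly tinted background plus pixel noise. Class 1 tiles carry a higher
  expected blob count; the two class means differ by `class_separation`
  standard deviations of the per-tile blob-count jitter. Blobs are placed
  fully inside the tile with a narrow radius range and the intensity field
  is not saturated, so the total "ink" — and hence mean tile intensity —
  is near-linear in blob count. That keeps the generator honest: the
  requested effect size is actually present in the pixels and recoverable
  by a linear read-out, rather than being destroyed by rendering
  artifacts.
* **Feature tables** are Gaussian class-conditional draws:
  `n_informative` columns (positions seeded, recorded in
  `informative_ids`) have class means separated by
  `class_separation × noise_sd`; all other columns are identical noise in
  both classes.

What the fixtures emulate is *statistical separability with known ground
truth* — planted effect sizes, planted informative sets, balanced classes.
What they do not emulate: H&E stain statistics, tissue morphology,
slide-level correlation between tiles from one patient, label noise, or
class imbalance. Passing tests therefore demonstrate that the pipeline's
mechanics recover known signal under controlled conditions; they say
nothing about clinical performance on real slides.

## Augmentation

Per input tile the augmenter emits the original (optional), one scaled,
one vertically flipped, and `n_rotations` rotated copies — output count is
exactly `N × (include_original + 2 + n_rotations)`. Open details were
fixed as follows: "scaling by 20%" is resize by 1.2 then center-crop to
the original geometry, so all outputs share one shape; rotation angles are
uniform on ±`rotation_range_deg` (default 50°), redrawing an exact 0;
rotations use reflection padding (avoiding black corners that would
dominate pooled features) and bilinear interpolation. The vertical flip is
a pure index reversal and hence an exact involution. Originals are tallied
separately from augmented copies, since published per-class counts list
the five augmented variants per tile on their own.

## Feature extraction

Preprocessing resizes to `input_size²` (default 224) and subtracts a
per-channel reference mean — fixed constants by default (the conventional
ImageNet channel means, recorded in the config), with an opt-in
`"dataset"` mode that recomputes the mean from the batch; the wording of
"removing the average intensity" is ambiguous between the two, so both are
supported and the default is the reproducible one.

The backbone is pluggable. `resnet50` consumes the published 50-layer
residual architecture through torchvision (never re-derived); its output
length is a pure function of input size because the network downsamples by
32 and ends in 2048 channels — 7·7·2048 = 100,352 at input 224 — and the
extractor asserts this. `stub` is a deterministic spatial-pyramid
descriptor (per-channel block means, then standard deviations, over 1×1,
2×2, 4×4, … grids, coarse-first, truncated to `stub_width`): global
intensity statistics lead, so texture-density signal concentrates in the
leading columns. The stub exists because output *shape and determinism*,
not weight values, are the contracts the rest of the pipeline depends on;
it also keeps CI free of framework downloads.

## Feature selection

Elimination is chunked: per round, drop the least-important
`step` (default 10%) of surviving features until `target_n_features`
remain — one-at-a-time elimination from 100k features would be
computationally absurd. Importance is the decision tree's entropy-based
impurity decrease, averaged over `n_folds` stratified folds; mean fold
accuracy is recorded per round as a diagnostic curve.

One refinement proved necessary: a *single* deterministic tree per fold
concentrates all importance on the few features it splits on, so equally
informative features tie at exactly zero importance with noise features
and the deterministic tie-break (retain lower column index) eliminates
them arbitrarily. Each fold therefore fits `n_tree_seeds` (default 3)
trees with per-split candidate subsampling (`max_features="sqrt"`) under
seeds derived from (round, fold, repetition); averaging spreads importance
across all features carrying signal while remaining fully reproducible.
Under the standard recovery conditions (5 planted among 100, effect size
3σ, 100 samples) this recovers the exact planted set in 20/20 replicates,
versus 2/20 for the single-tree variant.

Entropy follows the standard definition E = −Σ pᵢ log₂ pᵢ with
0·log 0 := 0.

## Fuzzy partitions and Wang–Mendel rules

Each selected rule variable is discretized into `n_levels` (default 9,
indices 0–8) membership functions ordered by center. Uniform placement
spaces apexes evenly over [min, max] — adjacent triangles then cross at
membership 0.5 and sum to 1 inside the domain; FCM placement instead puts
apexes at fuzzy c-means centers (fuzzifier m = 2, alternating updates,
objective non-increasing, centers returned sorted). Edge membership
functions extend past the domain bound far enough that the bound keeps
membership ≈ 0.5 or more, preserving coverage. A constant column
degenerates to a single all-covering level with a warning. Five kinds are
supported — triangular (default), trapezoidal, piecewise-linear, Gaussian
(σ chosen so membership is 0.5 at the nearest neighboring center), and
generalized bell — all mapping into [0, 1].

Rule induction is classic Wang–Mendel: per training sample, the antecedent
is the argmax-membership level per variable (ties → lower index), the
degree is the product of those memberships, the consequent is the label.
Identical (antecedent, consequent) pairs deduplicate; conflicting
antecedents keep the maximum-degree rule. Provenance counts (primitive =
n samples, deduplicated, final) are kept on the rule base, which
serializes to JSON.

Rule features are chosen by a prefilter: drop columns whose exact-zero
fraction exceeds `zero_frac_threshold` (default 0.10; the alternative
reading of 0.50 is selectable), rank survivors by |Pearson r| with the 0/1
label (point-biserial), keep the top `top_k` (default 8), shuffle rows
with the configured seed.

Max–min aggregation (per output grid point, max over rules of
min(activation, consequent membership)) and centroid defuzzification
(∫yμ dy / ∫μ dy via trapezoidal quadrature; undefined and rejected for an
all-zero set) are provided as inference primitives.

## The fuzzy deep classifier

Architecture (K classes, M rules, hidden width h, input width d):

```
dense path:  x → standardize → ReLU → dense(d→h) → ReLU  → h₁
rule path:   x[rule features] → αᵢ = Πⱼ μᵢⱼ(xⱼ)          → α (M values)
output:      [h₁ ; α] → linear((h+M)→K) → softmax
```

The output layer *is* the defuzzification β_k = Σᵢ αᵢ w_ik plus the dense
path's contribution and a bias. The rule block of the output weights is
initialized one-hot by rule consequent, scaled by the rule's degree
relative to the mean degree; raw degrees are products of eight
memberships (~10⁻³) and without the global rescale the randomly
initialized dense block (drawn at small scale, 0.1/√h) would drown the
rule scores at epoch 0. With it, rule knowledge dominates early epochs and
gradient training refines both pathways.

Two numerical choices matter inside the fuzzification layer. First,
compact-support membership kinds make the plain conjunctive product
*exactly zero* for any sample more than one level away from a rule in any
single variable — in eight dimensions that is the majority of unseen
samples, which would silence the rule path precisely where generalization
is needed. Each factor is therefore floored at `activation_floor`
(default 10⁻³), so rules violated in fewer variables still fire strictly
harder. Second, the floored activations are normalized per sample to sum
to one (the normalized-firing-strength layer familiar from neuro-fuzzy
systems), putting the rule-path scores on a scale independent of how
sparsely a sample is covered. The public `fuzzify()` keeps the plain
product (floor 0) so the stated firing-strength equation remains testable
against brute-force recomputation.

Training is Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸) at learning rate 0.001
on the cross-entropy loss, batch size 32, default 100 epochs, with a
stratified 80/20 train/validation split; per-epoch train and validation
loss and accuracy are recorded in `history_`. The dense path standardizes
inputs with training-split statistics; the rule path sees raw values (its
partitions are fitted on raw training values). Forward/backward passes and
the optimizer are implemented directly in numpy; a non-finite loss aborts
with a diagnostic. With a fixed `random_state` the fitted weights are
bit-reproducible. Softmax is computed shift-invariantly; ReLU is
max(0, x).

Defaults left open by the recipe: hidden width 128, triangular membership
kind inside the network (the kind found best in the comparison protocol;
trapezoidal and piecewise-linear are selectable to rerun that
comparison), and remaining Adam moments at conventional values.

## Evaluation

Confusion counts are exact; metrics are direct substitutions —
precision TP/(TP+FP), recall TP/(TP+FN), F1 2TP/(2TP+FP+FN), accuracy
(TP+TN)/n, specificity TN/(TN+FP) — computed per class (each class
treated as positive in turn) and macro-averaged (unweighted arithmetic
mean of the two class columns). A zero-denominator ratio is reported as
NaN with an `undefined` flag, never silently coerced to 0.

## Orchestration

`run_pipeline` executes fixtures → augment → extract → select → rules →
train → evaluate, writing every artifact (feature CSVs, ranking, rule-base
JSON, report JSON) plus a manifest (caller's config, its hash, the seed)
into the run directory; a manifest fully determines a run and a rerun with
the same config reproduces the report byte-for-byte. The
membership-function comparison harness trains once per kind under a shared
seed, split and rule-feature set, reporting rule-generation time (wall
clock; reported, never asserted — it is hardware-dependent) and final
train/test error per kind.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so the full
suite completes in well under a minute of compute per experiment on one
CPU: tiles of 32–48 px (tens per class, ×6 after augmentation), stub
features of width 24–48, elimination from ~100 columns, classifiers with
16–64 hidden units trained 5–60 epochs. The frozen end-to-end recovery
conditions are 40 tiles per class at 48 px with class separation 6, stub
width 48, selection to 16 features, hidden width 64, 60 epochs. Slide-
scale settings (100,352 → 10,000 features, 100 epochs) remain the
defaults of the respective configs and run unchanged on real extracted
features — only the inputs differ.

## Known limitations

* The `resnet50` backbone requires torch/torchvision at call time; without
  them the extractor raises an actionable error and the stub must be used.
* The fuzzification layer's partitions are fitted on the training split
  and frozen; membership parameters are not themselves trained (only the
  defuzzification weights are).
* Rule bases grow with training-set size (one primitive rule per sample);
  no rule pruning beyond deduplication and conflict resolution is
  implemented.
* The augment-then-split order mirrors the published procedure: augmented
  variants of one source tile can land on both sides of the train/
  validation split, so validation accuracy on augmented sets is optimistic
  relative to a patient-level holdout.
* Binary labels only (0/1) in the evaluation module; the classifier
  itself accepts any label alphabet but the pipeline and metric suite
  assume two classes.
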