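# Methods

## The problem

Protein chains fluctuate around their native structures, and the amplitude
of those fluctuations — summarized as the per-residue root-mean-square
fluctuation (RMSF) of the C-alpha atoms over a molecular-dynamics
trajectory — underlies many of their functions.  Running the simulations is
expensive; this package implements the alternative of predicting a chain's
flexibility directly from its static structure, encoded as a compact vector
of global shape descriptors.

## Gauss-integral descriptors

A C-alpha trace with N residues is an open polygonal curve with N−1
segments.  For two nonadjacent segments the mutual Gauss double integral is
computed in closed form from the signed area of the spherical quadrilateral
spanned by the four unit vectors connecting the segment endpoints: the four
face normals are formed, consecutive normal dot products are arcsine-summed
(each argument clamped to [−1, 1]), the handedness sign comes from the
scalar triple product of the two segment directions with a connecting
vector, and the total is divided by 2π.  The normalization is chosen so the
value counts both integration orders; consequently

* |W(i, j)| is exactly the probability that segments i and j cross in a
  projection along a uniformly random direction, and
* the sum of |W| over all pairs is literally the average crossing number
  (ACN), while the signed sum is the writhe.

Degenerate configurations — segments sharing an endpoint, collinear
segments, cross products with norm below 1e−12 — contribute exactly 0;
zero-length segments raise an error.

Higher-order invariants are organized by chord diagrams: a pattern of order
k pairs 2k index slots into k chords, and its value is the sum over strictly
increasing slot-index tuples of the product of the corresponding W entries,
with the absolute value applied to flagged chords.  The default registry has
30 components: chain length N, writhe I(1,2), ACN I|1,2|, the three order-2
matchings in all four abs variants (12), and the fifteen pure order-3
matchings.  The registry is data-driven (JSON), so an alternative
enumeration — e.g. replacing some pure order-3 patterns by abs variants, or
dropping the length — can be swapped in without code changes.

### Fast evaluation

Pattern sums are evaluated by a small symbolic engine.  A slot x that
appears in exactly one factor M[x, x_j], with surviving chain neighbours
lo < x < hi, is summed out via a column-wise cumulative sum,
`CS[hi−1, x_j] − CS[lo, x_j]`, splitting the term in two.  Reduction always
reaches at most three surviving slots for orders ≤ 3; a residual term over
u < v < w with pair factors A, B, C is finished with one masked BLAS
product, `sum(C ∘ (A_upper @ B_upper))`.  Orders 1–2 therefore run in
O(n²), order 3 in O(n³); all 30 descriptors of a 500-segment chain complete
in under a second on one CPU.  A brute-force nested-loop enumerator and two
Monte-Carlo projection estimators (crossing counts over random directions)
serve as independent oracles in the test suite.

## RMSF and flexibility labels

Frames are superposed on an iteratively refined mean structure (Kabsch
superposition with a proper rotation; alignment and mean are recomputed
until the mean shifts by < 1e−6 Å or 10 rounds).  RMSF_i is the root mean
squared displacement of residue i about its mean position.  The per-protein
scalar is the replicate-averaged profile averaged over residues; the two
averaging orders commute for equal-length replicates, so the choice is
presentational.  Proteins whose scalar strictly exceeds the dataset-wide
mean are labeled flexible; a value exactly at the threshold is
non-flexible.  The threshold is computed on the raw scale (log-transformed
values are only ever used for display).

## Descriptor statistics

Descriptor matrices are scaled to unit variance per column (division by the
standard deviation, no centering — the network consumes uncentered
features; PCA centers internally).  Zero-variance columns are left unscaled
with a warning.  The default pipeline fits the scaler on the training pool
and applies it to the test set (leakage-safe); fitting across the full
dataset is available where a caller wants the dataset-wide convention.
PCA is SVD-based with column signs fixed by making each loading's
largest-magnitude entry positive.  Structural clusters are k-means (k = 4,
10 restarts) on the first two PC scores, with labels renumbered 1..k by
descending cluster size so the labeling is reproducible.  k-means is an
explicit, replaceable stand-in: the clusters are defined in the PCA plane
and no particular boundary-drawing algorithm is canonical.  A protein's
dominant secondary structure is the class with the highest residue count
(ties: helix > sheet > coil, logged).

## Models

All four architectures read the 30-component descriptor vector.

* **Attention CNN** (primary): four 1-D convolution blocks (kernel 3,
  padding 1, stride 1, ReLU) map 1 → 32 → 64 → 64 → 128 channels while
  preserving the 30 positions; additive attention scores each position from
  its 128-dim feature (tanh projection to a 64-dim attention space, scalar
  score) plus a learned per-position bias, softmax over positions; the
  attention-weighted sum gives one 128-dim vector, mapped by a dense layer
  to a single logit (sigmoid for classification, identity for regression).
  The per-position bias matters: the convolution stack is
  translation-equivariant, so without it attention can only prefer
  positions by their feature *values*, never by their *index* — on data
  whose columns are identically distributed, interior positions are then
  unidentifiable in principle.  The bias (initialized at zero) breaks that
  symmetry and is what lets the model localize a planted informative
  component.
* **Plain CNN**: the same stack with mean pooling instead of attention.
* **GRU**: a single-layer gated recurrent network reads the vector as 30
  time steps of one feature (hidden size 64; the last hidden state feeds
  the head).  The update-gate bias is initialized at −1 so the gate starts
  near "carry": with a symmetric init the effective memory decays like
  0.5 per step and information from early positions is lost over the
  30-step read, which stalls learning under the fixed training budget.
* **SVM (RBF)**: scikit-learn SVC/SVR with C = 1 and gamma = "scale"
  (1/(30·Var[X])), Platt-scaled probabilities for classification.

The neural models run on a compact reverse-mode autodiff engine written in
numpy for this package: single-threaded, dependency-light, bit-reproducible
for a fixed seed, and differentiable with respect to the *input* as well as
the parameters, which is exactly what Integrated Gradients needs.  All
parameter initialization is drawn from a generator seeded by the model
spec, so fixing the seed fixes the initial weights bit for bit.

## Training protocol

Defaults follow the study design: binary cross-entropy (classification) or
mean squared error (regression), Adam with learning rate 1e−3 and L2 weight
decay 1e−4 added to the gradient, batch size 32, at most 50 epochs, early
stopping with patience 7 monitored on validation loss (best-validation
weights restored).  20% of the data is held out (stratified by class for
classification, e.g. 1,374 → 1,099 + 275); the pool is split into five
stratified folds; one model is trained per fold; the fold with the best
validation accuracy (classification; lowest validation loss for
regression; ties to the lowest fold index) is selected; a fresh model with
that fold's seed is retrained on the whole pool for the fold's
early-stopped epoch count (no validation set remains, so the budget is the
best epoch + 1); and the untouched holdout is scored once.

## Metrics

AUC uses the rank statistic with half credit for ties; its 95% CI is a
percentile bootstrap over 2,000 resamples of test indices (resamples that
lose a class are skipped).  Average precision is the step-wise area under
the precision-recall curve; maximum F1 and the Youden J threshold are
exhaustive over observed score thresholds with the `score >= t` decision
rule, ties resolved toward the lower (more sensitive) threshold.  The
confusion matrix is row-normalized at the Youden threshold; calibration
uses 10 equal-width probability bins with empty bins omitted.  Regression
reports Pearson r, R² = r², the least-squares slope of predicted on true,
and the *median* absolute error.  Integrated Gradients integrates the
gradient of the task-scaled output along the straight path from a zero
baseline, Riemann-approximated at `steps` midpoints (default 256), so the
completeness identity holds to discretization error and a linear model is
attributed exactly.

## Synthetic data

The generators define the conditions under which the package is validated:

* **Backbones**: the ideal helix places residues on a cylinder with rise
  1.5 Å and turn 100° per residue; the radius is derived from the 3.8 Å
  bond length (≈ 2.28 Å, the textbook ~2.3 Å) so consecutive C-alpha
  distances are exact, and handedness is a mirror flip.  Strands are
  gently twisted pleats with exact bond lengths; the planar zigzag lies in
  z = 0 (its descriptors vanish identically — a useful null); hairpins are
  two antiparallel arms joined by a short turn; coils are fixed-step
  (3.8 Å) self-avoiding random walks with a 3.0 Å non-bonded clearance and
  a 10⁴-retry budget.  Coil geometry, not Ramachandran statistics, is what
  the descriptors see, so the simple walk suffices.
* **Trajectories**: frames are the reference plus isotropic per-residue
  Gaussian noise with a caller-supplied σ-profile, composed with a random
  rigid motion per frame so superposition must do real work.  The expected
  superposed RMSF of residue i is σ_i·√3.  The noise is frame-independent;
  no attempt is made at correlated, physically realistic dynamics, so
  passing tests demonstrate correct RMSF *machinery*, not force-field
  realism.
* **Labeled descriptor sets**: standard-normal features with a planted
  linear signal on chosen components; labels are the thresholded (or raw)
  noisy latent score.  The achievable performance is known in closed form —
  Bayes AUC = 1/2 + (2/π)·arcsin(a/√(2(a² + σ²))) with a² = effect²·k, and
  Bayes R² = a²/(a² + σ²) — and solvers invert these so experiments are
  specified by their achievable target (e.g. effect sizes giving Bayes AUC
  0.95 or true R² 0.7 at n = 1,000, the conditions used throughout the
  tests).  Because the columns are iid, these sets are *harder* than real
  descriptor tables in one specific way: positions carry no marginal
  signature, so only a position-aware model can localize the signal.

The synthetic cohort used by the end-to-end pipeline cycles helix, hairpin
and coil backbones (30–60 residues) with fluctuation noise increasing from
helix (σ ≈ 0.25 Å) to coil (σ ≈ 0.9 Å), planting a learnable
structure-to-flexibility link of the kind the real data exhibits.

## Problem sizes

The test suite and the acceptance script run the method at reduced but
honest sizes chosen to exercise every code path with tight oracles:
enumeration oracles at N ≤ 12 residues where brute force is exact and fast,
Monte-Carlo projection oracles at 10⁵ directions, RMSF recovery at 100
residues × 2,000 frames, the learning protocols at n = 1,000 samples, and
the pipeline at 60 synthetic chains.

## Known limitations

* Chains with flagged breaks are still treated as a single polygonal curve
  (the Gauss-integral formalism needs one connected curve); fragmented
  chains should be filtered by the caller using the break flags.
* Descriptors are global: there are no windowed or per-residue profiles,
  and no closed-curve (knot) invariants.
* The published study-scale metric values depend on the full trajectory
  database and are not reproduced here; the validation rests on exact
  oracles and planted-signal recovery at synthetic scale.
* The SVM baseline is not differentiable: no attention weights, no
  Integrated Gradients.
* Binary trajectory formats (XTC/DCD) are not read; ensembles are
  exchanged as multi-model PDB.
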