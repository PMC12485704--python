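# gaussflex

Gauss-integral backbone descriptors and protein flexibility prediction.

Protein flexibility — how much a chain fluctuates around its native
structure — is usually measured as the per-residue RMSF of the C-alpha
atoms over a molecular-dynamics trajectory, which is expensive to compute
at scale.  `gaussflex` is for structural bioinformaticians who want that
dynamic signal from static structures alone: it encodes a chain's C-alpha
trace as a 30-component vector of generalized Gauss integrals and trains
compact neural models to predict whether the chain is flexible (RMSF above
the dataset mean) or to regress its RMSF value directly.

## The descriptors

A C-alpha trace is an open polygonal curve.  For two nonadjacent segments
the mutual Gauss integral W(i, j) is computed in closed form (signed area
of the spherical quadrilateral of end-to-end directions, divided by 2π);
|W(i, j)| is the probability the segments cross in a random planar
projection and the sign is the crossing handedness.  Generalized Gauss
integrals sum products of W entries over chord diagrams:

* order 1 — writhe `I(1,2) = Σ_{i<j} W[i,j]` and the average crossing
  number `I|1,2| = Σ_{i<j} |W[i,j]|`;
* order 2 — the three matchings of four slots, `(1,2)(3,4)`, `(1,3)(2,4)`,
  `(1,4)(2,3)`, each in four absolute-value variants;
* order 3 — the fifteen matchings of six slots.

With chain length N this gives the fixed 30-component descriptor.  The
engine evaluates orders 1–2 in O(n²) and order 3 in O(n³) via prefix-sum
elimination (all 30 descriptors of a 500-segment chain in under a second),
and is validated against brute-force enumeration and Monte-Carlo
projection oracles.

## The models

The primary model is a 1-D CNN with additive attention: four convolution
blocks (kernel 3, padding 1) map the length-30 single-channel input to 128
channels per position, attention weights the 30 positions, and a dense
layer maps the pooled 128-vector to a sigmoid probability (classification)
or a real value (regression).  Baselines: the same CNN with mean pooling, a
GRU reading the 30 components as a sequence, and an RBF-kernel SVM.
Training follows a fixed protocol — stratified 80/20 holdout, stratified
5-fold cross-validation with Adam (lr 1e−3, weight decay 1e−4, batch 32,
max 50 epochs, patience 7), best-fold retraining on the full pool, one
evaluation on the untouched holdout — and the evaluation suite reports
ROC/AUC with a bootstrap CI, average precision, max F1, the Youden
threshold, a calibrated confusion matrix, regression statistics, and
Integrated Gradients attributions over the 30 components.

## Worked example

```python
from gaussflex import (BackboneParams, make_backbone, compute_gi_vector,
                       acn_projection_estimate)

helix = make_backbone(BackboneParams(kind="helix", n_residues=40))
vec = compute_gi_vector(helix)
for name, val in list(zip(vec.names, vec.values))[:6]:
    print(f"{name:16s} {val:10.4f}")
```

prints

```
N                   40.0000
I(1,2)               4.9726
I|1,2|               9.3597
I(1,2)(3,4)         10.2989
I|1,2|(3,4)         18.1312
I(1,2)|3,4|         18.1312
```

The ideal right-handed 40-residue helix has writhe +4.97 — positive
because the helix is right-handed (the left-handed mirror gives −4.97) —
and an average crossing number of 9.36: projected along a random
direction, the curve shows about nine self-crossings on average.  The
Monte-Carlo estimator agrees:

```python
acn_projection_estimate(helix, 20000, seed=0)   # -> 9.2318
```

The same API scales to real structures:

```sh
gaussflex gi --in structures/ --chain all --out gi.tsv
gaussflex rmsf --traj run_rep1.pdb --traj run_rep2.pdb --out rmsf.tsv
gaussflex pca --gi gi.tsv --k 2 --clusters 4 --seed 17 --out pca.tsv
gaussflex train --gi gi.tsv --labels labels.tsv --arch cnn_attention \
    --task classify --out-model model.ckpt --out-report report.json
gaussflex pipeline --n-synthetic 60 --seed 1 --out run/   # fully synthetic demo
```

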