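# Methods

## Model

The classifier is a four-layer feed-forward network over standardized
expression: gene layer (input, *m* genes), pathway layer (*n* named
pathway nodes), one hidden layer (*h* nodes, default 100), and a
*K*-class softmax output (*K* = 2 for long- vs short-term survival).
Each connection layer computes `h_next = a((W ⋆ M) h + b)` with a
binary mask `M` congruent to `W`; sigmoids at the pathway and hidden
layers, softmax at the output (max-subtracted for stability).  The
gene→pathway mask `M(0)` equals the pathway biadjacency matrix `A` at
all times — it is the model's biological prior and is never modified by
training or sparse coding.  The hidden layer exists to capture
interactions *between* pathways; a single hidden layer is used
deliberately to keep the readout interpretable.

### Pathway filtering

Gene sets are read from GMT files.  Each pathway is intersected with
the measured genes first; pathways with fewer than `min_pathway_size`
(default 10) *measured* genes are dropped, then genes in no retained
pathway are dropped.  The size threshold is applied to the intersection
because only measured member genes can carry signal into the pathway
node; a pathway nominally large but mostly unmeasured is effectively
small.  One pass reaches a fixpoint: removing orphan genes cannot
shrink a retained pathway's measured-gene count.  Gene symbols match by
exact, case-sensitive string equality; no alias harmonization is
attempted.  Orderings (GMT line order, expression-header order) are
preserved so mask indexing is deterministic.

### Labelling and standardization

Samples surviving at least `cutoff_months` (default 24) are the
positive long-survival class regardless of vital status; deceased below
the cutoff are negative; alive below the cutoff are censored and
excluded.  Survival exactly at the cutoff counts as long-term — the
boundary belongs to the ≥ side by declared convention.  Expression is
z-scored per gene with *training-fold* mean and population standard
deviation (ddof = 0, fixed for bit-reproducibility); the same training
statistics scale the test fold, so test samples can never leak into
scaling.  A zero-variance training gene maps to exactly 0 rather than
being dropped, keeping gene columns aligned with `A` across folds.

## Training

### Cost

The mean-false-error (MFE) objective partitions cross-entropy by class:
`L = Σ_k C_k + (λ/2)·Σ w²` with `C_k` the mean cross-entropy over class
*k* and the penalty running over *active* (unmasked) weights only —
masked weights are non-parameters by construction.  The `(λ/2)‖W‖²`
squared form is used because the multiplicative `(1 − ηλ)` decay of the
plain-gradient update rule is its exact derivative.  With equal class
sizes the MFE data term equals K times the pooled mean cross-entropy;
with imbalance it up-weights each minority sample by the class-size
ratio, which is the point.  Posterior probabilities are clamped at
1e−12 inside the log so the cost is never NaN.

A `loss="pooled"` switch trains the identical architecture with plain
pooled cross-entropy; it exists so the cost-sensitivity benefit is
measurable rather than assumed.

### Epoch loop

Per epoch: (1) draw a dropout sub-network — independent Bernoulli keep
indicators per pathway node (drop rate 0.8) and hidden node (0.7),
redrawn if a layer loses every node; inverted-dropout scaling (kept
activations divided by the keep probability) so prediction needs no
rescaling; (2) one full-batch optimizer step on the sub-network's
parameters only (gradients are exactly zero at masked connections and
dropped nodes; Adam moments are likewise touched only inside the
sub-network, with a global timestep for bias correction); (3) re-derive
the sparsity masks of the pathway→hidden and hidden→output layers.
Full-batch steps are natural at cohort scale (hundreds of samples) and
make runs bit-reproducible.  Early stopping monitors the dropout-free
training loss with a patience counter (defaults: 5000 max epochs,
patience 100).

Two update rules are available: `adam` (default; L2 as an additive λW
gradient term, β = (0.9, 0.999), ε = 1e−8) and `sgd_decay` (plain
gradient step with multiplicative `(1 − ηλ)` decay).  Both appear in
the method's standard description; exposing both keeps the plain rule
testable while Adam is what the experiments use.

Default η = 1e−4 and λ = 3e−4 are PASNet's published values for real
tumour cohorts.  The synthetic experiments in the test suite and
acceptance script use η = 1e−2: the method's hyper-parameters are tuned
per dataset (originally by random search per cohort), and at desk-scale
epoch budgets 1e−4 moves the weights far too little to converge on the
simulated cohorts.

### Initialization

Weights are standard-normal draws scaled by 1/√fan-in (a pathway
node's fan-in is its member-gene count; hidden and output nodes use the
previous layer's width); biases are standard normal; gene→pathway
weights are exactly zero where `A` is zero, and the upper layers start
fully connected.  Unscaled unit-variance draws were tried first and
rejected: they saturate the sigmoids, producing confidently random
posteriors whose cost *exceeds* that of any constant-posterior
classifier — at which point the sparsity search correctly concludes
that dropping every connection minimizes the loss, severs the network,
and leaves no gradient path to recover (see next section).  The scaled
form keeps initial pre-activations at unit scale and initial posteriors
near uniform.

### Sparse coding

At level *S* a layer's mask keeps entries with |w| ≥ *Q*, where *Q* is
the *S*-th percentile of |W| under the sorted linear-interpolation
convention (the 50th percentile of four values is the midpoint of the
middle pair).  Ties at *Q* are kept (the literal ≥).  *S* = 0 yields a
fully connected layer; *S* = 100 is an explicit all-zeros override —
the literal formula would always keep the maximal entry.  Masks are
pure functions of the current |W| and *S*: rebuilding is idempotent and
kept-sets nest monotonically in *S*.

The per-layer optimum *S\** minimizes a cubic spline fitted through the
costs of a small grid of levels (default {0, 20, 40, 60, 80, 100};
quadratic/linear fallback below four points), evaluated densely at 0.5
resolution over the grid range; exact ties break toward the largest
(sparsest) level, interpretability being the goal.  The search cost is
the *data* term of the training loss of the current sub-network with
the candidate mask in place, forward passes only.  The L2 penalty is
deliberately excluded from the search: it shrinks mechanically as
connections are dropped and would bias every search toward sparsity
regardless of fit.  Layer-1 searches reuse the epoch's pathway
activations (they do not depend on upper-layer masks), which makes the
per-epoch search cost negligible.

Sparse coding engages only once the dropout-free training data cost is
below the best constant-posterior cost (K·ln K for the MFE term; the
label entropy for pooled).  Above that floor, "connections that do not
contribute to minimizing the loss" is ill-defined — dropping *all*
connections also attains the floor, so the search degenerates to
*S\** = 100 on an essentially flat curve and permanently severs the
network.  While gated, the upper layers stay fully connected, exactly
as at initialization; this also undoes a severing *S\** picked on a
flat curve in a borderline epoch.  Training loss crosses the floor
within tens of epochs on the synthetic cohorts, after which the search
runs every epoch as intended.

## Evaluation protocol

Repeated stratified k-fold CV (defaults k = 5, 10 repeats, fresh fold
seed per repeat).  Folds are built by shuffling within each class and
dealing round-robin, so per-class fold counts differ by at most one.
Standardization is recomputed inside every fold from its training
samples only.  Test samples are scored by the positive-class posterior;
AUC comes from the ROC sweep (trapezoidal area, equal to the
Mann–Whitney pair statistic with half-credit for ties) and F1 for the
positive class at a 0.5 posterior threshold (the canonical softmax
decision; configurable).  F1 degenerates to 0, not NaN, when PPV + TPR
is zero.

Paired model comparison uses a two-sided Wilcoxon signed-rank test over
per-(repeat, fold) AUC pairs.  Zero differences are discarded and |d|
ranks tie-averaged; the p-value is exact for up to 25 nonzero pairs —
the full distribution of the rank sum is built by convolution over
doubled ranks, which stay integral under tie-averaging — and a normal
approximation with tie and continuity corrections beyond that.  The
exact branch is hand-built because standard exact routines refuse tied
ranks.

## Interpretation

All readouts come from a dropout-free forward pass.  Node values
(sigmoid/softmax outputs) lie in (0,1); output-node group means are
also reported as −log2 (ε-guarded) to spread the scale near zero.
Pathway importance is the column sum of |W(1) ⋆ M(1)| — the aggregate
absolute masked weight from a pathway node into the hidden layer — with
`max` as a configurable alternative; the aggregation across hidden
nodes is a declared convention, ties break by pathway name.  Genes rank
by |masked gene→pathway weight| within their pathway; genes outside a
pathway cannot appear because `A` forces their weight to zero.
Group-mean activations summarize the *model's* response and are
reported as continuous values, never binarized into "active/inactive".

## Synthetic cohorts

The generator emulates the target regime: `n_samples` labelled samples
(default 300) by `n_genes` genes (400) grouped into `n_pathways` gene
sets (25 × 16, a full partition by default; an `overlap_fraction`
re-uses genes across pathways), i.i.d. Gaussian baseline expression,
and a gene-level mean shift of `effect_size` SD units (default 1.0)
planted in the member genes of `n_informative_pathways` (3) for the
minority class (default 20%, matching the ~20% long-survival fraction
of the motivating cohort; the imbalance experiments use 10%).  Survival
times are drawn so 24-month labelling reproduces the design exactly,
plus a 5% censored-alive tail to exercise exclusion.  Minority counts
are allocated deterministically (`round(n × fraction)`).

The generator does *not* emulate RNA-seq count distributions, gene–gene
correlation beyond the planted shifts, batch effects, or
hazard-model survival times; the planted effect is additive at the gene
level rather than through a latent pathway factor.  Passing tests
therefore demonstrate that the machinery recovers pathway-structured
mean shifts under class imbalance — not performance on real cohorts,
where effect sizes are far smaller and correlation structure matters.

## Problem sizes and budgets

The test suite and acceptance script run the signal-recovery design
(300 × 400, 25 pathways, 3 informative, δ = 1.0, 20% minority) with
400-epoch fits on 80/20 stratified splits over 5 seeds; the null design
(δ = 0) with 5-fold CV at 250 epochs over 5 seeds; and the 10%-minority
comparison over 10 seeds per loss.  These sizes were chosen so a full
run completes in minutes on one CPU while leaving the conclusions
seed-stable; gradient checks run on a 4-gene/2-pathway/2-hidden/2-output
toy where central finite differences are exact to ~1e−9.

## Known limitations

- Exact gene-symbol matching; real GMT + expression joins usually need
  alias mapping first.
- Full-batch training only; cohorts far beyond ~10⁴ samples would want
  mini-batching.
- The sparsity search scores candidates on training loss, consistent
  with the method's description; a held-out search set would be a
  defensible variant.
- Pathway importance ignores downstream (hidden→output) weight
  magnitudes; pathways feeding hidden nodes that the output layer
  ignores can rank high.
- `K > 2` outputs are supported by the network and cost but the
  evaluation protocol (AUC/F1) is binary.
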