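# Methods

## Model and objective

`wirenet` trains spatially embedded sparse recurrent classifiers under a
joint objective

    L = E(X, y; θ) + η · C_wiring,

where `E` is the cross-entropy task error and `C_wiring` is the physical
cost of the hidden layer's wiring. Hidden units sit at fixed positions
(by default on the unit circle; for bio-instantiated models at the
neuron coordinates of a connectome), and only the hidden-to-hidden
connections are sparse and carry geometry: the dense input and output
projections have no positions and no cost.

Two cost forms are provided:

- **volume** (default): `C = Σ_ij A_ij D_ij |w_ij|` — connection length
  times connection strength, summed over the active directed edges. It is
  absolutely homogeneous of degree one in both weights and distances, so
  the penalty scale depends on the layout's units; tests and experiments
  therefore fix the circle radius at 1.
- **normalized**: the mean of `|w| D` over active edges divided by
  `sqrt(mean |w|² over edges × mean D² over all n(n−1) ordered pairs)`.
  This ratio is invariant under global positive rescaling of either the
  weights or the coordinates. (The printed form of this ratio in our
  source material is typographically garbled; the implementation uses
  the only reading consistent with the stated symbols and with the word
  "normalized", namely the scale-invariant ratio above.)

## Recurrent cells

Four cells share a single architecture (dense input projection, one
sparse recurrent hidden layer, dense readout, `h_0 = 0`):

- **RNN**: `h_t = ReLU(U x_t + W h_{t−1} + b)`.
- **CT-RNN**: `dh/dt = −h/τ + tanh(U x_t + W h + b)`, integrated with
  classical fixed-step RK4 (default `dt = 0.1`, `τ = 1`, one unit of
  model time per observation).
- **Neural ODE**: the same without the leak term.
- **GRU**: standard reset/update-gate equations.

The sparsity mask is binary over hidden-to-hidden connections and is
applied inside the forward graph (weights are multiplied by the mask),
so masked-out positions receive exactly zero gradient; after every
parameter update the storage is re-masked as well. For the GRU one mask
is shared by all three recurrent matrices (U_R, U_Q, U_S): a connection
i→j exists or not as a unit. Per-gate masks would triple the effective
edge count and break the one-to-one mapping between mask entries and
connectome edges.

Where a single per-connection weight is needed — the wiring cost, SET's
magnitude ranking, DeepR's sign constraint — the GRU uses its
candidate-state matrix U_Q as the designated weight. The candidate
matrix is the one that carries new content into the hidden state, making
it the closest analogue of a synaptic efficacy; the gate matrices are
trained normally and simply follow the shared mask.

Because no automatic-differentiation framework is part of the
dependency set, gradients come from a small reverse-mode tape
(`wirenet._autograd`) over numpy arrays. It supports exactly the
operations the cells need and is validated against central finite
differences in the test suite.

## Optimization and the cost penalty

The default optimizer is stochastic gradient descent with classical
momentum (lr 0.2, momentum 0.9, batch 16). The choice is deliberate: the
wiring-cost gradient `η A_ij D_ij sign(w_ij)` is proportional to the
distance a connection spans, and that proportionality is the entire
mechanism by which long connections are weakened faster than short
ones. An adaptive per-parameter method such as Adam normalizes each
coordinate's step by its own gradient magnitude and thereby erases the
distance selectivity (every weight under a near-constant pull moves at
the same speed regardless of D). Adam remains available via
`TrainConfig(optimizer="adam")` for the task term, but the volume
penalty is then still applied in decoupled form.

For SET and DSR training, the volume penalty is applied as the exact
proximal operator of `η Σ D |w|` after each gradient step:

    w ← sign(w) · max(|w| − lr · η · D, 0),

i.e. distance-proportional soft thresholding. This drives the weights of
unhelpful long connections to exactly zero, which the magnitude-based
pruning rules then remove. For DeepR the cost gradient is added to the
task gradient inside its own update (which is already a plain SGD step
by definition). The normalized cost form uses its analytic gradient
instead of a proximal step.

Checkpointing keeps the parameters of the epoch with the highest
validation accuracy; among tied maxima the latest epoch wins, so once
validation accuracy saturates the saved model reflects the matured
topology rather than the first epoch that happened to reach the
plateau.

## Dynamic sparse rewiring

All three strategies conserve the number of active connections exactly
(asserted every epoch):

- **SET** (end of each epoch): the fraction ζ of smallest-magnitude
  non-negative and of smallest-magnitude negative connections is pruned
  (ties broken by index for determinism); the same number of connections
  is regrown at inactive positions with weight 0.
- **DeepR** (every gradient step): each active connection holds a fixed
  sign s; the update is `w − α ∇E − α ξ s + sqrt(2 α T) ν` with standard
  normal ν. A connection whose weight crosses zero against its sign is
  deactivated and replaced by a newly activated connection with weight
  `s' ε`, `ε = 1e−12`, `s'` a fresh random sign. α is tied to the
  optimizer's learning rate.
- **DSR** (end of each epoch): global magnitude pruning at threshold H
  (default 0.001); H is halved when the pruned count exceeds (1+δ)K and
  doubled when it falls below (1−δ)K (δ = 0.1, K configurable); the
  regrowth budget is allocated across layers proportionally to surviving
  counts with largest-remainder rounding.

Regrowth sites are sampled without replacement among inactive positions,
with probability proportional to 1/D when distance bias is on (the
default); zero-distance pairs are excluded from biased sampling.

## Topology and specialization analysis

Trained masks are symmetrized into simple undirected graphs (an edge
{i, j} exists if either direction is active). Modularity Q uses the
Newman definition on the binary adjacency; the average clustering
coefficient counts nodes of degree ≤ 1 as 0 and averages over all
nodes. Partitions come from seeded Louvain with 20 restarts, keeping
the best-Q result, which makes the partition deterministic given
(seed, restarts).

Lesioning a module zeroes all of its units' recurrent, input, and output
projections (shapes preserved, no retraining). Per-subtask accuracy is
per-class recall; `acc(i, β)` is the relative change
`(lesioned − full)/full`. Task variance (per module, across subtasks)
and module variance (per subtask, across modules) are population
(divisor-N) variances, matching their definition as plain averages of
squared deviations; the reported condition averages are means of the
corresponding standard deviations. Lesion evaluations use the full
pooled dataset rather than the small test split: with 700 sequences the
per-class recall resolution is 1%, which the variance statistics need.

Connection-length distributions are compared with the two-sample
Kolmogorov–Smirnov distance; each directed connection contributes one
value (a deduplicated option exists), and distances are normalized by
the longest observed separation. The position-randomized baseline keeps
the graph and weights fixed and permutes unit coordinates.

## Synthetic task generator

The generator emulates small wearable-sensor / gesture-phase
classification data: 7 classes, 7 features, 32 time steps, features
scaled to [0, 1], splits 0.75/0.15/0.1 (stratified). Each class owns a
stable random linear recurrence (spectral radius 0.85) driven by a
class-specific input; class drives lie along a random orthonormal frame
scaled by 2.3, so between-class separation is identical across seeds.
Within-class variability has two parts:

- `drive_jitter` (default 0.35): a per-sequence perturbation of the
  drive, shifting the whole trajectory coherently — the analogue of
  execution variability between repetitions of the same activity.
  Independent frame noise cannot play this role because temporal
  integration averages it away.
- `noise_sd` (default 0.05): i.i.d. Gaussian frame noise (sensor noise).

The drive scale is calibrated so that a logistic regression on the
final frame alone exceeds 90% test accuracy at `noise_sd ≤ 0.1` — the
generator's learnability guarantee, verified in the tests — while
leaving enough class overlap that a trained network's margins are not
unbounded. What the generator does **not** emulate: heterogeneous
subtask structure (all classes are fixed-point discriminations of the
same kind), sensor-ID coding, label noise, class imbalance, and
long-range temporal dependencies. Passing results on this task
demonstrate the mechanics of cost-controlled training, not performance
on real recordings.

## Desk-scale reference experiments

`wirenet.experiments` fixes the problem sizes used by the tests and by
`scripts/acceptance.py`; they are chosen so the full set runs in
minutes on one CPU core:

- **Penalty sweep**: 64-unit GRU, 10% recurrent density, SET, η ∈
  {0, 1e−4, 1e−3, 1e−2}, 5 seeds, 30 epochs, 100 sequences per class.
  The best non-zero η is the one with the highest mean test accuracy,
  ties resolved toward the larger penalty (at equal accuracy the more
  economical network is preferred).
- **Lesion comparison**: 131 hidden units with a budget of 1,500
  connections (the configuration whose wiring diagrams motivated the
  module analysis), η = 1e−3 vs 0, 5 seeds each.
- **Connectome match**: an 80-neuron, 640-edge synthetic connectome
  with distance-dependent connectivity (edge probability ∝
  exp(−D/0.1), positions uniform in the unit cube) stands in for a real
  neural map so that nothing needs downloading; the short decay scale
  mirrors the strong short-range bias of real neural maps.
  Bio-instantiated GRUs start from its exact edge set and coordinates
  and are trained with DeepR at η = 1e−2 vs 0. DeepR's L1 coefficient is
  raised to ξ = 5e−3 here so that the η = 0 baseline reaches its
  rewiring equilibrium within the 30-epoch budget — with negligible ξ
  the baseline's mask stays largely identical to its initialization
  (the reference itself), and its distance distribution would measure
  the initialization, not the training regime.
- **Density bound**: the 131-unit model at a 10% connection budget,
  tracked across rewiring epochs (conservation makes the density
  constant by construction; the experiment verifies it end to end).

Real connectome files (neurons.csv with id/x/y/z/role, edges.csv with
pre/post/n_synapses) are supported by `wirenet.bio_connectome` and the
`wirenet bio-compare` command; the loaders are format-documented rather
than version-pinned, and the test suite exercises them on toy and
synthetic fixtures only.

## Numerical choices and edge cases

- The subgradient of |w| at 0 is taken as 0; proximal shrinkage clips at
  exactly 0 rather than crossing.
- SET tie-breaks in the magnitude ranking use (|w|, i, j) lexicographic
  order, making a rewiring step bit-reproducible given (seed, config).
- Optimizer moment buffers are zeroed at positions whose mask changed,
  so pruned entries carry no stale momentum into their next activation.
- Degenerate inputs raise: empty distance samples, all-zero samples in
  max-normalization, single-unit or zero-weight nets in the normalized
  cost, empty graphs in modularity/Louvain, lesions that would remove
  every unit, subtasks with zero baseline accuracy (excluded with a
  warning).
- Divergent (non-finite) training losses abort with a diagnostic rather
  than continuing.

## Known limitations

- The CT-RNN and Neural ODE cells train through fixed-step RK4; no
  adaptive solvers or adjoint gradients are provided, and the step size
  trades accuracy for time linearly.
- DSR's cross-layer reallocation is implemented and tested on lists of
  sparse layers, but the recurrent models expose a single sparse layer,
  so the multi-layer path is exercised synthetically.
- The qualitative directions (topology gains, specialization,
  geometry match) are statements about majorities over 5 seeds at desk
  scale; they are noisy at the level of individual seeds.
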