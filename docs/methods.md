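# Methods

This note documents the models implemented in `fgcn`, the choices made
where the design was genuinely open, and what the synthetic experiments
do and do not demonstrate.

## Channel graphs

All three graphs are N x N matrices over a fixed electrode set, with unit
diagonal (full self-connection) by convention.

**Topological.** `A^T_ij = exp(-dist(i,j)^2 / (2 theta^2))` with
`dist` the planar Euclidean distance between electrodes. The width
`theta` (same unit as the coordinates) controls the radial range of
action; its default is the *median pairwise electrode distance*, which
makes the graph invariant to the montage's length unit and gives a
mid-range kernel on any cap. The packaged 62-channel table is a
10-20-style planar projection consistent with an 8 x 9 grid packing
(prefrontal and anterior-frontal electrodes share the top row, the
cerebellar pair flanks the occipital row); users can substitute any CSV
of `name, x, y` coordinates.

**Functional.** Pearson correlation of the two channels' samples over a
trial (or a sample window). Negative correlations are retained — no
absolute value is taken — because the downstream row normalization maps
each row's range onto [0, 1/2] anyway, and sign information would
otherwise be discarded twice. A constant channel has no correlation and
raises an error naming the channel.

**Causal.** The Granger-causality log variance ratio from nested
ordinary-least-squares autoregressions:

    GC_{i<-j} = ln( var(resid of x_i on own lags 1..p)
                  / var(resid of x_i on own lags + lags of x_j) ).

Both fits include an intercept and use the same observation window, so
in-sample nesting guarantees `GC >= 0`, and the matrix is genuinely
directed. The VAR order defaults to `p = 1` and is configurable; no
automatic order selection is performed, keeping the estimator
deterministic. No F-test or significance screening is applied — raw GC
magnitudes are used as edge weights. Implementation note: all ordered
pairs share one Gram matrix of the lagged design, so each pair reduces to
two small normal-equation solves; the tests verify this path against
per-pair `lstsq` fits and against `statsmodels`' likelihood-ratio
statistic (`lrtest / nobs`).

The harness estimates functional and causal graphs per training trial and
averages the matrices across trials; the window default is the whole
trial. Graphs are estimated **from training trials only** — the
evaluation reports record the trial indices used so the absence of test
leakage is auditable.

## Normalization, thresholding, fusion

Because the three matrices live on incommensurate scales, each row i's
off-diagonal entries are min-max rescaled onto `[0, 1/2]` and the diagonal
is pinned at `1/2` (self-similarity is half the total weight ceiling). A
row with constant off-diagonal entries has no scale; it is set to zero
with a logged warning. The map is idempotent on its own output.

A hard threshold then sparsifies each matrix: entries strictly below the
threshold are zeroed, the diagonal untouched. The rule and value are
configurable; the default keeps the top half of each matrix's
off-diagonal entries (`percentile, 50`), which is scale-free across graph
kinds. Thresholding is applied *after* normalization.

Fusion strategies (inputs in the fixed order topological, causal,
functional):

* **add** (default): entrywise sum. Diagonal of the fused graph is
  `M/2` for M inputs; strong-everywhere edges dominate (monotone).
* **product**: entrywise product; an edge absent from any one view
  vanishes.
* **kronecker_product / kronecker_addition**: the Kronecker product (or
  Kronecker sum `A (x) I + I (x) B`) of two N x N matrices is N^2 x N^2
  and not usable as an N-node adjacency; after each pairwise step every
  N x N block is mean-pooled back to N x N before the next matrix is
  folded in. This reduction is this package's interpretation — for the
  product it collapses to `A * mean(B)`, which the tests verify against a
  literal `np.kron` + block-pooling oracle.
* **cross_diffusion**: similarity-network-fusion style. Each input
  yields a dense row-stochastic status kernel `P_m` and a sparse
  row-stochastic k-nearest-neighbour kernel `S_m` (each row keeps its
  diagonal plus its k largest off-diagonal entries); the update
  `P_m <- S_m . mean_{m'!=m}(P_{m'}) . S_m^T` runs for a fixed number of
  iterations (defaults k = 10, T = 20) and the fused graph is the mean of
  the final statuses.

The causal graph's asymmetry survives fusion; symmetrization is deferred
to the spectral operator, which requires it.

## Spectral classifier

The fused adjacency is symmetrized as `(H + H^T)/2` (preserving total
edge weight), degrees `D` are formed, and the normalized Laplacian
`R = I - D^{-1/2} H D^{-1/2}` (spectrum in [0, 2]) is rescaled to
`R' = R / lambda_max - I` so its spectrum lies in [-1, 1], the Chebyshev
domain. `lambda_max` is computed with a dense symmetric eigensolver for
N <= 128 and by power iteration (tolerance 1e-8) above that; when the
Laplacian is (near-)zero — a pure identity adjacency — `lambda_max` falls
back to 2, the top of the normalized-Laplacian range, giving `R' = -I`.
An isolated (zero-degree) node is an error naming the channel.

The filter `sum_i theta_i T_i(R') X` uses the three-term recurrence
`T_0 = I, T_1 = R', T_i = 2 R' T_{i-1} - T_{i-2}` and is exactly equal to
filtering with the polynomial evaluated on the eigenvalues; the tests
hold this to 1e-6 (observed ~1e-14) against a dense eigendecomposition.

Architecture (defaults; all configurable): one Chebyshev graph-convolution
layer (k = 3, 16 output maps, ReLU), one depthwise-separable block — a
length-3 depthwise filter along the node axis per feature map, then 1 x 1
pointwise mixing to 16 maps, ReLU — and a dense softmax layer. An
alternative depthwise layout on the 8 x 9 electrode grid (3 x 3 filter,
channels scattered to their grid cells) is available via
`depthwise_layout="grid"`; it is not the default because the node-axis
form needs no montage and behaved equivalently here. The loss is the mean
cross-entropy over samples (the sum only rescales the gradient); zero
predicted probability at a true label is clamped at 1e-12 and logged.

No deep-learning framework is a dependency: forward and backward passes
are explicit NumPy, optimized with Adam (lr 1e-3, beta 0.9/0.999), 100
epochs, batch size 32, Glorot-uniform initialization from a seeded
generator. Given `random_state` and fixed BLAS threading, training is
bit-deterministic, which the reproducibility checks rely on. Features are
standardized per (channel, band) with training-set statistics.
Classification is per 1-second feature segment; no trial-level voting.

## Synthetic data

The generator emulates the *layout* of SEED-style emotion datasets, not
their physiology. Per class, a sparse set of directed lag-1 couplings
(default 15 edges at strength 0.7, self-regression 0.5) is drawn
acyclically under a class-specific node ordering — so the VAR is
stationary by construction (eigenvalues equal the self-coefficient) —
and trials are simulated with unit Gaussian innovations at 200 Hz for
10 s, after a 200-sample burn-in. Classes therefore differ in their true
causal and functional graphs, and the generator emits the ground-truth
edge lists so graph-recovery metrics are computable.

DE features follow the Gaussian band-power closed form: per 1-second
window, channel and band, the periodogram power integrated over the band
gives `sigma^2_band` and the feature is `0.5 ln(2 pi e sigma^2_band)`.
Band defaults: delta 1-4, theta 4-8, alpha 8-14, beta 14-31, gamma
31-50 Hz. A class-dependent mean shift (default 1.0 nat, the "strong
class effect") is added to the beta/gamma DE of each class's *driven*
channels, tying the discriminative signal to the coupling structure and
placing it in the bands reported most emotion-informative. DASM-style
hemispheric-difference features are provided secondarily.

Trials are ordered class-interleaved and split first-fraction/
last-fraction (default 0.6: first 9 of 15 trials train, last 6 test for
the 3-class default; a 0.625 fraction reproduces a 15/9 split for
4-class studies). The generator requires only that both split sides
contain every class, so small test configurations are possible.

**What passing tests show, and what they do not.** The synthetic signals
are linear, Gaussian, stationary and artifact-free; volume conduction,
non-stationarity, inter-subject variability of montage fit, and the
nonlinear dynamics of real EEG are absent. Results here demonstrate the
*mechanics* — that the estimators recover planted structure, that fusion
preserves it, that the classifier exploits it, and that no mode is ever
hurt by the fused graph — not that any accuracy level transfers to real
recordings. Under the default strong class effect all adjacency modes
saturate near 100% on held-out windows; the null configuration
(`chance_level_spec`) drops all of them to chance, and the class-effect
knob interpolates monotonically between the two regimes.

## Evaluation protocol and problem sizes

Per subject: graphs from training trials, training on the train split's
features, accuracy on the held-out trials; reported numbers are the mean
and standard deviation (population, ddof = 0) over subjects. Ablations
reuse the same generated subjects, graph estimates and partitions across
rows, so rows differ only in the ablated factor; partition hashes are
recorded to make this auditable. The default study size — 15 subjects,
3 classes x 5 trials, 62 channels, 10 s trials — keeps a full
five-mode-by-three-seed ablation around ten minutes on one CPU while
leaving the per-subject sample counts (90 training / 60 test windows)
representative of per-second feature classification.

## Known limitations

* The Kronecker fusion variants depend on the block-pooling reduction
  described above; other reductions would give different numbers.
* GC edge weights are in-sample statistics without significance
  screening; on short windows they are biased upward (approximately
  p/n under the null).
* The montage is a planar projection; 3-D scalp geometry is not used.
* Training is plain full-batch-shuffled Adam with a fixed epoch count;
  no early stopping or hyperparameter search is included.
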