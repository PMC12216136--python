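# Methods

This note records the models implemented in `swarmdx`, the parameters that
matter, the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Synthetic cohort generator

`synthdata.generate_hd_like` emulates the *shape* of the classic 303-patient
heart-disease table: 13 predictors named age, sex, cp, trestbps, chol, fbs,
restecg, thalach, exang, oldpeak, slope, ca, thal; binary presence/absence
label (`num`), 165/138 by default. Categorical predictors are drawn as
uniform integer codes over their small clinical level sets (sex ∈ {0,1},
cp ∈ {0..3}, …) and treated as numeric downstream, mirroring how the named
dataset encodes them; continuous predictors are Gaussians on rough clinical
scales (age ≈ N(54, 9²), chol ≈ N(246, 51²), …) so that z-scoring is doing
real work.

Labels follow a planted logistic model: a score
s = Σ_k w_k · z(x_{·,k}) + ε, with the informative set k defaulting to
{age, cp, thalach, oldpeak}, weights (3.0, −2.5, 2.0, 2.5), and
ε ~ N(0, 0.5²). The n_presence highest-scoring rows get the positive label
(ties broken by row index). Rank-thresholding rather than Bernoulli sampling
makes the class counts exact and every fixture bit-reproducible; the cost is
that labels are not conditionally independent given features — acceptable
for fixtures whose purpose is a known ground truth.

Weights and noise were chosen once to make the planted signal strong but not
trivial: the noise SD (0.5) is about one tenth of the score's spread, so a
few percent of rows near the ranking threshold are genuinely ambiguous, and
the four features carry clearly unequal importance. The generator does *not*
emulate the real data's marginal distributions, inter-feature correlations,
or missingness, so passing results here demonstrate algorithmic correctness
and recoverability of a planted signal — not clinical performance.

`generate_sequences` provides two-class Gaussian sequence fixtures (class
mean shift = `separation`) for unit-testing the recurrent classifier, and
`benchmark_suite` exposes sphere / Rosenbrock / Rastrigin with their known
minima as optimizer oracles.

## Z-score preprocessing

x_new = (x − μ)/σ per column. Sample SD (divisor n−1) is the default — the
choice is exposed (`ddof`) because nothing in the problem fixes it. Stats
are fit on the training split only and applied to validation/test, keeping
the evaluation leakage-free. A zero-variance column raises an error naming
the column rather than silently dividing by zero.

## Spotted-hyena optimizer and feature selection

Continuous minimization on a box. Per iteration, with control value
l = 5 − Iter·(5/Max_iter) (linear decay 5 → 0):

* one scalar G ~ U(0.5, 1) defines the attack cluster: members whose fitness
  is within G·|f_best| of the best-so-far value (at least the current
  argmin). The source formulation of the cluster count is not operational;
  this fitness-neighborhood reading is isolated in one function.
* each cluster member draws Y = 2r₁, Z = 2lr₂ − l (vectors) and encircles a
  reference point: new = ref − Z∘|Y∘ref − pos|, clamped to the box. Members
  with mean |Z| > 1 explore by referencing a uniformly random point instead
  of the best-so-far ("Z higher or lesser than one" operationalized for a
  vector Z).
* non-cluster members jump to the centroid of the updated cluster.
* the best-so-far solution is tracked outside the population (elitism), so
  the best-value trace is monotone non-increasing.

Adaptive stopping: quit after `patience` consecutive iterations whose
best-value improvement is below `epsilon` (default 1e-10). The patience is
*opt-in* (default None): because the linear 5 → 0 schedule makes progress
end-loaded — the wide early coefficients throw proposals against the box
and the incumbent typically does not improve until l falls below ~1 — any
patience small relative to `max_iter` would stop the run before
exploitation begins, which is exactly the premature termination the
criterion is meant to avoid. When a caller sets a patience, the rule
behaves as stated (a constant objective stops after exactly `patience`
stalled iterations).

Feature selection wraps this optimizer: positions in [−4, 4]^d are
binarized per evaluation by a stochastic sigmoid transfer
(bit_j = 1 iff σ(x_j) > u_j, all-zero masks repaired to the single best
bit), and masks are scored by

Fitness(X) = α·E(X) + β·|R|/|N|,  α = 0.99, β = 0.01 (α + β = 1),

minimized: E(X) is the wrapper classification error, |R| the mask size, |N|
the number of candidates. The historical form of the size term, 1 − |R|/|N|,
*rewards* larger subsets under minimization; it is retained behind
`as_printed` but the parsimony form is the default. The label column is
never a candidate.

E(X) is the repeated (3×) stratified 5-fold CV error of a 5-nearest-neighbor
classifier on the masked columns. k-NN is the standard cheap wrapper
learner; the estimator is pluggable. Repetition matters: single-split fold
noise (±0.03 error at n ≈ 180) can rank an inferior subset above the planted
one and send the search to a suboptimal basin; averaging three fold
assignments restores a stable ranking at 3× cost. Mask evaluations are
memoized.

## Attention BiGRU classifier

A tabular row of d selected features is read as a d-step sequence of scalars
(feature j at timestep j, in post-selection column order) — the only
recasting that lets a recurrent model consume a fixed-width table; it is
isolated behind `row_to_sequence`. Two GRU cells (standard reset/update
gating) process the sequence in opposite directions; their per-timestep
states are combined through shared learned weights W_f, W_b and a single
shared bias (per-timestep weights would fix the sequence length). Softmax
attention — scores e_t = v·tanh(W h_t + b), weights a = softmax(e),
numerically stabilized by max-subtraction — pools the states into one
context vector, and a dense ReLU layer plus two-way softmax produces class
probabilities (the head is this package's addition; the underlying
formulation stops at the context vector).

Training minimizes cross-entropy by mini-batch backpropagation through time,
implemented manually in numpy (float64). Gradient correctness is guarded by
a central-finite-difference check at step 1e-4 — the right step for this
loss in double precision; much smaller steps leave roundoff noise above the
1e-4 relative target on gradient entries of magnitude ~1e-7.

Defaults follow the reference configuration: learning rate 0.01, batch
size 5, dropout 0.5, 50 epochs, ReLU head. Dropout is applied to the
combined hidden states during training only (inverted scaling); where it
applies was unstated, and the combined states are the single bottleneck all
downstream computation shares. The update rule is Adam at the stated
learning rate, with plain SGD selectable: at the stated budget plain SGD
demonstrably stalls on these short scalar sequences (cross-entropy
0.693 → 0.677 over 50 epochs; predictions collapse to the majority class),
so a reported >97% accuracy under this configuration is only reachable with
an adaptive update rule. Initialization is seeded uniform scaled by fan-in;
biases start at zero. Inference is deterministic (no dropout), ties in the
probability pair go to the positive class.

## Modified coati optimizer and tuning

Plain COA runs two stages per iteration over an even population, every
proposal accepted only on strict improvement:

1. **Predation** — the first half moves toward the best solution,
   x + r(Xbest − I·x) with I ∈ {1, 2} per member; a random "iguana" point is
   dropped in the box and the second half moves toward it if it beats them,
   away otherwise.
2. **Escape** — every member jumps by (1 − 2r)(lb/t + r(ub/t − lb/t)) inside
   local bounds that shrink with the 1-based iteration t (t = 0 would divide
   by zero).

The modification adds a third stage, dynamic-opposite learning: member i is
paired with member i + pop/2 (mod pop) — the only symmetric reading of the
source's half-population indexing — and proposes
x + r₁(r₂(lb + ub − x^op) − x^op) with two fresh uniform vectors (the source
writes one symbol r_c twice; two draws mirror the underlying two-draw DOL
formulation). Opposition bounds are the global box, not the shrunken local
ones. The stage consumes its randomness strictly after the two phases, so
disabling it reproduces plain COA draw-for-draw — asserted bit-exactly in
the tests.

Hyperparameter tuning decodes optimizer positions in the unit cube into
learning rate (log scale over [1e-3, 1e-1]), hidden size ([4, 32], integer),
dropout ([0, 0.8]) and batch size ([2, 16], integer), centered on the
reference configuration. Fitness is 1 − P with validation precision
P = TP/(TP+FP) — the default tuning criterion — with accuracy selectable,
since the surrounding text names accuracy as the primary condition. A
candidate whose training diverges scores worst and the search continues.
Candidate training uses a reduced epoch budget (default 15) purely for
search cost; the final model is retrained at full budget. The search is
warm-started with the reference configuration encoded into the initial
population: greedy acceptance then guarantees the returned settings never
score below the baseline on the validation split.

## Pipeline

Stages, in order: ledger-commit of the input digest → stratified 60/20/20
split (invented here; no split protocol is inherited) → z-score fit on
train → SHO feature selection on train → MCOA tuning on train/val → final
training on train+val with tuned settings → macro report on test →
ledger-commit of the report digest. One global seed fans out to per-stage
seeds by SHA-256 of "seed:stage-name", so stages are individually
reproducible and the whole run is a pure function of (data, config, seed)
apart from timestamps. Test rows are touched exactly once.

Default budgets — FS population 24 × 100 iterations (~1400 mask
evaluations of the 2^13 candidates; smaller budgets measurably return
strictly worse-fitness masks under the stochastic binarization), tuning
population 6 × 4 iterations at 15 epochs per candidate, final training 200
epochs — were chosen as a desk-scale compromise: at the 50-epoch reference
budget the final classifier is visibly undertrained on the synthetic
cohort, and the reference evaluation itself extends training to the
500–3000-epoch range.
A full default run takes a few minutes on one CPU; the test suite and the
examples use reduced budgets where only structure (determinism, leakage,
error handling) is being exercised.

## Metrics

All metrics derive from one 2×2 tally. Reporting follows the per-class +
macro convention: each metric is computed with each class as positive and
the Average row is their unweighted mean. The per-class "accuracy" column is
that class's recall — the only reading consistent with the reference table's
class sizes and printed values — while overall accuracy (TP+TN)/total is
reported separately and unambiguously. Internal math is full precision;
percentages are rounded half-up to two decimals only at the reporting
boundary (pre-written at six decimals so a true decimal half survives binary
representation). Degenerate 0/0 ratios return 0 with a flag instead of
raising, so metaheuristic fitness loops never abort mid-search. MCC and
kappa are validated against brute-force enumeration and an independent
library implementation in the tests.

## Ledger

Single-writer hash chain: each block stores (index, timestamp, SHA-256 of
payload, previous hash) and its own SHA-256 over a canonical length-prefixed
serialization of those fields; the genesis block links to 64 zero digits.
Only digests enter the chain — raw patient rows stay in their external file,
keeping the ledger small and free of sensitive content by construction.
There is no consensus, networking or signature scheme: none is needed for a
desk-scale tamper-evidence guarantee, and inventing an unspecified signature
scheme was out of scope. Verification recomputes every hash and link and
reports the first inconsistent index; appends to an inconsistent chain are
refused.

## Known limitations

* The generator matches type and shape only; results on it bound nothing
  about real clinical data (no correlations, no missingness, rank-coupled
  labels).
* The recurrent classifier processes features positionally; it is a faithful
  realization of the stated architecture, not the strongest model for i.i.d.
  tabular data (a linear model on the planted features would be hard to
  beat).
* The wrapper fitness uses k-NN error as a proxy for the final classifier's
  error; the two can disagree on near-tied subsets.
* The feature-selection fitness is stochastic (sigmoid transfer), so the
  same position can map to different masks across evaluations; determinism
  holds only for a fixed seed.
* The ledger is tamper-*evident*, not tamper-*proof*: a single writer who
  controls the whole file can rewrite the chain; detecting that requires an
  externally held head hash.
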