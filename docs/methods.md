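# Methods

## The behavioral setting

The package models two-alternative reversal learning under a deterministic
("100–0") contingency: within a block of trials one side is always rewarded
and the other never, and the high-reward side flips at unsignaled block
boundaries.  Behavior is summarized per block by *signed choices*
y_t ∈ {0, 1}: y_t = 1 when the choice on the t-th trial of the block matched
the block's high-reward side.

## Choice-transition functions

Within a block, the probability of a signed-correct choice is modeled as an
increasing sigmoid in the 1-based within-block trial index t:

    σ(t) = ε + (1 − 2ε) / (1 + exp(−α (t − s)))

with switch offset s (trials), slope α (1/trials) and lapse ε ∈ [0, 0.5];
σ is confined to [ε, 1 − ε].  Signed choices are conditionally independent
Bernoulli draws with rate σ(t), so a block's log-likelihood is the sum of
per-trial Bernoulli terms.

The *foraging efficiency* of a transition function is the trapezoidal
integral of σ over t ∈ [1, 25] on a 0.1 grid, normalized by the interval
length 24; it is the expected fraction of signed-correct trials and lives in
[ε, 1 − ε].  Normalizing makes the taxonomy thresholds read directly as
fractions: efficiency < 0.65 is *low* performance, 0.65–0.84 *intermediate*
(split at lapse 0.1 into a high-lapse and a high-offset subtype), > 0.84
*high*; a high-performing mode with negative fitted offset is *high-early*
(it switches before the reversal).  Rectangle- vs trapezoid-rule differences
on the 0.1 grid are below 1e-3 and never move a mode across a threshold.

## The block-level hidden Markov model

A session is a chain of blocks.  Each hidden mode k carries one transition
function (s_k, α_k, ε_k); the emission probability of an entire block under
mode k is the product of its per-trial Bernoulli likelihoods, and modes
evolve block-to-block as a first-order Markov chain (K × K row-stochastic
transition matrix, initial distribution π).  Block emissions are tiny
(e^-20 and below for 30-trial blocks), so the forward–backward recursions
run in scaled linear space after max-normalizing each block's emission row
in log space; the log-likelihood is reassembled from the scaling constants.
This is exact to machine precision and is cross-checked in the tests against
brute-force enumeration over all K^B hidden paths on small instances.

**Fitting** is by EM.  The E-step is exact forward–backward.  The M-step
updates the transition matrix and π in closed form from expected counts
(entries floored at 1e-10 and renormalized so sampled chains never hit a
zero-probability path) and maximizes the expected complete-data
log-likelihood over (s, α, ε) per mode with L-BFGS-B under the box
constraints s ≥ 0.01, α ≥ 0.01, 0.01 ≤ ε ≤ 0.5.  Because σ depends on t
only, the per-mode objective reduces to T weighted success/failure counts,
making the inner optimization essentially free.  If the bounded optimizer
fails to improve the objective the previous iterate is kept, so the joint
log-likelihood is non-decreasing across iterations (asserted in tests at
1e-6 slack).  Emission parameters are initialized to (s, α, ε) =
(0.2, 4, 0.3) for every mode; the first E-step responsibilities come from
k-means clustering of the raw binary block rows into K clusters (0.95/0.05
soft one-hot), which breaks the symmetry of the shared initialization.

**Restarts and cross-validation.**  A fixed random 80/20 block split is
drawn once per fit.  Each of the `n_restarts` (default 5) EM runs is trained
on the 80% and scored on the held-out 20%; the winning run's parameters are
then used to warm-start a final EM pass on the full block matrix
(refit-after-selection), whose trace is reported as `loglik_trace_`.
Randomly removed blocks cut the chain, so the retained blocks are treated as
contiguous *segments*: forward–backward runs per segment, each starting from
π, and π is re-estimated from segment-start posteriors.  (Treating the 80%
as one unbroken chain measurably biases self-transition probabilities
downward — a mixture of one- and two-step transitions.)

The held-out score is normalized as

    L_norm = (L_test − L_0) / (n_test · log 2)

bits per trial, where L_0 is the held-out log-likelihood of a Bernoulli null
model whose rate is the training-set fraction of y = 1 (clipped to
[1e-6, 1 − 1e-6]).

**Choosing K.**  L_norm is computed for K = 1..6 on one shared split.  The
held-out likelihood plateaus once the true mode count is reached, and the
strict float argmax then rides on noise of a few log-likelihood units.  K is
therefore selected by the standard cross-validation one-standard-error rule:
the smallest K whose held-out score lies within one paired standard error
(computed over held-out segments) of the maximum.  `se_rule=0` restores the
strict argmax.  On data sampled from the three-mode reference mixture this
rule returned K = 3 on every chain tried; the strict argmax flipped to 4–6
on some chains.

**Decoding** of per-block states is by the marginal MAP (argmax of the
posterior, ties to the lower mode index), matching how per-block state
sequences are usually displayed; Viterbi is not used.

### Identifiability at the benchmark scale

With 1000 blocks of 30 trials, offsets and lapses are sharply identified,
but the slope of a mode whose transition completes within the first two or
three trials (s ≈ 1) is informed by only a couple of grid points: its
maximum-likelihood estimate has a sampling s.d. of roughly 15–20% even when
the true block labels are revealed to the estimator.  The EM fit tracks that
oracle closely, so scatter of that size in recovered slopes reflects the
information limit of the benchmark, not fitting error.

## Agent families

*Model-free Q-learning*: values q_L, q_R (initialized 0.5) with the chosen
action updated by q ← q + γ(r − q); ε-greedy policy (explore with
probability ε_explore, uniform ties).  γ may exceed 1 (overshooting updates
remain bounded for γ < 2).  Only the chosen action's value updates — no
forgetting of the unchosen value.  A consequence worth knowing: at γ = 1 the
agent is *not* exactly win-stay-lose-shift, because the side it must switch
to was itself zeroed when last abandoned, so the post-reversal choice is a
coin flip until the first correct — expected initial errors are 2, not 1.

*Inference-based observer*: an internal two-state Markov world model with
switch probability P_switch and reward probability P_rew; the posterior
belief P_L is updated recursively from the previous choice and outcome
(likelihood P_rew when the choice matches the hypothesized side, 1 − P_rew
otherwise, then the Markov transition, then normalization) and the policy
thresholds the belief at 0.5 (random tie).  The belief starts at 0.5 and the
first trial acts on it directly; updates begin from the second trial.

The simulation environment alternates sides with block lengths uniform on
the closed interval [15, 25]; the animal task's trailing-window performance
gate (15 trials at 75%) is available as an opt-in (`rolling_criterion`) and
is off in all forward simulations.  Simulations are reproducible from a
single seed per session.

## Regime mapping

The 25 × 20 Q grid (γ ∈ [0.01, 1.4] × ε ∈ [0.01, 0.5], inclusive evenly
spaced) and 15 × 10 inference-based grid (P_switch ∈ [0.01, 0.45] ×
P_rew ∈ [0.55, 0.99]) give 650 agents.  Each is simulated for 1000 blocks;
its average transition curve is fit by constrained least squares (s ≥ 0,
α ≥ 0, 0 ≤ ε ≤ 0.5, analytic Jacobian, data-driven start) and summarized by
the four features (lapse, slope, offset, efficiency).

**Clustering.**  The regime geometry is four clusters in the Q parameter
space and two in the inference-based space.  The default segmentation
(`method="per-family"`) realizes this directly and deterministically:
k-means with k = 4 on the standardized features of the Q-grid agents and
k = 2 on those of the inference-based agents, yielding contiguous regions
of each parameter space.  Q clusters are named Q1..Q4 in order of
increasing mean learning rate, inference-based clusters IB5..IB6 by mean
P_switch.

A pooled density pipeline (`method="tsne-watershed"`) is also provided: the
650 × 4 matrix is embedded in 2-D with t-SNE (Euclidean metric, perplexity
50, PCA initialization), histogrammed on a 50 × 50 grid, Gaussian-smoothed,
and segmented by a watershed seeded at density peaks (minimum peak
separation 8 bins), descending a smoothing ladder (σ = 4, ×0.75 steps)
until at least six basins appear and folding the smallest basins into their
nearest neighbor until exactly six remain.  It is not the default because
tightly clustered near-deterministic observers produce identical feature
vectors — a zero-width density spike that becomes its own basin — giving a
degenerate inference-based split whose session-level decodability is poor;
the per-family cut avoids that failure mode while matching the intended
composition.  A pooled k-means (k = 6, fixed seed) fallback is available
(`method="kmeans"`).

**Decoder.**  Every agent is re-simulated in 50 independent sessions of 20
blocks; per-session features are extracted as above.  Classes are balanced
by subsampling to the smallest class, split 80/20 stratified by class, and a
k-nearest-neighbor classifier (k = 10) runs on z-scored features (scaling
learned on the training portion and stored on the decoder, which therefore
expects raw features and rejects inputs that look already standardized).
Evaluation reports held-out accuracy, the multiclass Matthews correlation
coefficient, and the row-normalized confusion matrix.  Fitted blockHMM modes
are decoded by feeding their (ε, α, s, E) through the same scaler and
classifier.

## Behavioral benchmarks

Session metrics: fraction of rewarded trials; initial errors (errors before
the first correct response per block; a block with no correct response
contributes its full length); late performance (mean accuracy over each
block's last 10 trials; shorter blocks are excluded with a warning); side
bias (left-block minus right-block accuracy).  The win-stay-lose-shift
benchmark agent makes exactly one error per block, so its per-block accuracy
is exactly (len − 1)/len — 93–96% over lengths 15–25 — with late performance
100%.

**Uniform-strategy bootstrap.**  The observed statistic is the s.d. of
per-block performances.  A single sigmoid is fit to the pooled average
transition curve; a surrogate agent responds correctly with probability
σ(n) on trial n, with block lengths matched to the data; 100 surrogate
replicates give the null distribution and the p-value is the fraction of
replicates with simulated s.d. at or above the observed (small p = excess
variability).  With n_boot = 100, rejection at p ≤ 0.01 requires the
observed s.d. to exceed all 100 replicates, which has probability 1/101
under exchangeability — the test is calibrated by construction, and a
200-replicate study in the acceptance suite confirms it.

**Early switches.**  To expose anticipatory switching, each block's three
pre-reversal trials (the last three of the preceding block) are prepended
and signed against the *new* block's correct side, giving B × 18 matrices;
K-selection and fitting run unchanged on the shifted axis, and reported
offsets subtract 3.  A high-performing mode with resulting s < 0 is labeled
high-early.  Signing against the new side is the only convention under which
a correct anticipation scores y = 1 and s < 0 encodes early switching.

## Synthetic data

The three-mode reference agent used throughout tests and docs has modes
(s, α, ε) = (4, 0.2, 0.3), (1, 0.8, 0.15), (9, 1.5, 0.05), a sticky
transition matrix with self-transitions 0.966/0.954/0.955, uniform initial
distribution, and is sampled for 1000 blocks of 30 trials.  Generators for
mixture datasets (session CSV plus a ground-truth state sidecar) and for
anticipatory sessions (a sigmoid defined on the true axis with possibly
negative offset, whose block tails anticipate the next target) are
first-class, seeded, and byte-reproducible.

What the generators do *not* emulate: reaction times, aborted/timeout
trials, satiety or motivation drift, session-boundary effects, and the
rolling performance gate (off by default).  Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
assumptions, not robustness to those animal-data artifacts.

## Problem sizes and numerical choices

The benchmark scales are the ones the methods are designed for: 1000 blocks
× 30 trials for mixture recovery; 650 agents × 1000 blocks for clustering;
650 × 50 sessions × 20 blocks for decoder training.  EM runs to an absolute
log-likelihood tolerance of 1e-4 (cap 3000 iterations; typical convergence
is a few hundred); the per-mode optimizer is bounded L-BFGS-B with analytic
gradients; curve fits use trust-region least squares with analytic
Jacobians.  Probability rates inside logs are clipped at 1e-12.

## Known limitations

* Transition matrices are stationary; no covariate- or time-dependent
  transitions (GLM-HMM-style inputs are out of scope).
* Slopes of very fast transitions are weakly identified at realistic data
  sizes (see above); compare slopes only with that caveat.
* The regime labels are defined by clustering simulated agents; decoding a
  fitted mode asserts similarity of its transition features to those
  agents, not that the subject literally implements either algorithm.
* The six-cluster segmentation is a modeling choice held fixed by the
  adaptive watershed; on feature sets whose density genuinely lacks six
  basins the smallest-basin merges are arbitrary at the margin.
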