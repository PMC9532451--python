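# Methods

## Task structure emulated by the synthetic generator

The stimulus space is the 100-lottery grid {0.1, …, 1.0} × {0.1, …, 1.0}
(probability × magnitude in mL). Choice trials pair two lotteries drawn
independently and uniformly from the grid, with the left/right
assignment random; the chooser is a logistic random-utility agent,
P(right) = 1/(1+e^−β(V_R−V_L)). Single-cue trials present every grid
lottery once per block in random order (blocks of 100 trials,
concatenated to reach the requested count), matching the task's
100–120-trial recording blocks.

Trial-level firing noise is not specified by the protocol, so the
generator's default is Poisson spike counts in the 1-s analysis window
at rate max(0, R) — firing is nonnegative and count-like — with a
Gaussian-rate mode (`noise_model="gaussian_rate"`) retained for
analytic checks; `noise_scale = 0` returns the mean surface exactly in
either mode. Negative mean rates under the Poisson model are truncated
at 0 and logged.

The default choice gain for simulations is β = 10. V spans [0, 1] on
the grid, so β ≈ 10 gives near-deterministic choice at large value gaps
and graded stochasticity near indifference, the regime seen in trained
animals' choice matrices. β is a parameter everywhere, not a constant.

What the generator does *not* emulate: session-to-session drift,
history dependence (win-stay/lose-shift), lapse trials, spike-train
autocorrelation, and between-epoch correlation within a neuron. Passing
recovery tests therefore demonstrate estimator correctness under the
stated sampling model, not robustness to those real-data features.

## Behavioral fitting

The Bernoulli log-likelihood is maximized over the model's free
valuation parameters plus β with L-BFGS-B under box constraints
α, δ, γ ∈ [0.05, 5], β ∈ [0, 100]. Multi-start: one start at the
neutral point (curvatures 1, β = 5) plus starts drawn log-uniform
within the bounds (β within [0.5, 50]); default 20 starts. Values are
computed once per unique lottery and scattered to trials, which makes
a 45,000-trial likelihood evaluation cheap. Standard errors are the
square roots of the diagonal of the inverse observed information
(central finite-difference Hessian of the negative log-likelihood at
the optimum). Tests of fitted parameters against 0 and 1 are Wald
z = (estimate − null)/SE referred to a t distribution with
df = n_trials − 1, matching the reporting convention for the behavioral
estimates. AIC counts k = free valuation parameters + 1 (for β); ties
in the model ranking go to the model with fewer parameters.

The likelihood surface for PT2 on small datasets is shallow along the
(δ, γ) trade-off; the test suite therefore anchors the optimizer to an
exhaustive coarse grid search (the fit must attain at least the grid
optimum's likelihood) rather than to point identity of the arg max.

## Neural screening and fitting

Firing rates are counts in four 1-s windows stepped 0.5 s through the
2.5-s cue period ([0,1], [0.5,1.5], [1,2], [1.5,2.5] s from cue onset),
no smoothing. Each neuron-epoch ("signal") is screened by OLS of trial
rate on (1, p, m); P+M+ requires both slopes positive and significant
at two-sided 0.05, P−M− both negative and significant; only these
classes enter model fitting, and each qualifying epoch remains a
separate signal. No multiple-epoch correction is applied. Contingency
tests of qualifying proportions use Pearson chi-square, with Yates
continuity correction on 2×2 tables only (the convention of R's
`chisq.test`, which reproduces the reference statistics).

Neural models R = g·w(p)·u(m) + b are fit by least squares. Because g
and b enter linearly, they are profiled out exactly — at each candidate
(α, δ, γ) the conditional optimum of (g, b) is a closed-form linear
solve — and the multi-start search (default 100 starts, log-uniform in
[0.05, 5]) runs only over the nonlinear parameters. This dominates
random initialization of all five parameters: every restart evaluates
the exact conditional optimum, and negative-coding signals
automatically receive g < 0. Model comparison uses the Gaussian
equivalence AIC = n·log(SSE/n) + 2k (k = 2, 3, 4, 5 for EV, EU, PT1,
PT2); the additive constant cancels in all comparisons, which are
always within-signal differences. Regional comparisons run one-sample
t-tests on the per-signal AIC difference ladder EV−EU, EU−PT1, PT1−PT2;
the winner is the most complex model whose rung is significantly
positive, EV when significance only favors simpler models, and
"undetermined" when no rung is significant.

## Clustering

Per-signal PT2 parameter vectors (b, g, α, δ, γ) are winsorized at the
optimizer bounds (so one divergent fit cannot define a component),
z-scored, reduced by PCA to the fewest components exceeding 90%
cumulative explained variance, and partitioned by k-means (k = 5
default, 100 restarts, fixed seed). Standardization is a flag
(`standardize=False` runs centered-only PCA) because the five
parameters differ in scale by two orders of magnitude and the
unstandardized variant lets g and b dominate. Clusters are renamed in
descending size order, so C1 is always the predominant cluster.

## Network reconstruction

The three-layer model takes cluster mean parameters as fixed inputs.
Cluster responses are summed with signs — subtractive for clusters with
negative mean gain, which inverts their value-anticorrelated signal —
and rectified: SEV(p, m) = max(0, Σ_j s_j R_j). The fraction of grid
lotteries clipped by the ReLU is reported. Choices are simulated for
all 10,000 ordered grid pairs (including identical pairs),
`reps_per_pair` times each (default 4 → 40,000 trials), with the
logistic rule at unit gain on SEV differences. The refit estimates β
freely: SEV is in spikes/s while V is dimensionless, and β absorbs the
scale, leaving α, δ, γ scale-invariant (multiplying all gains and
baselines by c > 0 rescales β by c and leaves the preferences
unchanged). Repetitions resample only choice noise; parameter tests
against 1 (or supplied behavioral estimates) use the empirical
two-sided tail of the repetition distribution.

## Numerical choices

- Optimizer tolerances: behavioral L-BFGS-B at scipy defaults; neural
  NLS at ftol 1e-12, gtol 1e-10, 500 iterations per start.
- SSE floor of 1e-300 inside the neural AIC log, so a perfect
  (zero-residual) fit yields −inf AIC and wins any comparison, with
  ties broken toward fewer parameters.
- Degenerate inputs: screening rejects < 10 trials, < 2 distinct p or m
  levels, or collinear designs; neural fitting rejects < 20 trials or
  < 4 distinct lotteries; empty selections propagate as explicit
  errors, not silent empties.
- Zero-variance AIC difference vectors in regional comparisons are
  reported as no-difference (t undefined) rather than significant.

## Problem sizes

The test suite and acceptance script run at the study's behavioral
scales (44,883 and 19,292 choice trials) with 8–15 optimizer starts,
which on these well-identified likelihoods reach the same optimum as
larger start counts; synthetic neural populations in the pipeline tests
use tens of signals with one block per neuron, and network recovery
distributions use up to 100 repetitions of the 40,000-trial simulation,
with smaller repetition counts in unit tests. These sizes are stated so
results can be reproduced exactly; all are parameters.

## Known limitations

- AIC model selection over nested models is not consistent: on
  EV-generated data, a richer model wins by chance in a minority of
  samples. Tests assert the modal outcome and bounded likelihood gains,
  not certainty.
- The (δ, γ) pair is weakly identified in small samples; behavioral
  fits below a few hundred trials can sit anywhere along a shallow
  ridge. Recovery claims are made at the study's trial counts.
- The clustering stage fixes k = 5; no automatic model-order selection
  is provided, and cluster means (not within-cluster distributions)
  drive the network stage.
- The network's recovered preferences depend on which clusters feed it;
  with heterogeneous clusters the recovered parameters match no single
  cluster and are reported, not asserted, as a qualitative outcome.
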