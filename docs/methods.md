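# Methods

`synmem` computes the storage capacity of fully connected recurrent networks
of `N` binary neurons with binary (0/1) stochastic synapses, for three
learning scenarios, and validates the analytic results against direct
simulation.  This note records the model, the formulas implemented, the
numerical choices, and the limits of what the tests demonstrate.

## Model

**Patterns.**  A memory is a binary activity vector; neuron `i` is selective
with probability `f` (the coding level), independently, or — in the
fixed-size variant — every pattern has exactly `M = f N` selective neurons.
All capacity results live in the sparse-coding regime `f = beta ln N / N`
with `beta` of order one.

**Retrieval.**  A pattern is retrieved if it is a fixed point of the
synchronous threshold dynamics: neuron `i` becomes active iff its field
`h_i = sum_j J_ij s_j - I * sum_j s_j` strictly exceeds the raw threshold
`theta * f * N`, where `theta` is a scaled threshold of order one and `I` an
optional uniform inhibition.  Ties go silent (a fixed convention is needed
because integer fields can hit the threshold exactly; the suite asserts the
convention).  The error-tolerant analyses use the overlap
`m = (1/(M(1-f))) sum_i (eta_i - f) s_i`, which is 1 on the pattern itself,
0 on the silent state, and penalises spurious activity.

**Learning rules.**
* *Willshaw*: `J_ij = 1` iff some stored pattern co-activated `i` and `j`.
  After storing `P` patterns the background occupancy is
  `g0 = 1 - (1 - f^2)^P`.
* *SP (single presentation)*: each pattern is presented once; plasticity is
  presynaptically gated.  With presynaptic neuron active, the synapse is
  potentiated with probability `q+` if the postsynaptic neuron is active and
  depressed with probability `q-` if it is silent; nothing happens at silent
  presynaptic neurons.  Each synapse is a two-state Markov chain with
  per-presentation rates `a = P(pair active) q+` and
  `b = P(pre active, post silent) q-`, giving the stationary potentiated
  fraction `g_inf = a/(a+b) = 1/(1+g)` where
  `g = q-(1-f)/(q+ f)` is the depression/potentiation ratio (the ratio of
  depressing to potentiating *events* per presentation).  A pattern of age
  `K` leaves `g_plus(K) = g_inf + (1-g_inf) q+ lambda^(K-1)` on its
  selective pairs, with `lambda = 1 - a - b` (decay time
  `tau = 1/(f^2 q+ (1+g))` in the sparse limit), and a small depression
  imprint `g_minus(K) = g_inf (1 - q- lambda^(K-1))` on pre-selective /
  post-silent pairs.
* *MP (multiple presentations)*: noisy instances of `P` fixed prototypes are
  presented repeatedly; a presented neuron keeps its prototype state with
  probability `1-x` and is redrawn as Bernoulli(f) with probability `x`.  In
  the slow-learning limit each synapse equilibrates to the ratio of its
  potentiation and depression rates.  Conditional on a pair being
  co-selective in `k` prototypes, with `omega = P f^2` the mean co-selection
  count,

      rho(k) = (k(1-x)^2/omega + x(2-x)) / (k(1-x)^2/omega + x(2-x) + g),

  and `g_minus = E[rho(k)]`, `g_plus = E[rho(k+1)]` with `k ~ Poisson(omega)`
  (the tested prototype co-selects the pair by construction).  This form
  reproduces every limit the theory requires: `g_plus = g_minus` at `x = 1`,
  and exactly the Willshaw occupancies and information at `g -> 0, x = 0`.
  An exact finite-(P, f) enumeration (`mp_occupancy_finite`) validates the
  Poisson sparse limit and the `learn_mp` simulator.

## Asymptotic capacity

Fields of selective / non-selective neurons are sums of ~`fN` weakly
dependent Bernoulli variables with means `g_plus`, `g_minus`.  Treating them
as binomial, wrong-side probabilities decay with the large-deviation rate
function `Phi(x; g) = x ln(x/g) + (1-x) ln((1-x)/(1-g))`.  Storing
`P = alpha (N/ln N)^2` patterns stores `i = alpha beta / ln 2` bits per
synapse, and a tested pattern is stable with probability -> 1 iff

    Phi(theta; g_plus) > 0          (selective side; rhs decays as lnlnN/lnN)
    beta Phi(theta; g_minus) > 1    (non-selective side)

Saturating both (`theta -> g_plus`, `beta = 1/Phi(g_plus; g_minus)`) and
optimising over model parameters gives:

* Willshaw: `i = ln(1-g0) ln(g0) / ln 2`, maximal at `g0 = 1/2` with
  `i = ln 2 ~ 0.693` bits/synapse, on a broad plateau.
* SP: parametrising the oldest stored age by `w = K f^2 q+ (1+g)`,
  `i(w) = w Phi(g_plus(w); g_inf) / (q+ (1+g) ln 2)`; the global optimum
  (grid + Nelder-Mead, deterministic) is `i ~ 0.0827` bits/synapse at
  `g ~ 2.46`, `q+ = 1` — about 8.4x below Willshaw, the price of palimpsest
  (continual) learning.
* MP: `i(omega) = omega Phi(g_plus(omega); g_minus(omega)) / ln 2`,
  decreasing in the presentation noise `x` (capacity/generalisation
  trade-off) and bounded by the Willshaw value, which it attains at
  `g -> 0, x = 0`.

## Finite-size calculation

For a pattern with `M` selective neurons, the probability of exact one-step
stability is `(1 - p_sel)^M (1 - p_ns)^(N-M)` with `p_sel` and `p_ns` exact
log-domain binomial tails of `Bin(M-1, g_plus)` and `Bin(M, g_minus)`
against the integer threshold `floor(theta f N)` (with inhibition, the
threshold becomes `theta f N + I * M`).  When pattern sizes fluctuate the
probability is averaged over `M ~ Binomial(N, f)` by the exact weighted sum
over a +/-6-standard-deviation window (the historically used Gaussian-weight
surrogate is available for comparison; it deviates by up to ~1% of
probability on the steep part of the curve because it drops the binomial
skewness).  The finite-size capacity `P(alpha50)` is the largest age (SP) or
pattern count (Willshaw/MP) at which the averaged probability is still >=
1/2, found by doubling plus integer bisection; ties resolve to the larger
load.

The Gaussian approximation replaces the tails by normal ones with matched
mean and variance, evaluated at the half-integer cut `floor(T) + 0.5`
(fields are integers; without the continuity correction the comparison with
the binomial tails is contaminated by discretisation rather than tail
shape).  In the sparse regime it overestimates retrieval because the
capacity probes the far tail, which a Gaussian underestimates.  The
covariance-corrected variant adds the within-row synaptic covariance
`M(M-1) Cov` to the field variances (SP model).  That covariance is computed
exactly from the observation that synapses sharing their postsynaptic
neuron are conditionally independent given that neuron's activity history:
`Cov(J_ij, J_ik) = Var(m)` where `m(history)` obeys an affine random
recursion whose first two moments close linearly and sum in closed form
(stationary initial moments, a storage-step map, then `K-1` relaxation
steps).  A ground-truth simulation at `f = 0.1` reproduces the closed form
to three digits.  The correction grows with `f` and lowers capacity at
dense coding, as expected.

**Leading-order capacity formula (SP, fixed sizes).**  Keeping the Stirling
prefactor and the geometric-series factor of the selective tail, the 1/2
crossing satisfies `M Phi(theta; theta + Delta) = L0 - ln(1 - r(Delta))`
with `L0 = (1/2) ln(M/(2 pi theta(1-theta))) - ln ln 2` and `r` the
geometric ratio at the threshold; `Delta` is found by bracketed root
finding (its quadratic-expansion form is `sqrt(2 theta(1-theta) L0/M)`).
Inverting the age decay yields
`P(N) = (N/lnN)^2 [A1 - (A2/(theta-g_inf)) sqrt(L0/M) + ...]` with recorded
constants A1, A2.  Because `M = beta ln N` grows only logarithmically,
integer rounding of `M` and of the threshold never becomes negligible; the
convergence of this formula to the full calculation is therefore checked
against a continuous evaluation (binomial tails continued in both argument
and index via the regularised incomplete beta function), which is also used
for the step-function (load slightly below/above the asymptotic boundary)
checks.  The step-function limit is demonstrated on the Willshaw model,
where the load drives the *non-selective* occupancy and convergence is
polynomial in N; in the SP model a load margin only relaxes the selective
condition, whose finite-size correction decays as `ln ln N / ln N` — far
too slowly to observe at any simulable size (this is precisely why finite
networks reach only ~20-40% of the asymptotic capacity).

## Simulation protocols

The stream simulator initialises `J` i.i.d. Bernoulli at the stationary
potentiated fraction (the exact stationary *marginal*), presents patterns
through the stochastic rule (index-set updates: potentiation on the active
block, depression by geometric gap sampling — exact Bernoulli statistics at
O(events) cost), and tests stored patterns either as one-step exact fixed
points or by iterating the dynamics to a fixed point (period-2 cycles are
detected and reported as non-converged).

Two protocols are provided:

* **matched history** — each trial stores its tracked pattern on a fresh
  stationary-marginal matrix and simulates exactly `K-1` subsequent
  presentations.  This is precisely the ensemble the binomial finite-size
  calculation describes, and is used for theory/simulation comparison.
* **stationary stream** — one long stream per realisation with periodic
  checkpoints.  This additionally accumulates the *within-row correlations*
  of the true stationary state (built up on the `1/(f q+ f)`-presentation
  timescale).  At the coding levels of networks of 10^4+ neurons the
  difference is negligible; at `N = 2000` (where `f ~ 0.01`) the stationary
  correlations measurably depress the plateau of the no-error probability
  by a few percent relative to the independent-synapse calculation — a real
  effect of exactly the kind the covariance-corrected Gaussian models.

The error-tolerance analysis at `N = 10^4` uses the stream protocol without
extra pre-history (an optional `burn_in` argument lets the matrix
equilibrate its correlations first; the fully stationary variant gives
noisier and somewhat lower gains because clustered failures raise the exact
capacity and depress the tolerant one).  The exact and error-tolerant
retrieval curves are measured on the *same* trials, so their 1/2-crossing
capacities are estimated by a paired logistic fit in log-age with a shared
slope (`paired_capacity_crossings`): the joint fit cancels the common-mode
sampling noise and reduces the seed-to-seed spread of the capacity-gain
estimate from ~+-6 to ~+-1.5 percentage points at 300 trials per age.

## Problem sizes and determinism

Default experiment sizes were chosen so every analysis runs on a single
desktop core: theory curves are instantaneous; the `N = 2000`
theory-vs-simulation comparison uses 500 matched-history trials per age
(~1 min); the `N = 10^4` error-tolerance simulation uses a few hundred
trials per age over ~16 ages (~5 min).  Every stochastic routine takes an
explicit seed or generator; identical seeds give byte-identical outputs
(PCG64, child streams spawned via `SeedSequence`).  Optimisers are
grid-plus-deterministic-refinement and reproduce bit-for-bit given the same
grid specification.

## What the synthetic conditions do and do not show

All validation data are generated by the package itself under the model's
own assumptions (i.i.d. sparse patterns, full connectivity, binary
synapses, synchronous updates).  Passing tests therefore demonstrate the
internal consistency of theory and simulation — not that cortical or
hippocampal synaptic matrices satisfy the assumptions.  Known limitations:

* correlated or structured memory ensembles are out of scope;
* the finite-size theory covers exact retrieval only; error-tolerant
  capacity is simulation-only (fixed points reached *from* the stored
  pattern; basins of attraction are not characterised);
* the covariance-corrected Gaussian is implemented for the SP model;
* the asymptotic MP occupancies assume the slow-learning limit; at finite
  learning rates the exact enumeration should be used;
* the depression/potentiation ratio convention counts events per
  presentation, so `q- = g q+ f/(1-f)` is coding-level dependent.
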