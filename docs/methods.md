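# Methods

## Decision architecture

All models operate on the arrival-time difference ΔA = ΔL + d, where d is the
stimulus-onset difference (d = t_y − t_x, positive when x leads; loaders never
flip signs) and ΔL is the arrival-latency difference of the two channels.  Two
ΔL families are supported, each with location μ_ΔL and a scale parameter:
normal (σ_ΔL) and Laplace (b_ΔL).  The Laplace variants of every model differ
from the normal ones only in the CDF used; bounds and starting values for the
Laplace scale reuse those of σ_ΔL.

Internal states partition the real line of ΔA by thresholds.  Because ΔL is
continuous, the choice of closed versus open interval boundaries has no effect
on any probability; closed intervals are used.  State probabilities follow
from the ΔL CDF F:

- basic (3 parameters): P(I_xy|d) = 1 − F(c_su − d), P(I_yx|d) = F(−c_su − d),
  P(I_si|d) the remaining mass.
- TTM (5): an order threshold c_o ≥ c_su adds the state I_su of unordered
  successiveness on the two bands c_su ≤ |ΔA| < c_o; responses in I_su follow
  a guess g.
- TSM (7): two independent (ΔL, threshold) pairs, one per processing center;
  joint state probabilities are products.  No ordering constraint links the
  two thresholds.
- REM (9): single threshold; overt responses arise by row-stochastic mixing of
  the basic states with misreport rates ε ∈ [0, 0.8] and conditional biases
  κ ∈ [0, 1].  Complement biases (e.g. κ_xy−si = 1 − κ_xy−yx) are derived,
  never stored.  Reduced variants fix ε = 0 (and κ = 0.5, inert) for inactive
  responses, giving the 3/5/5/5/7/7/7/9-parameter hierarchy.

A channel-specific processing-delay parameter and an overt R_su response
category are deliberately out of scope; quaternary data are handled by
dropping R_su trials at load time.

## Fitting

The objective is G² = 2 Σ O ln(O/E) over response × SOA cells, with expected
frequencies E = n_d · P(R|d) floored at 0.1 counts (the floor applies to
expected frequencies only, per cell, after scaling by n_d; cells with O = 0
contribute exactly 0).  Minimization is box-constrained L-BFGS-B started from
the full factorial grid of two values per free parameter (2^k starts).  Bounds
and starts: locations [−100, 100] ms from {−33, 34}; scales [1, 100] ms from
{33, 67}; thresholds [1, 150] ms from {50, 100}; ε [0, 0.8] from {0.27, 0.53};
κ and g [0, 1] from {0.33, 0.67}.

Numerical choices not fixed by the procedure above:

- The TTM constraint c_o ≥ c_su is enforced by reparameterizing c_o = c_su + δ
  with δ ∈ [0, 149] ms and starts {0, 50}, preserving a plain box-constrained
  search.
- Objective tolerance ftol = 1e-9, iteration cap 2000 per start.  Gradients
  are analytic (hand-derived Jacobians of each model's response probabilities,
  validated against finite differences in the test suite); a numba JIT kernel
  evaluates objective and gradient, with a pure-numpy fallback asserted equal
  to it.
- Ties across starts break first-found; the fit is fully deterministic.
- Probabilities are clamped to [1e-300, 1] before forming expected counts, so
  extreme |d| cannot underflow the logarithm.

BIC = G² + k·ln(n) uses n = total trials Σ_d n_d, since the multinomial
likelihood has one observation per trial (an alternative "n = number of cells"
convention exists; the trials convention is fixed here and recorded in every
FitResult).  The NMI is evaluated on the observed d grid only, from observed
proportions or fitted probabilities; levels with zero trials are skipped.

## Synthetic data

`study_presets()` mirrors the d grids of the eight studies entering the
comparison: ±150 and ±90 step 30 (the two grids of the three Benussi
experiments; the historical 29.7-ms step is represented by the printed 30-ms
grid), ±100 step 25 (three studies), ±75 step 15, ±350 step 50, ±170 step 17
(a fixed-grid stand-in for an adaptive placement procedure that only fixes the
17-ms step), and ±65 step 5 (27 levels).  Historical per-level trial counts
are unpublished, so presets default to a configurable constant (100).

`simulate_response_table` draws multinomial counts from a model's analytic
response probabilities — appropriate for recovery studies, but by construction
it cannot detect errors in those probabilities.  That check is done by the
test suite's independent trial-level oracle, which walks individual simulated
trials through each model's state/response mapping.  The oracle uses
Latin-hypercube stratification (stratified marginals of every latent
coordinate, randomly paired): the estimator stays unbiased and model-blind
while its error drops well below the iid binomial standard error, so a
3-SE-per-cell agreement bound is informative rather than a coin flip across
thousands of cells.  A green oracle test establishes that the analytic
response probabilities are the distributions the models' mechanisms generate;
it says nothing about real observers (no sequential effects, no lapses beyond
the REM's own mechanism, no adaptive placement).

`simulate_dual_trials` generates SJ-then-forced-TOJ trials from a TTM with one
shared ΔA per trial.  The ternary TTM never defines a forced order report
inside the simultaneity band, so the generator adds a `forced_guess_si`
parameter (default 0.5, unbiased guessing).  With c_o = c_su and unbiased
guessing, recoded dual responses reproduce the basic model exactly.

## Conditional order-accuracy analysis

For dual-response data, the report computes per |d| and pooled (d = 0
excluded, empty conditioning sets reported as NaN): unconditional order
accuracy, accuracy given a correct successiveness response (sj = su at
d ≠ 0), and accuracy given an incorrect simultaneity response (sj = si),
the latter tested against 0.5 by a two-sided exact binomial test.  The
two-sided p-value uses the point-probability convention (sum of all outcome
probabilities not exceeding the observed outcome's); at p₀ = 0.5 this equals
doubling the smaller tail, where all standard conventions coincide.
Significance counts use α = 0.05.  If order detection requires successiveness
detection, accuracy after R_si should sit at chance — the pattern the
simulated generator reproduces and the exact tests quantify.

## Latency-difference approximation theory

If each channel latency is a sum of k exponential stages (Erlang), ΔL is a
difference of Erlangs, computed here in closed form (binomial expansion of the
convolution integral, evaluated in log space; the k = 1 equal-rate case is
exactly Laplace).  If each latency is a Wald (inverse-Gaussian) first-passage
time, ΔL's density is computed by numerical cross-correlation of the two Wald
densities on a uniform grid spanning the difference mean ± 8 SD with 4096
points (tail mass < 1e-12 outside).  The Wald law is parameterized by (mean,
shape), the standard equivalent of drift/boundary descriptions.
`normal_approx_distance` reports the sup-norm and KS distance to the
moment-matched normal.  The "plausible range" of channel means tested is
50–250 ms with shape = 10 × mean (per-channel coefficient of variation ≈ 0.32,
typical of simple-reaction latencies); the resulting KS distances (≈ 0.03–0.06,
cross-checked against a Monte-Carlo ECDF oracle) are documented in the tests
rather than asserted against any published value.

## Known limitations

- The eight historical data sets are external; every quantitative result in
  this repository is computed on synthetic data from a stated ground truth.
- BIC penalizes parameters uniformly; the TSM's unconstrained order threshold
  buys it more flexibility per parameter than the TTM's constrained one, a
  structural asymmetry BIC ignores.
- The G² surface of REM and TSM is multimodal (the per-start spread is exposed
  as a FitResult diagnostic); the factorial multistart makes a global optimum
  likely, not guaranteed.
- No standard errors or bootstrap confidence intervals are produced.
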