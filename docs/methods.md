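# Methods

## Model

A two-choice decision is made when a superimposed diffusion process
`X(t) = X_c(t) + Σ_m X_a,m(t)` first crosses one of two symmetric
boundaries: +b selects the correct response, −b the error.  The controlled
process `X_c` has constant drift μ_C (activation units per ms).  Each
task-irrelevant modality contributes an automatic process whose *expected*
trajectory is a pulse — a rescaled Gamma density with shape a, scale τ (ms)
and signed peak A:

    E[X_a(t)] = A · e^(−t/τ) · [ t·e / ((a−1)·τ) ]^(a−1)

so its drift is the time derivative

    μ_a(t) = A · e^(−t/τ) · [ t·e / ((a−1)·τ) ]^(a−1) · [ (a−1)/t − 1/τ ].

The pulse is zero at t = 0, peaks at exactly |A| when t = (a−1)·τ, and
decays monotonically afterwards; its drift is positive before the peak and
negative after.  The shape is a structural constant (a = 2 throughout this
model family); it is carried as a field of `AutomaticProcessSpec` to make
the Gamma family explicit but is never a free fitting parameter.

The congruency of each modality's stimulus location maps to the pulse sign:
congruent → +1, neutral → 0 (the automatic process simply does not engage),
incongruent → −1.  Modalities are a named, ordered collection, so the same
core covers the single-modality special case (one automatic process) and
arbitrarily many superimposed sources.

Observed response time decomposes as RT = D + R: the decision time D from
the diffusion plus a residual (non-decision) duration R ~ Normal(μ_R, σ_R),
redrawn until positive.  Congruency affects only D.  The faster-neutral
variant (`fn-mdmc`) assigns the visual-neutral condition its own residual
mean μ_RN — foveally presented (central) stimuli enjoy a ~10–15 ms retinal
processing advantage — and is otherwise identical; μ_RN exists if and only
if that variant is selected.

## Simulation

The superimposed process is integrated by Euler steps

    X(t+Δt) = X(t) + μ(t)·Δt + σ·√Δt·Z,   Z ~ N(0,1)

with μ(t) = μ_C + Σ_m sign_m · μ_a,m(t).  Defaults Δt = 1 ms and σ = 4
match the simulation protocol of the original model family.  Noise is
applied once to the superimposed process; per-process diffusion constants
are not separately identifiable from the superposition and are not
simulated.  The drift of step k is evaluated at the end of the step,
t = (k+1)·Δt, which keeps the 1/t singularity of μ_a at t = 0 out of the
scheme.  The starting point is 2b·Beta(α, α) − b: symmetric on (−b, b),
mean 0, variance b²/(2α+1); α = 1 is uniform, large α collapses to 0.

Trials not absorbed within a 5,000 ms cap are flagged censored, excluded
from all summaries, and counted; at the published parameter scales the
censoring rate is below 10⁻⁴.  One root seed drives everything; each
congruency condition gets its own deterministic child stream so changing
one condition's trial count never reshuffles another's.

Known numerical property: first-passage detection on a grid carries the
usual O(√Δt) bias — the path can cross and return within a step, and the
crossing is detected only at the next grid point, with an overshoot of
order σ√Δt.  At Δt = 1 ms and the published parameters this inflates mean
decision time by ≈ 2 ms and accuracy by ≈ 0.004 relative to the Δt → 0
limit (measured by step-halving at 450k trials).  The closed-form
Wiener-oracle test therefore runs at Δt = 0.002 ms, where the bias is
below Monte-Carlo resolution at n = 10⁵.  Analyses comparing variants are
unaffected, since both variants share the discretization.

## Summaries

* RT filter: keep the closed interval [150, 1200] ms (strictly faster or
  slower trials are discarded, as are censored ones); idempotent.
* Quantiles: linear interpolation between order statistics with plotting
  position (k−1)/(n−1) (numpy's default).  The convention is pinned because
  it feeds the fitting objective.
* CAF: all trials of a condition — correct and error — sorted by RT (stable
  for ties), split into five near-equal bins, earlier bins absorbing any
  remainder (103 trials → 21/21/21/20/20); accuracy per bin.
* Delta plots: incongruent-minus-congruent quantile differences on the
  5–95% percentile grid, plotted against the mean of the two quantiles.
* Modality-marginal CDFs average quantiles per condition and then across
  the other modality's three labels (never pooled trials), matching how
  marginal CDFs are defined for this design.  For descriptive figures a
  per-participant-then-average (Vincentized) path can be obtained by
  grouping before calling these functions; the fitting path always pools
  trials over participants, because the models are fitted to aggregate
  data.

## Fitting

Ten proportions per condition form the objective.  With q_p the observed
correct-RT quantiles at p = .1,...,.9, the five CDF slots hold the fraction
of trials that are correct with RT in (−∞,q.1], (q.1,q.3], ..., (q.7,q.9] —
by construction ≈ (0.1, 0.2, 0.2, 0.2, 0.2) × accuracy — and the five CAF
slots hold the fraction of trials that are errors within each observed RT
quintile bin.  Predictions are simulated (default 50,000 trials per
condition, passed through the same RT filter) and scored in the *observed*
bins, so all distributional shape information enters through the predicted
vector.  Scoring the observed data against its own bins reproduces the
observed vector exactly.  This slot construction is a pinned convention —
the exact mapping of CDF/CAF bins to proportions is not uniquely determined
by the literature it follows — and alternative conventions can be plugged
in at `score_proportions`.

The discrepancy is G² = 2·Σ_c N_c·Σ_i |p_ci·log(p_ci/π_ci)| with
0·log(0/π) = 0 and predicted proportions floored at 10⁻⁵.  The absolute
value is implemented exactly as the objective is printed in the reference
table this package reproduces; it differs from the classical signed
likelihood-ratio form (available via `absolute=False`), is non-negative,
and — important when reading absolute G² magnitudes — has a strictly
positive noise floor that grows with N_c and with observed/simulated sample
sizes even for the true model.  Model comparison and minimization are
unaffected because both variants share the floor.

BIC = G² + f·ln(N) with f free parameters (9 base, 10 faster-neutral).  N
defaults to the number of trials entering the fit and is configurable
(`bic_n`); the reference table's printed BIC−G² gaps correspond to N = 270.

Minimization is multi-start Nelder–Mead (adaptive coefficients) in a
unit-box normalized space — parameters span four orders of magnitude, and
normalizing by the documented ranges (μ_C ∈ [0.2, 1.2], b ∈ [30, 100],
τ ∈ [10, 120], |A| ∈ [1, 40], μ_R, μ_RN ∈ [200, 450], σ_R ∈ [10, 80],
α ∈ [1, 6], also the hard bounds) makes the simplex scale-free.  All
randomness of the objective — starting-point uniforms, Gaussian increments
(a pre-generated per-trial matrix shared across conditions), residual
normals, and the fallback stream for trials outliving the matrix — is
frozen per fit (common random numbers), so the optimizer sees a
deterministic surface and the fit is exactly reproducible from its seed.
The search runs in two stages: `n_starts` short explorations from random
initial vectors, then one long Nelder–Mead restart (fresh simplex) from the
best endpoint.  The restart matters: short runs routinely end in collapsed
simplexes far from the optimum, and re-inflating the simplex at the best
point reliably descends the remaining way.  At the published
visual-tactile faster-neutral generating values (9 × 2,000 trials, 20,000
simulations per condition, 5 starts + polish) this recovers μ_C, b, A_V,
τ_V and μ_R to within a few percent.

Model comparison simulates `n_sims` G² values per model at its fitted
parameters against the fixed observed proportions — both models share the
same simulation streams, so the k-th values are genuinely paired and a
model compared with itself ties exactly — and applies a two-sided paired
sign-flip permutation test (default 50,000 permutations) to the G² and BIC
differences, with the add-one p-value estimator (1+#extreme)/(1+perms).

## Synthetic data

`DesignSpec`/`generate_dataset` emulate the factorial experiments the model
targets: 3 visual × 3 secondary-modality positions × 2 letters = 18 trial
types, 5 repetitions per block, 6 blocks, 30 participants, letter-response
mapping counterbalanced by participant parity, trials shuffled uniformly
within block — every participant sees each of the nine congruency cells
exactly 60 times (540 trials).  All participants share one parameter set,
since the fitting target is the aggregate; an optional multiplicative
jitter on μ_R exists for robustness exercises only and is off by default.
The generator does not emulate response deadlines, feedback displays,
letter confusability, or interindividual parameter variability — so
passing recovery tests demonstrate that the estimation machinery works
under the model's own assumptions, not that those assumptions hold for any
real dataset.

## Problem sizes used in the shipped checks

Unit and acceptance tests scale the published procedure to what the
package's own test suite exercises end-to-end: recovery fits use 2,000
trials per condition with 20,000 simulations per condition and 5 + 1
simplex runs; qualitative-signature checks use 50,000 simulated trials per
condition; the Wiener-oracle check uses 10⁵ trials at Δt = 0.002 ms.  The
CLI defaults follow the full published procedure (50,000 simulations per
condition, 10 starts, 1,000 comparison simulations, 50,000 permutations).

## Limitations

* No closed-form first-passage solution exists for the time-varying drift;
  everything is Monte Carlo, and fitted G² values inherit simulation noise
  (mitigated, not removed, by common random numbers).
* The absolute-value objective makes printed G² magnitudes convention-
  dependent (they scale with the N_c convention chosen); compare models on
  the same convention only.
* Trial-to-trial drift variability, collapsing boundaries, and exact
  (bridge-corrected) first-passage sampling are out of scope.
* The residual distribution is assumed normal (truncated at zero); only
  its first two moments are constrained by the fitted summaries.
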