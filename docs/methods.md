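# Methods

## Model

The ribosome flow model with different site sizes (RFMD) is a system of `n`
nonlinear ODEs for site occupancies `x_i(t) ∈ [0, q_i]`,

    dx_i/dt = λ_{i-1} x_{i-1} (q_i − x_i) − λ_i x_i (q_{i+1} − x_{i+1}),

with boundary conventions `x_0 := 1` (a saturated reservoir feeding the
chain) and `x_{n+1} := 0` (an absorbing exit). The exit capacity `q_{n+1}`
never appears in the dynamics except through the last equation; we set
`q_{n+1} := 1` so the outflow is exactly `λ_n x_n`, which is the only
convention under which the steady-state chain
`λ_0(q_1−e_1) = λ_1 e_1(q_2−e_2) = … = λ_n e_n` closes. With all `q_i = 1`
the model reduces to the equal-capacity ribosome flow model (RFM); there is
no separate code path for that case.

Assumptions inherited from the model class: rates are positive constants
(no time dependence), capacities lie in `(0, 1]`, flow is strictly
unidirectional, and the mean-field (soft-exclusion) closure replaces the
hard exclusion of the underlying lattice gas. The equilibrium `e` is unique
and globally attracting on the state space, which is what licenses both
solution routes below.

## Solvers

**Spectral route (production).** The `(n+2)×(n+2)` symmetric tridiagonal
matrix `A_n(r)` — diagonal `(0, (1−q_1)r, …, (1−q_n)r, 0)`, off-diagonal
`λ_i^{−1/2}` — is irreducible and nonnegative, so its largest eigenvalue
`σ(A_n(r))` is simple and positive. `σ` is nondecreasing in `r` and
`g(r) = σ(A_n(r)) − r` has exactly one sign change; the fixed point
`σ(A_n(r*)) = r*` gives `R = 1/(r*)²`. We solve `g(r) = 0` with Brent's
method (a bracketing method, inheriting bisection's unconditional safety)
on `[0, 2·max λ_i^{−1/2}/min q_i]`: the left endpoint has `g(0) = σ(A_n(0)) > 0`
and the right endpoint is nonpositive by the row-sum bound
`σ ≤ max row sum`. When all `q_i = 1` the diagonal vanishes, `σ` is
independent of `r`, and `r* = σ(A_n(0))` directly. Eigenvalues come from
LAPACK's Sturm-sequence bisection for symmetric tridiagonal matrices
(`scipy.linalg.eigh_tridiagonal`, `select="i"`); the dense matrix is never
materialized outside tests. Default fixed-point tolerance: `1e-12` absolute
on `r` (all defaults live in `rfmd.constants.DEFAULTS`).

**Dynamical route (oracle).** `solve_ivp` (LSODA, `rtol 1e-10`,
`atol 1e-12`) integrates from `x_i = q_i/2` over horizons
`T, 2T, 4T, …` with `T = 100/min λ` until the max-norm of the vector field
drops below `1e-10`, raising a convergence error (with the last residual)
after 12 doublings. Global convergence makes the start point a speed choice
only. The two routes agree to ≤1e-6 relative on random instances up to 50
sites; this cross-check is part of the test suite.

**Densities.** Back-substitution from the flow rate
(`e_n = R/λ_n`, `e_i = R/(λ_i(q_{i+1}−e_{i+1}))`) is exposed as
`densities_from_rate` and reports the inflow residual `|λ_0(q_1−e_1) − R|`.
That recursion, however, is numerically unstable for long chains: the local
error-amplification factor is `e_i/(q_{i+1}−e_{i+1})`, and its running
product behaves like a random walk, so roundoff grows roughly as
`exp(O(√n))` — noticeable by `n ≈ 20` and fatal (negative headroom) by
`n ≈ 1000`. `steady_rate` therefore reads densities off the Perron
eigenvector `ζ` of `A_n(r*)`: the eigenvalue equations at the fixed point
reproduce the steady-state chain exactly with
`e_i = λ_i^{−1/2} ζ_{i+1}/(r* ζ_i)`. Because the Perron vector of a long
disordered chain localizes (tail components fall below eigenvector-routine
accuracy), the successive ratios `ζ_{i+1}/ζ_i` are computed by the standard
two-sided three-term recurrence — run from each edge toward the vector's
peak, the direction in which the recurrence is stable — and stitched at the
peak located from the LAPACK eigenvector, which is reliable there. Flow
conservation at `n = 1000` holds to ~1e-14 relative with this scheme.

## Random parameters

Distribution families carry their support declaratively because every
asymptotic statement depends only on support endpoints: the essential
infimum/supremum of the family, and `M_{X^{−1/2}} = (ess inf X)^{−1/2}` for
rates. Shipped families: `constant`, `uniform(lo, hi)`, and
`half_normal_shifted` (`loc + |N(0, σ)|`). A "half-normal with sd `s`" is
parameterized by `σ = s/√(1 − 2/π)` so the distribution's standard deviation
equals `s`; its support starts exactly at `loc`, which is the quantity the
limits consume — the scale convention cannot move any limit or bound.

Tail probabilities `a(ε) = P{X^{−1/2} ≥ M_{X^{−1/2}} − ε}` (equivalently
`P{X ≤ (M−ε)^{−2}}`) and `b(η) = P{Q ≤ m_Q + η}` are evaluated from the
closed-form CDFs; a Monte Carlo estimator with binomial standard errors is
provided as a distribution-free fallback and is checked against the closed
forms to three standard errors.

Ensembles map each index to a distribution (i.i.d., contiguous
heterogeneous blocks, or blocks plus a permutation of the index set — the
device showing the limits are insensitive to interleaving). Sampling is
reproducible: replicate streams derive from `SeedSequence(seed, n,
replicate)`, so tables are bit-identical across runs and replicates are
order-independent.

## Limits and bounds

Two mechanisms generate all bounds. The row-sum bound on the Perron root
gives lower bounds on `R`; planting the `(s+1)×(s+1)` 0/1 window matrix
`G_s` (largest eigenvalue `2cos(π/(s+2))`) on a run of `s` consecutive
indices where the parameter is extreme gives upper bounds, tightest at the
best window.

- Asymptotic limits: `q²(2M_{X^{−1/2}})^{−2}` (i.i.d. rates, homogeneous
  capacity) and `m_Q² λ/4` (i.i.d. capacities, homogeneous rate) — the same
  formula under `λ ↦ M^{−2}`.
- Finite-n i.i.d. intervals: the upper bound keeps the exact finite-window
  forms `q_L²(2(M−ε)cos(π/(s+2)))^{−2}` and
  `(m_Q+η)²(2λ_ℓ cos(π/(s+2)))^{−2}` rather than their truncated
  `(1 + O(ε + s^{−2}))` expansions, so reported bounds are valid at every
  `n`, not just asymptotically. Probability guarantees use
  `1 − exp(−⌊(n−1)/s⌋ a(ε)^s)` (rates) and `1 − exp(−⌊n/s⌋ b(η)^s)`
  (capacities) — the block-counting forms from the underlying argument,
  which are the conservative readings of the two floor expressions.
- Realized almost-sure bounds for arbitrary bounded draws: the implicit
  inequalities in `1/√R` are rearranged exactly into explicit per-window
  constraints; each `(s, window)` contributes one bound and the tightest is
  reported together with the attaining choice. In the capacity-only
  inequality the cosine argument is `π/(s+1)` — unlike the `π/(s+2)` of
  every sibling bound — and is implemented as stated; its `s = 1` constraint
  is vacuous (`cos(π/2) = 0`). The convention here: `λ_ℓ` and `λ_L` always
  denote the minimum and maximum of `{λ_i^{−1/2}}`, not of the rates
  themselves.
- Deterministic envelope for rates on `[a, b]`, capacities on `[c, d]`:
  `c²a/4 ≤ R ≤ d²b/4` asymptotically, `d²b/(4cos²(π/(s+2)))` at finite
  window length `s`.

A note on direction of convergence: for a homogeneous chain (`λ_i = λ`,
`q_i = q`), `R_n` decreases monotonically to `q²λ/4` from above, mirroring
the full-capacity closed form `λ/(4cos²(π/(n+3)))` (exact at `q = 1`,
itself decreasing in `n`). The asymptotic limits are therefore floors that
finite chains approach from above, which is also why ensemble sample means
at finite `n` sit slightly above the limiting values.

## Monte Carlo experiments

The driver draws `(λ, q)` per replicate, solves spectrally, and optionally
attaches per-draw realized bounds. Default study conditions mirror the
model's reference experiments: rate ensembles with fixed capacity 0.5 and
half-normal rates supported on `[2, ∞)` with sd 0.1; capacity ensembles
uniform on `[0.8, 1]` with unit rates, both at dimensions
`{50, 500, 1000}`; and a three-site joint ensemble with rates uniform on
`[1, 2]` and capacities uniform on `[0.5, 0.7]`. Full-scale runs use 5000
(10000 for the joint ensemble) replicates via the `paper` CLI profile; the
test suite and the acceptance script run 100-replicate (10000 for the
three-site chain, where a solve costs microseconds) versions, which already
pin the sample mean to a few percent — the Monte Carlo standard error of the
mean at 100 replicates is below 5e-4 for every shipped ensemble.
Convergence summaries report per-n mean, sd, and mean absolute deviation
from the theoretical limit; coverage checks report the fraction of
replicates inside attached bounds (1.0 for the almost-sure reports).

What the generator emulates — and what it does not: draws are independent
across indices and replicates with exactly the declared supports, so tests
verify the i.i.d./bounded-support theory. Real translation or traffic data
would have correlated, possibly time-varying rates and estimation error in
the supports; nothing here speaks to those regimes (dependence is explicitly
out of scope).

## Numerical choices and edge cases

- All tolerances live in `rfmd.constants.DEFAULTS` and are overridable per
  call; comparisons are explicit absolute+relative.
- `n = 1` is fully supported (the spectral matrix is 3×3); zero or negative
  rates/capacities are rejected at construction, never clipped.
- `G_1` is 2×2, below the generic matrix floor; its eigenvalue `1` comes
  from the closed form.
- Infeasible back-substitution (`q_{i+1} − e_{i+1} ≤ 0`) raises a dedicated
  error: the requested rate exceeds the chain's capacity.
- Replicate failures in ensemble runs are logged and skipped; an experiment
  errors out if more than 1% of its replicates fail.

## Known limitations

- The capacity-ensemble convergence toward `m_Q² λ/4` is slow (the
  finite-`n` upper bound carries a `(1+η/m_Q)²` factor), so sample means at
  `n = 1000` still sit ~15% above the limit; the rate-ensemble analogue sits
  ~4% above. This matches the theory's own convergence-rate ordering and is
  visible in the convergence summaries.
- Only the three shipped distribution families have closed-form tails;
  other families would use the Monte Carlo fallback.
- Bounds are reported as stated by the theory; no tightness analysis is
  attempted.
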