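# rfmd

Steady-state particle flow in the **ribosome flow model with different site
sizes (RFMD)**, with transition rates and site capacities treated as random
variables.

The RFMD is a deterministic mean-field model of unidirectional transport with
soft exclusion — ribosomes along an mRNA, data packets through a line of
buffers, vehicles on a road whose lane count varies. A chain of `n` sites has
occupancies `x_i(t) ∈ [0, q_i]`, capacities `q_i ∈ (0, 1]`, and hop rates
`λ_i > 0`:

```
dx_i/dt = λ_{i-1} x_{i-1} (q_i − x_i) − λ_i x_i (q_{i+1} − x_{i+1}),   i = 1..n
```

with `x_0 := 1`, `x_{n+1} := 0`. Every trajectory converges to a unique
interior equilibrium, where all links carry the same **steady-state flow rate
`R = λ_n e_n`**. `R` is computed here spectrally: the symmetric tridiagonal
matrix `A_n(r)` with diagonal `(0, (1−q_1)r, …, (1−q_n)r, 0)` and
off-diagonal `(λ_0^{−1/2}, …, λ_n^{−1/2})` has a unique fixed point
`σ(A_n(r*)) = r*` of its Perron root, and `R = 1/(r*)²`.

When the parameters are random with known support, the package provides the
flow-rate theory built on this representation:

- **Asymptotic limits.** For i.i.d. rates from `X` (support bounded away
  from 0) and homogeneous capacity `q`: `R_n → q² (2 M_{X^{−1/2}})^{−2}`
  almost surely, with `M_{X^{−1/2}} = (ess inf X)^{−1/2}`. For i.i.d.
  capacities `Q` and homogeneous rate `λ`: `R_n → m_Q² λ / 4`.
- **Finite-n intervals** with explicit probability guarantees built from the
  tail probabilities `a(ε) = P{X^{−1/2} ≥ M_{X^{−1/2}} − ε}` and
  `b(η) = P{Q ≤ m_Q + η}`.
- **Realized almost-sure bounds** for arbitrary bounded (not necessarily
  i.i.d.) parameter draws, via sliding-window extremes and the window-matrix
  eigenvalue `2 cos(π/(s+2))`.
- **Deterministic support envelopes** `c²a/4 ≤ R ≤ d²b/4` when rates live in
  `[a, b]` and capacities in `[c, d]`.

A Monte Carlo driver samples declared ensembles (uniform, shifted
half-normal, constant; i.i.d., block-heterogeneous, or permuted), solves each
instance, and summarizes convergence and bound coverage. An independent ODE
integrator cross-checks the spectral solver.

## Worked example

```python
import numpy as np
from rfmd import (RFMDParams, steady_rate, integrate_to_steady_state,
                  realized_bounds_full)

params = RFMDParams(lam=[1.0, 1.5, 2.0, 1.2], q=[0.6, 0.9, 0.7])
spectral = steady_rate(params)
ode = integrate_to_steady_state(params)
print(f"R  (spectral) = {spectral.R:.6f}")
print(f"R  (ODE)      = {ode.R:.6f}")
print(f"r* = sigma    = {spectral.r_star:.6f}")
print("densities e   =", np.round(spectral.e, 6))

report = realized_bounds_full(params.lam, params.q)
print(f"a.s. bounds   = [{report.lower:.6f}, {report.upper:.6f}]"
      f"  attained at (s, window start) = {report.attaining_choice}")
```

prints

```
R  (spectral) = 0.282998
R  (ODE)      = 0.282998
r* = sigma    = 1.879785
densities e   = [0.317002 0.304844 0.235832]
a.s. bounds   = [0.109102, 0.810000]  attained at (s, window start) = (2, 1)
```

The two solvers agree to their shared tolerance; `r*` is the spectral fixed
point (`R = 1/r*²`); the densities sit strictly inside `(0, q_i)`; and the
realized flow rate lies inside the almost-sure window bounds, here tightest
for the length-2 window starting at rate index 1.

The same from the shell:

```
rfmd solve --lam 1,1.5,2,1.2 --q 0.6,0.9,0.7
rfmd bounds --rate-support "1 2" --cap-support "0.5 0.7" --s 2
rfmd simulate --config config.yaml --out table.csv --profile ci
rfmd converge --table table.csv --limit 0.16 --coverage
```

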