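"""The RFMD dynamical system.

The ribosome flow model with different site sizes (RFMD) describes
unidirectional particle flow along a chain of ``n`` sites.  Site ``i`` has
capacity ``q_i`` in (0, 1] and occupancy ``x_i(t)`` in ``[0, q_i]``; the hop
from site ``i`` to ``i+1`` is controlled by the rate ``lambda_i > 0``.  The
dynamics are

    dx_i/dt = lam_{i-1} x_{i-1} (q_i - x_i) - lam_i x_i (q_{i+1} - x_{i+1})

with the boundary conventions x_0 := 1, x_{n+1} := 0 and q_{n+1} := 1, so the
outflow from the last site is ``lam_n x_n``.  Every trajectory starting in the
state space converges to a unique interior equilibrium ``e``, and the common
value of all link flows there is the steady-state flow rate ``R = lam_n e_n``.

This module provides the vector field, the instantaneous link flows, a
steady-state integration oracle, and back-substitution of the equilibrium
densities from a known flow rate.  The production path for ``R`` is the
spectral solver in :mod:`rfmd.spectral`; the integrator here is the
independent dynamical oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .constants import DEFAULTS

__all__ = [
    "RFMDParams",
    "SteadyState",
    "ConvergenceError",
    "InfeasibleRateError",
    "rhs",
    "flows",
    "integrate_to_steady_state",
    "densities_from_rate",
]


class ConvergenceError(RuntimeError):
    """Integration did not reach the steady-state residual target."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class InfeasibleRateError(ValueError):
    """A requested flow rate exceeds what the chain can carry."""


@dataclass(frozen=True)
class RFMDParams:
    """One RFMD instance: dimension ``n``, rates ``lam`` (length n+1, all > 0)
    and site capacities ``q`` (length n, each in (0, 1])."""

    n: int
    lam: np.ndarray
    q: np.ndarray

    def __init__(self, lam, q):
        lam = np.asarray(lam, dtype=float)
        q = np.asarray(q, dtype=float)
        if lam.ndim != 1 or q.ndim != 1:
            raise ValueError("lam and q must be one-dimensional sequences")
        n = q.size
        if n < 1:
            raise ValueError("need at least one site")
        if lam.size != n + 1:
            raise ValueError(
                f"rate vector must have length n+1 = {n + 1}, got {lam.size}"
            )
        if not np.all(np.isfinite(lam)) or np.any(lam <= 0):
            raise ValueError("all transition rates must be positive and finite")
        if not np.all(np.isfinite(q)) or np.any(q <= 0) or np.any(q > 1):
            raise ValueError("all site capacities must lie in (0, 1]")
        object.__setattr__(self, "n", int(n))
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "q", q)

    def validate_state(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n,):
            raise ValueError(
                f"state must have length n = {self.n}, got shape {x.shape}"
            )
        return x

    def to_dict(self) -> dict:
        return {"n": self.n, "lam": self.lam.tolist(), "q": self.q.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RFMDParams":
        return cls(d["lam"], d["q"])


@dataclass(frozen=True)
class SteadyState:
    """Equilibrium of an RFMD: interior densities ``e``, flow rate ``R``,
    spectral fixed point ``r_star`` with Perron root ``sigma = r_star``, and
    the n+1 link flows (all equal to R at equilibrium)."""

    e: np.ndarray
    R: float
    r_star: float
    sigma: float
    flows: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "e": np.asarray(self.e).tolist(),
            "R": float(self.R),
            "r_star": float(self.r_star),
            "sigma": float(self.sigma),
            "flows": np.asarray(self.flows).tolist(),
        }


def _padded(params: RFMDParams, x: np.ndarray):
    """State and capacities with the boundary conventions applied:
    x_0 = 1, x_{n+1} = 0, q_{n+1} = 1."""
    xp = np.concatenate(([1.0], x, [0.0]))
    qp = np.concatenate((params.q, [1.0]))
    return xp, qp


def rhs(params: RFMDParams, x) -> np.ndarray:
    """Time derivative dx/dt of the occupancy vector.

    Exact arithmetic contract: no smoothing or clipping is applied, so the
    value is meaningful slightly outside the state space too (the integrator
    relies on this).
    """
    x = params.validate_state(x)
    f = flows(params, x, _validate=False)
    return f[:-1] - f[1:]


def flows(params: RFMDParams, x, _validate: bool = True) -> np.ndarray:
    """Instantaneous flow across each of the n+1 links.

    Entry 0 is the inflow ``lam_0 (q_1 - x_1)``; entry i (1 <= i <= n-1) is
    ``lam_i x_i (q_{i+1} - x_{i+1})``; entry n is the outflow ``lam_n x_n``.
    """
    if _validate:
        x = params.validate_state(x)
    xp, qp = _padded(params, x)
    return params.lam * xp[:-1] * (qp - xp[1:])


def default_initial_state(params: RFMDParams) -> np.ndarray:
    """Half-full lattice, x_i = q_i / 2 (speed choice; any start in C works)."""
    return params.q / 2.0


def integrate_to_steady_state(
    params: RFMDParams,
    x0=None,
    tol: float | None = None,
    rtol: float | None = None,
    atol: float | None = None,
) -> SteadyState:
    """Integrate the ODE until the max-norm of dx/dt drops below ``tol``.

    The equilibrium is globally attracting on the state space, so this is a
    brute-force oracle for the steady state: integrate over horizons T, 2T,
    4T, ... (T = 100/min(lam)) until the residual target is met.

    Raises
    ------
    ConvergenceError
        If the residual target is not reached within the horizon-doubling
        budget; carries the last residual.
    """
    tol = DEFAULTS["ode_steady_tol"] if tol is None else float(tol)
    rtol = DEFAULTS["ode_rtol"] if rtol is None else float(rtol)
    atol = DEFAULTS["ode_atol"] if atol is None else float(atol)
    if tol <= 0:
        raise ValueError("tol must be positive")
    if x0 is None:
        x = default_initial_state(params)
    else:
        x = params.validate_state(x0)
        if np.any(x < 0) or np.any(x > params.q):
            raise ValueError("initial state must lie in the state space C")

    def fun(_t, y):
        return rhs(params, y)

    horizon = DEFAULTS["ode_horizon_factor"] / float(np.min(params.lam))
    residual = float(np.max(np.abs(rhs(params, x))))
    for _ in range(DEFAULTS["ode_max_doublings"]):
        if residual < tol:
            break
        sol = solve_ivp(
            fun, (0.0, horizon), x, method="LSODA", rtol=rtol, atol=atol
        )
        if not sol.success:  # pragma: no cover - LSODA failure is pathological here
            raise ConvergenceError(f"integrator failed: {sol.message}", residual)
        x = sol.y[:, -1]
        residual = float(np.max(np.abs(rhs(params, x))))
        horizon *= 2.0
    if residual >= tol:
        raise ConvergenceError(
            f"steady-state residual {residual:.3e} above tol {tol:.3e} "
            "after horizon-doubling budget",
            residual,
        )
    R = float(params.lam[-1] * x[-1])
    sigma = 1.0 / np.sqrt(R)
    return SteadyState(
        e=x, R=R, r_star=sigma, sigma=sigma, flows=flows(params, x)
    )


def densities_from_rate(params: RFMDParams, R: float):
    """Back-substitute the equilibrium densities from a known flow rate.

    At equilibrium the flow across every link equals R, so ``e_n = R/lam_n``
    and ``e_i = R / (lam_i (q_{i+1} - e_{i+1}))`` descending from i = n-1.
    Returns ``(e, residual)`` where the residual is how far the inflow
    ``lam_0 (q_1 - e_1)`` is from R; it vanishes when R is the true
    steady-state rate.

    Raises
    ------
    InfeasibleRateError
        If any intermediate ``q_{i+1} - e_{i+1}`` is non-positive, i.e. R
        exceeds what the chain can carry.
    """
    R = float(R)
    if R <= 0:
        raise ValueError("R must be positive")
    n, lam, q = params.n, params.lam, params.q
    e = np.empty(n)
    e[-1] = R / lam[-1]
    for i in range(n - 2, -1, -1):
        headroom = q[i + 1] - e[i + 1]
        if headroom <= 0:
            raise InfeasibleRateError(
                f"rate {R} infeasible: site {i + 2} saturated during back-substitution"
            )
        e[i] = R / (lam[i + 1] * headroom)
    residual = abs(params.lam[0] * (q[0] - e[0]) - R)
    return e, residual
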