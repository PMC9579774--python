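"""Spectral fixed-point solver for the RFMD steady-state flow rate.

The steady-state rate of an RFMD is encoded by a symmetric tridiagonal
(n+2)x(n+2) matrix

    A_n(r):  diagonal   (0, (1-q_1) r, ..., (1-q_n) r, 0)
             off-diagonal (lam_0^{-1/2}, ..., lam_n^{-1/2})

A_n(r) is nonnegative and irreducible (all off-diagonal entries positive),
so it has a simple maximal positive eigenvalue sigma(A_n(r)), its Perron
root.  There is a unique r* > 0 with sigma(A_n(r*)) = r*, and the flow rate
is R = 1/(r*)^2.  This scalar fixed point is the production path for R; the
ODE integrator in :mod:`rfmd.core` is the independent cross-check.

The Perron map r -> sigma(A_n(r)) is nondecreasing and g(r) = sigma(A_n(r)) - r
has exactly one sign change on (0, inf), so a bracketing root finder is
unconditionally safe.  The row-sum bound sigma <= max_i sum_j |a_ij| supplies
a guaranteed bracket endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh_tridiagonal
from scipy.optimize import brentq

from .constants import DEFAULTS
from .core import RFMDParams, SteadyState, flows

__all__ = [
    "SpectralMatrix",
    "build_matrix",
    "perron_root",
    "gs_matrix",
    "gs_max_eig",
    "solve_r_star",
    "steady_rate",
]


@dataclass(frozen=True)
class SpectralMatrix:
    """Symmetric tridiagonal matrix stored as diagonal + off-diagonal only."""

    diag: np.ndarray
    offdiag: np.ndarray

    def __post_init__(self):
        diag = np.asarray(self.diag, dtype=float)
        offdiag = np.asarray(self.offdiag, dtype=float)
        if diag.size < 3:
            raise ValueError("spectral matrix must be at least 3x3")
        if offdiag.size != diag.size - 1:
            raise ValueError("off-diagonal must be one shorter than the diagonal")
        if np.any(offdiag <= 0):
            raise ValueError("off-diagonal entries must be strictly positive (irreducibility)")
        object.__setattr__(self, "diag", diag)
        object.__setattr__(self, "offdiag", offdiag)

    @property
    def size(self) -> int:
        return self.diag.size

    def dense(self) -> np.ndarray:
        """Materialize the full matrix (tests and row-sum checks only)."""
        m = np.diag(self.diag)
        m += np.diag(self.offdiag, 1) + np.diag(self.offdiag, -1)
        return m

    def max_row_sum(self) -> float:
        pad = np.concatenate(([0.0], self.offdiag, [0.0]))
        return float(np.max(np.abs(self.diag) + pad[:-1] + pad[1:]))


def build_matrix(params: RFMDParams, r: float) -> SpectralMatrix:
    """Assemble A_n(r) for the given parameters."""
    r = float(r)
    if r < 0:
        raise ValueError("r must be nonnegative")
    diag = np.concatenate(([0.0], (1.0 - params.q) * r, [0.0]))
    offdiag = params.lam ** -0.5
    return SpectralMatrix(diag=diag, offdiag=offdiag)


def perron_root(M: SpectralMatrix) -> float:
    """Largest eigenvalue of a symmetric tridiagonal matrix.

    Uses LAPACK's Sturm-sequence bisection on the tridiagonal form, which
    returns the maximal eigenvalue to near machine precision without ever
    forming the dense matrix.
    """
    if not (np.all(np.isfinite(M.diag)) and np.all(np.isfinite(M.offdiag))):
        raise ValueError("matrix entries must be finite")
    m = M.size
    w = eigh_tridiagonal(
        M.diag, M.offdiag, eigvals_only=True, select="i", select_range=(m - 1, m - 1)
    )
    return float(w[0])


def perron_pair(M: SpectralMatrix):
    """Largest eigenvalue and its (positive) eigenvector."""
    if not (np.all(np.isfinite(M.diag)) and np.all(np.isfinite(M.offdiag))):
        raise ValueError("matrix entries must be finite")
    m = M.size
    w, v = eigh_tridiagonal(
        M.diag, M.offdiag, select="i", select_range=(m - 1, m - 1)
    )
    vec = v[:, 0]
    # Perron vector of an irreducible nonnegative matrix is strictly positive;
    # fix the arbitrary sign returned by LAPACK
    if vec[np.argmax(np.abs(vec))] < 0:
        vec = -vec
    return float(w[0]), vec


def gs_matrix(s: int) -> SpectralMatrix:
    """The (s+1)x(s+1) tridiagonal 0/1 matrix G_s used in the window bounds."""
    if s < 1:
        raise ValueError("s must be >= 1")
    if s == 1:
        # 2x2 falls below the generic size floor; G_1 = [[0,1],[1,0]] has
        # lambda_max = 1 = 2cos(pi/3), handled by the closed form.
        raise ValueError("G_1 is 2x2; use gs_max_eig(1) == 1.0")
    return SpectralMatrix(diag=np.zeros(s + 1), offdiag=np.ones(s))


def gs_max_eig(s: int) -> float:
    """Closed form for the largest eigenvalue of G_s: 2 cos(pi / (s + 2))."""
    if s < 1:
        raise ValueError("s must be >= 1")
    return 2.0 * np.cos(np.pi / (s + 2))


def solve_r_star(params: RFMDParams, tol: float | None = None) -> float:
    """Solve the scalar fixed point sigma(A_n(r*)) = r*.

    When all capacities equal 1 the diagonal of A_n(r) vanishes and the
    Perron root does not depend on r, so r* = sigma(A_n(0)) directly.
    Otherwise brentq on g(r) = sigma(A_n(r)) - r over the bracket
    [0, 2 max_i lam_i^{-1/2} / min_i q_i]; the row-sum bound guarantees
    g <= 0 at the upper endpoint and g(0) = sigma(A_n(0)) > 0.
    """
    tol = DEFAULTS["fixed_point_tol"] if tol is None else float(tol)
    if tol <= 0:
        raise ValueError("tol must be positive")
    z = params.lam ** -0.5
    if np.all(params.q == 1.0):
        return perron_root(build_matrix(params, 0.0))

    def g(r: float) -> float:
        return perron_root(build_matrix(params, r)) - r

    r_hi = 2.0 * float(np.max(z)) / float(np.min(params.q))
    # the row-sum argument makes g(r_hi) <= 0; the loop is a pure safety net
    for _ in range(8):
        if g(r_hi) < 0:
            break
        r_hi *= 2.0
    else:  # pragma: no cover - unreachable for valid parameters
        raise AssertionError("failed to bracket the spectral fixed point")
    r_star = brentq(g, 0.0, r_hi, xtol=tol, rtol=8 * np.finfo(float).eps)
    return float(r_star)


def steady_rate(params: RFMDParams, tol: float | None = None) -> SteadyState:
    """Steady state via the spectral fixed point: R = 1/(r*)^2.

    The equilibrium densities are read off the Perron eigenvector zeta of
    A_n(r*): the eigenvalue equation at the fixed point reproduces the
    steady-state flow chain exactly with

        e_i = lam_i^{-1/2} zeta_{i+1} / (r* zeta_i),   i = 1..n.

    This is algebraically equivalent to back-substitution from R
    (:func:`rfmd.core.densities_from_rate`) but stays numerically stable for
    long chains, where the backward recursion amplifies rounding error.
    """
    r_star = solve_r_star(params, tol=tol)
    R = 1.0 / (r_star * r_star)
    e = _densities_from_fixed_point(params, r_star)
    return SteadyState(
        e=e, R=R, r_star=r_star, sigma=r_star, flows=flows(params, e)
    )


def _densities_from_fixed_point(params: RFMDParams, r_star: float) -> np.ndarray:
    """Densities from the Perron-vector ratios at the fixed point.

    Only successive ratios of zeta are needed, and for long chains the
    Perron vector localizes: its tail components underflow the eigenvector
    routine's accuracy.  The three-term recurrence for the ratios is stable
    when run in the direction of component growth, so the ratios are built
    from each edge toward the vector's peak (located from the LAPACK
    eigenvector, which is reliable there) and stitched.
    """
    n = params.n
    z = params.lam ** -0.5
    q = params.q
    r = r_star
    _sigma, zeta = perron_pair(build_matrix(params, r))
    k = int(np.argmax(zeta))  # peak position in the (n+2)-vector

    # rho_i = zeta_{i+1}/zeta_i, i = 0..n; e_i = z_i rho_i / r for i = 1..n
    rho = np.empty(n + 1)
    # forward sweep (stable left of the peak): row 0 gives rho_0 = r/z_0,
    # row i gives z_{i-1}/rho_{i-1} + z_i rho_i = q_i r
    rho[0] = r / z[0]
    for i in range(1, min(k, n) + 1):
        rho[i] = (q[i - 1] * r - z[i - 1] / rho[i - 1]) / z[i]
    # backward sweep (stable right of the peak): row n+1 gives
    # zeta_n/zeta_{n+1} = z_n/r, i.e. rho_n = r/z_n read the other way
    if k <= n:
        tau = r / z[n]  # tau_i = zeta_i / zeta_{i+1}
        rho[n] = 1.0 / tau
        for i in range(n, k, -1):
            # row i: z_{i-1} tau_{i-1} + z_i / tau_i = q_i r
            tau = (q[i - 1] * r - z[i] / tau) / z[i - 1]
            rho[i - 1] = 1.0 / tau
    return z[1:] * rho[1:] / r
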