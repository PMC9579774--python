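"""Closed-form limits and bounds for the RFMD steady-state flow rate.

The spectral representation R = 1/sigma^2 turns eigenvalue bounds for the
tridiagonal matrix A_n(r) into flow-rate bounds.  Two mechanisms recur:

* the row-sum bound on the Perron root gives *lower* bounds on R;
* planting the 0/1 window matrix G_s (largest eigenvalue 2 cos(pi/(s+2)))
  on a run of s consecutive indices where the relevant parameter is extreme
  gives *upper* bounds on R, tightest for the best window.

Asymptotically both mechanisms meet: with i.i.d. rates from a distribution X
supported away from zero and homogeneous capacity q,

    R_n -> q^2 (2 M)^{-2}   with M = M_{X^{-1/2}} = (ess inf X)^{-1/2},

and with i.i.d. capacities Q on [beta, gamma] and homogeneous rate lambda,

    R_n -> m_Q^2 lambda / 4.

For finite n the window mechanism yields either probabilistic interval
guarantees (i.i.d. parameters) or almost-sure bounds evaluated on the
realized parameter draw (arbitrary bounded parameters).  The realized upper
bounds arise from implicit inequalities in 1/sqrt(R); they are returned in
explicit form via the exact algebraic rearrangement, one constraint per
(window length s, window), reporting the tightest together with the choice
attaining it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "WindowSet",
    "BoundReport",
    "limit_random_rates",
    "limit_random_caps",
    "finite_bounds_iid_rates",
    "finite_bounds_iid_caps",
    "realized_bounds_rates",
    "realized_bounds_caps",
    "realized_bounds_full",
    "deterministic_envelope",
]


@dataclass(frozen=True)
class WindowSet:
    """All runs of ``s`` consecutive integers inside ``index_range``.

    ``index_range`` is inclusive, e.g. (1, n-1).  ``h_extension`` appends the
    index following each window's last entry; windows whose extension would
    leave the parent range (start..stop+1) are still valid because the
    extension targets the capacity index set, one longer on the right.
    """

    start: int
    stop: int
    s: int

    def __post_init__(self):
        if self.s < 1:
            raise ValueError("window length must be >= 1")
        if self.stop - self.start + 1 < self.s:
            raise ValueError("index range shorter than the window length")

    @property
    def windows(self) -> list[range]:
        return [
            range(k, k + self.s) for k in range(self.start, self.stop - self.s + 2)
        ]

    @property
    def h_extension(self) -> list[range]:
        """H_s = J_s together with the index after its last entry."""
        return [range(w.start, w.stop + 1) for w in self.windows]


@dataclass(frozen=True)
class BoundReport:
    """Lower/upper bounds on R with provenance.

    ``attaining_choice`` records the (s, window-start) pair achieving the
    reported upper bound (None for purely closed-form bounds);
    ``probability_guarantee`` is a float in [0, 1] or the string
    "almost sure"; ``extreme_stats`` carries the extreme parameter values
    the formulas consumed.
    """

    lower: float
    upper: float
    attaining_choice: tuple | None = None
    probability_guarantee: float | str = "almost sure"
    extreme_stats: dict | None = None

    def __post_init__(self):
        if self.lower > self.upper + 1e-15:
            raise ValueError(f"lower bound {self.lower} exceeds upper bound {self.upper}")

    def contains(self, R: float) -> bool:
        return self.lower <= R <= self.upper

    def to_dict(self) -> dict:
        return {
            "lower": self.lower,
            "upper": self.upper,
            "attaining_choice": list(self.attaining_choice)
            if self.attaining_choice is not None
            else None,
            "probability_guarantee": self.probability_guarantee,
            "extreme_stats": self.extreme_stats,
        }


def limit_random_rates(q: float, m_inv_sqrt: float) -> float:
    """Limiting flow rate with homogeneous capacity q and i.i.d. rates:
    q^2 (2 M_{X^{-1/2}})^{-2}."""
    if q <= 0 or m_inv_sqrt <= 0:
        raise ValueError("q and M_{X^{-1/2}} must be positive")
    return q * q / (4.0 * m_inv_sqrt * m_inv_sqrt)


def limit_random_caps(m_q: float, lam: float) -> float:
    """Limiting flow rate with homogeneous rate lambda and i.i.d. capacities:
    m_Q^2 lambda / 4.  Algebraically limit_random_rates(m_Q, lambda^{-1/2})."""
    if m_q <= 0 or lam <= 0:
        raise ValueError("m_Q and lambda must be positive")
    return m_q * m_q * lam / 4.0


def _coverage_probability(blocks: int, tail_prob: float, s: int) -> float:
    """1 - exp(-blocks * p^s): the chance at least one of ``blocks`` disjoint
    windows is an all-extreme run."""
    return 1.0 - math.exp(-blocks * tail_prob ** s)


def finite_bounds_iid_rates(
    q_lo: float,
    q_hi: float,
    m_inv_sqrt: float,
    eps: float,
    s: int,
    n: int,
    a_eps: float,
) -> BoundReport:
    """Finite-n probabilistic interval for R with i.i.d. rates.

    Lower bound q_lo^2 (2M)^{-2} holds surely; the upper bound uses the exact
    finite-window form q_hi^2 (2 (M - eps) cos(pi/(s+2)))^{-2}, valid with
    probability at least 1 - exp(-floor((n-1)/s) a(eps)^s).
    """
    if not (0 < q_lo <= q_hi <= 1):
        raise ValueError("need 0 < q_lo <= q_hi <= 1")
    if not (0 <= eps < m_inv_sqrt):
        raise ValueError("need 0 <= eps < M_{X^{-1/2}}")
    if not (1 <= s < n - 1):
        raise ValueError("need 1 <= s < n - 1")
    if not (0 <= a_eps <= 1):
        raise ValueError("a_eps must be a probability")
    lower = q_lo ** 2 / (4.0 * m_inv_sqrt ** 2)
    cos_s = math.cos(math.pi / (s + 2))
    upper = q_hi ** 2 / (2.0 * (m_inv_sqrt - eps) * cos_s) ** 2
    prob = _coverage_probability((n - 1) // s, a_eps, s)
    return BoundReport(
        lower=lower,
        upper=upper,
        attaining_choice=(s, None),
        probability_guarantee=prob,
        extreme_stats={"q_lo": q_lo, "q_hi": q_hi, "M_inv_sqrt": m_inv_sqrt, "eps": eps},
    )


def finite_bounds_iid_caps(
    m_q: float,
    lam_min_inv_sqrt: float,
    lam_max_inv_sqrt: float,
    eta: float,
    s: int,
    n: int,
    b_eta: float,
) -> BoundReport:
    """Finite-n probabilistic interval for R with i.i.d. capacities.

    lam_min_inv_sqrt / lam_max_inv_sqrt are the extremes of
    {lambda_i^{-1/2}}.  Lower bound m_Q^2 (2 lam_max_inv_sqrt)^{-2} holds
    surely; the upper bound uses the exact finite-window form
    (m_Q + eta)^2 (2 lam_min_inv_sqrt cos(pi/(s+2)))^{-2}, valid with
    probability at least 1 - exp(-floor(n/s) b(eta)^s).
    """
    if not (0 < m_q <= 1):
        raise ValueError("need 0 < m_Q <= 1")
    if lam_min_inv_sqrt <= 0 or lam_max_inv_sqrt < lam_min_inv_sqrt:
        raise ValueError("need 0 < lam_min_inv_sqrt <= lam_max_inv_sqrt")
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    if not (1 <= s < n):
        raise ValueError("need 1 <= s < n")
    if not (0 <= b_eta <= 1):
        raise ValueError("b_eta must be a probability")
    lower = m_q ** 2 / (2.0 * lam_max_inv_sqrt) ** 2
    cos_s = math.cos(math.pi / (s + 2))
    upper = (m_q + eta) ** 2 / (2.0 * lam_min_inv_sqrt * cos_s) ** 2
    prob = _coverage_probability(n // s, b_eta, s)
    return BoundReport(
        lower=lower,
        upper=upper,
        attaining_choice=(s, None),
        probability_guarantee=prob,
        extreme_stats={
            "m_Q": m_q,
            "lam_min_inv_sqrt": lam_min_inv_sqrt,
            "lam_max_inv_sqrt": lam_max_inv_sqrt,
            "eta": eta,
        },
    )


def _window_extreme(values: np.ndarray, s: int, inner: str) -> np.ndarray:
    """Per-window inner extreme over all s-length runs of ``values``."""
    view = sliding_window_view(values, s)
    return view.min(axis=1) if inner == "min" else view.max(axis=1)


def realized_bounds_rates(lam_samples, q_lo: float, q_hi: float) -> BoundReport:
    """Almost-sure bounds on R from a realized rate draw (capacities bounded
    by [q_lo, q_hi]).

    With Z_i = lam_i^{-1/2},
    lower = q_lo^2 (max_i (Z_{i-1} + Z_i))^{-2};
    upper = q_hi^2 (2 max_{s, J_s} cos(pi/(s+2)) min_{i in J_s} Z_i)^{-2},
    where J_s runs over windows of {1..n-1} in the rate index set.
    """
    lam = np.asarray(lam_samples, dtype=float)
    if lam.ndim != 1 or np.any(lam <= 0):
        raise ValueError("lam_samples must be a 1-d positive vector")
    n = lam.size - 1
    if n < 2:
        raise ValueError("need n >= 2 (at least one interior window)")
    if not (0 < q_lo <= q_hi <= 1):
        raise ValueError("need 0 < q_lo <= q_hi <= 1")
    z = lam ** -0.5
    lower = q_lo ** 2 / float(np.max(z[:-1] + z[1:])) ** 2
    interior = z[1:n]  # Z_1 .. Z_{n-1}
    best = -math.inf
    choice = None
    for s in range(1, n):
        cos_s = math.cos(math.pi / (s + 2))
        mins = _window_extreme(interior, s, "min")
        k = int(np.argmax(mins))
        val = cos_s * float(mins[k])
        if val > best:
            best = val
            choice = (s, k + 1)  # window starts at rate index k+1
    upper = q_hi ** 2 / (2.0 * best) ** 2
    return BoundReport(
        lower=lower,
        upper=upper,
        attaining_choice=choice,
        probability_guarantee="almost sure",
        extreme_stats={"q_lo": q_lo, "q_hi": q_hi, "z_max_pair": float(np.max(z[:-1] + z[1:]))},
    )


def realized_bounds_caps(
    q_samples, lam_min_inv_sqrt: float, lam_max_inv_sqrt: float
) -> BoundReport:
    """Almost-sure bounds on R from a realized capacity draw (rates bounded,
    lam_*_inv_sqrt the extremes of {lambda_i^{-1/2}}).

    lower = (min_i Q_i)^2 (2 lam_max_inv_sqrt)^{-2}; the upper bound comes
    from rearranging, for each window length s >= 2 over {1..n},

        R <= (min_{J_s} max_{i in J_s} Q_i)^2
             / (2 lam_min_inv_sqrt cos(pi/(s+1)))^2

    (s = 1 gives cos(pi/2) = 0, a vacuous constraint), minimized over s.
    Note the cosine argument pi/(s+1) specific to this inequality.
    """
    q = np.asarray(q_samples, dtype=float)
    if q.ndim != 1 or np.any(q <= 0) or np.any(q > 1):
        raise ValueError("q_samples must be a 1-d vector in (0, 1]")
    if lam_min_inv_sqrt <= 0 or lam_max_inv_sqrt < lam_min_inv_sqrt:
        raise ValueError("need 0 < lam_min_inv_sqrt <= lam_max_inv_sqrt")
    n = q.size
    lower = float(np.min(q)) ** 2 / (2.0 * lam_max_inv_sqrt) ** 2
    upper = math.inf
    choice = None
    for s in range(2, n + 1):
        cos_s = math.cos(math.pi / (s + 1))
        maxs = _window_extreme(q, s, "max")
        k = int(np.argmin(maxs))
        bound = float(maxs[k]) ** 2 / (2.0 * lam_min_inv_sqrt * cos_s) ** 2
        if bound < upper:
            upper = bound
            choice = (s, k + 1)  # capacity indices are 1-based
    return BoundReport(
        lower=lower,
        upper=upper,
        attaining_choice=choice,
        probability_guarantee="almost sure",
        extreme_stats={
            "q_min": float(np.min(q)),
            "lam_min_inv_sqrt": lam_min_inv_sqrt,
            "lam_max_inv_sqrt": lam_max_inv_sqrt,
        },
    )


def realized_bounds_full(lam_samples, q_samples) -> BoundReport:
    """Almost-sure bounds on R when both rates and capacities are realized
    draws.

    lower = (min_i Q_i)^2 (max_i (Z_{i-1} + Z_i))^{-2}; the upper bound
    rearranges, per window J_s of {1..n-1} with extension
    H_s = J_s u {last+1},

        R <= (max_{i in H_s} Q_i)^2
             / (2 cos(pi/(s+2)) min_{i in J_s} Z_i)^2,

    minimized over all (s, J_s).
    """
    lam = np.asarray(lam_samples, dtype=float)
    q = np.asarray(q_samples, dtype=float)
    n = q.size
    if lam.size != n + 1:
        raise ValueError("lam_samples must have length n+1 for n capacities")
    if n < 2:
        raise ValueError("need n >= 2 (at least one interior window)")
    if np.any(lam <= 0) or np.any(q <= 0) or np.any(q > 1):
        raise ValueError("rates must be positive, capacities in (0, 1]")
    z = lam ** -0.5
    lower = float(np.min(q)) ** 2 / float(np.max(z[:-1] + z[1:])) ** 2
    interior = z[1:n]  # Z_1 .. Z_{n-1}
    upper = math.inf
    choice = None
    for s in range(1, n):
        cos_s = math.cos(math.pi / (s + 2))
        mins = _window_extreme(interior, s, "min")
        # window starting at rate index k+1 covers J_s = {k+1..k+s};
        # H_s = {k+1..k+s+1} in capacity indices -> q[k : k+s+1] (0-based)
        h_max = _window_extreme(q, s + 1, "max")[: mins.size]
        bounds = h_max ** 2 / (2.0 * cos_s * mins) ** 2
        k = int(np.argmin(bounds))
        if bounds[k] < upper:
            upper = float(bounds[k])
            choice = (s, k + 1)
    return BoundReport(
        lower=lower,
        upper=upper,
        attaining_choice=choice,
        probability_guarantee="almost sure",
        extreme_stats={
            "q_min": float(np.min(q)),
            "z_max_pair": float(np.max(z[:-1] + z[1:])),
        },
    )


def deterministic_envelope(
    a: float, b: float, c: float, d: float, s: int | None = None
):
    """Support-level envelope for R when rates lie in [a, b] and capacities
    in [c, d].

    lower = c^2 a / 4 always; upper = d^2 b / 4 asymptotically (s omitted)
    or d^2 b / (4 cos^2(pi/(s+2))) at finite window length s.
    """
    if not (0 < a <= b):
        raise ValueError("need 0 < a <= b for the rate support")
    if not (0 < c <= d <= 1):
        raise ValueError("need 0 < c <= d <= 1 for the capacity support")
    lower = c * c * a / 4.0
    if s is None:
        upper = d * d * b / 4.0
    else:
        if s < 1:
            raise ValueError("s must be >= 1")
        upper = d * d * b / (4.0 * math.cos(math.pi / (s + 2)) ** 2)
    return lower, upper
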