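"""Declarative random-parameter model for RFMD ensembles.

Transition rates and site capacities are drawn from distributions with a
declared, known support, because the asymptotic theory depends only on the
support endpoints: the essential supremum M_X and essential infimum m_X of a
random variable X, and M_{X^{-1/2}} = (ess inf X)^{-1/2} for rates.  Three
families are shipped:

``constant``
    Degenerate at ``value``.
``uniform``
    Uniform on [lo, hi].
``half_normal_shifted``
    ``loc + |N(0, sigma_hn)|``, supported on [loc, inf).  The convenience
    constructor :func:`half_normal_from_sd` chooses ``sigma_hn`` so the
    distribution's standard deviation equals a stated value
    (``sigma_hn = sd / sqrt(1 - 2/pi)``).

The tail probabilities used by the finite-n probability guarantees are
``a(eps) = P{X^{-1/2} >= M_{X^{-1/2}} - eps}`` (rates) and
``b(eta) = P{Q <= m_Q + eta}`` (capacities); both have closed forms here, and
a Monte Carlo estimator is provided as a distribution-free fallback.

An :class:`EnsembleSpec` assigns one distribution per index — i.i.d.,
block-heterogeneous, or with a small outlier block — with an optional
permutation of the index set, and samples reproducibly from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DistributionSpec",
    "EnsembleSpec",
    "half_normal_from_sd",
    "essential_stats",
    "sample_vector",
    "tail_probabilities",
    "tail_probabilities_mc",
]

_FAMILIES = ("constant", "uniform", "half_normal_shifted")


class InvalidSupportError(ValueError):
    """Distribution support incompatible with the requested use."""


@dataclass(frozen=True)
class DistributionSpec:
    """One distribution family with declared support.

    Parameters
    ----------
    family : {"constant", "uniform", "half_normal_shifted"}
    params : dict
        constant: {"value"}; uniform: {"lo", "hi"};
        half_normal_shifted: {"loc", "scale"} (scale = sigma of the folded
        normal before shifting).
    """

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {_FAMILIES}")
        p = self.params
        if self.family == "constant":
            if "value" not in p:
                raise ValueError("constant family needs 'value'")
        elif self.family == "uniform":
            if not {"lo", "hi"} <= p.keys():
                raise ValueError("uniform family needs 'lo' and 'hi'")
            if not p["lo"] < p["hi"]:
                raise ValueError("uniform needs lo < hi")
        else:
            if not {"loc", "scale"} <= p.keys():
                raise ValueError("half_normal_shifted needs 'loc' and 'scale'")
            if p["scale"] <= 0:
                raise ValueError("half_normal_shifted needs scale > 0")

    @property
    def support(self) -> tuple[float, float]:
        p = self.params
        if self.family == "constant":
            return (p["value"], p["value"])
        if self.family == "uniform":
            return (p["lo"], p["hi"])
        return (p["loc"], math.inf)

    def cdf(self, x: float) -> float:
        p = self.params
        if self.family == "constant":
            return 1.0 if x >= p["value"] else 0.0
        if self.family == "uniform":
            return float(np.clip((x - p["lo"]) / (p["hi"] - p["lo"]), 0.0, 1.0))
        if x <= p["loc"]:
            return 0.0
        return float(stats.halfnorm.cdf(x, loc=p["loc"], scale=p["scale"]))

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.family == "constant":
            return np.full(size, float(p["value"]))
        if self.family == "uniform":
            return rng.uniform(p["lo"], p["hi"], size)
        return p["loc"] + np.abs(rng.normal(0.0, p["scale"], size))

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        return cls(family=d["family"], params=dict(d["params"]))


def half_normal_from_sd(loc: float, sd: float) -> DistributionSpec:
    """Shifted half-normal parameterized by its standard deviation.

    The sd of ``|N(0, sigma)|`` is ``sigma * sqrt(1 - 2/pi)``, so the scale
    is ``sd / sqrt(1 - 2/pi)``.  The support starts at ``loc``, which is what
    the limit theorems consume.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    scale = sd / math.sqrt(1.0 - 2.0 / math.pi)
    return DistributionSpec("half_normal_shifted", {"loc": loc, "scale": scale})


def essential_stats(spec: DistributionSpec, require_positive: bool = True):
    """Essential infimum m_X, essential supremum M_X, and M_{X^{-1/2}}.

    M_{X^{-1/2}} is the essential supremum of X^{-1/2}, i.e.
    (ess inf X)^{-1/2}; it is only defined for supports bounded away from 0.
    """
    lo, hi = spec.support
    if require_positive and lo <= 0:
        raise InvalidSupportError(
            "support must lie in R_{>=delta} with delta > 0 for the "
            "inverse-square-root bound"
        )
    m_inv_sqrt = lo ** -0.5 if lo > 0 else math.inf
    return lo, hi, m_inv_sqrt


def tail_probabilities(spec: DistributionSpec, eps: float, eta: float):
    """Closed-form tail probabilities a(eps) and b(eta).

    a(eps) = P{X^{-1/2} >= M_{X^{-1/2}} - eps} = P{X <= (M - eps)^{-2}} for
    eps < M (and 1 for eps >= M); b(eta) = P{X <= ess_inf + eta}.
    """
    if eps < 0 or eta < 0:
        raise ValueError("eps and eta must be nonnegative")
    lo, _hi, m_inv_sqrt = essential_stats(spec)
    if eps >= m_inv_sqrt:
        a_eps = 1.0
    else:
        threshold = (m_inv_sqrt - eps) ** -2.0
        a_eps = spec.cdf(threshold)
    b_eta = spec.cdf(lo + eta)
    return a_eps, b_eta


def tail_probabilities_mc(
    spec: DistributionSpec, eps: float, eta: float, n_draws: int = 100_000, seed: int = 0
):
    """Monte Carlo estimate of (a(eps), b(eta)) with binomial standard errors.

    Distribution-free fallback for families without a closed-form CDF;
    returns ((a, se_a), (b, se_b)).
    """
    if eps < 0 or eta < 0:
        raise ValueError("eps and eta must be nonnegative")
    lo, _hi, m_inv_sqrt = essential_stats(spec)
    rng = np.random.default_rng(seed)
    x = spec.sample(n_draws, rng)
    a = float(np.mean(x ** -0.5 >= m_inv_sqrt - eps))
    b = float(np.mean(x <= lo + eta))
    se = lambda p: math.sqrt(max(p * (1 - p), 1.0 / n_draws) / n_draws)
    return (a, se(a)), (b, se(b))


@dataclass(frozen=True)
class EnsembleSpec:
    """Per-index distribution assignment with an optional permutation.

    ``assignment`` maps each index of the target vector to a
    :class:`DistributionSpec`; indices must cover 0..size-1 exactly once.
    If ``permutation`` is given, entry ``i`` of the sampled vector is the
    draw made for index ``permutation[i]`` — the device used to show the
    asymptotics are insensitive to how heterogeneous blocks are interleaved.
    """

    assignment: dict
    permutation: tuple | None = None

    def __post_init__(self):
        idx = sorted(self.assignment)
        if idx != list(range(len(idx))):
            raise ValueError("assignment indices must be exactly 0..size-1")
        if self.permutation is not None:
            perm = tuple(int(i) for i in self.permutation)
            if sorted(perm) != idx:
                raise ValueError("permutation must be a bijection on the index set")
            object.__setattr__(self, "permutation", perm)

    @property
    def size(self) -> int:
        return len(self.assignment)

    @classmethod
    def iid(cls, spec: DistributionSpec, size: int) -> "EnsembleSpec":
        return cls(assignment={i: spec for i in range(size)})

    @classmethod
    def blocks(cls, block_list, permutation=None) -> "EnsembleSpec":
        """Contiguous heterogeneous blocks: [(spec, count), ...]."""
        assignment = {}
        i = 0
        for spec, count in block_list:
            for _ in range(count):
                assignment[i] = spec
                i += 1
        return cls(assignment=assignment, permutation=permutation)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(self.size)
        # group indices by distribution identity for vectorized draws while
        # preserving per-index assignment
        groups: dict[int, list[int]] = {}
        specs: dict[int, DistributionSpec] = {}
        for i in range(self.size):
            spec = self.assignment[i]
            key = id(spec)
            groups.setdefault(key, []).append(i)
            specs[key] = spec
        for key, indices in groups.items():
            out[indices] = specs[key].sample(len(indices), rng)
        if self.permutation is not None:
            out = out[np.asarray(self.permutation)]
        return out


def sample_vector(assignment, count: int, seed) -> np.ndarray:
    """Draw one vector from a per-index assignment.

    ``assignment`` is an :class:`EnsembleSpec`, a single
    :class:`DistributionSpec` (treated as i.i.d.), or a dict of index ->
    DistributionSpec.  ``seed`` may be an int or a numpy Generator.
    """
    if isinstance(assignment, DistributionSpec):
        ens = EnsembleSpec.iid(assignment, count)
    elif isinstance(assignment, EnsembleSpec):
        ens = assignment
    else:
        ens = EnsembleSpec(assignment=dict(assignment))
    if ens.size != count:
        raise ValueError(f"assignment covers {ens.size} indices, expected {count}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return ens.sample(rng)
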