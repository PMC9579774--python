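"""Monte Carlo driver for RFMD ensembles.

Draws rate/capacity vectors from a declared ensemble, solves each instance
spectrally, optionally attaches realized flow-rate bounds per replicate, and
summarizes convergence toward a theoretical limit.  Everything is
reproducible from (config, seed): replicate streams are derived as
SeedSequence(seed, n, replicate) so runs are order-independent and
parallelizable.

Configs round-trip through YAML or JSON.  Output is a pandas DataFrame with
the fixed column contract (n, replicate, seed, R, r_star, lower, upper) plus
run metadata (config hash, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bounds import realized_bounds_full
from .core import RFMDParams
from .ensembles import DistributionSpec, EnsembleSpec
from .spectral import steady_rate

__all__ = [
    "ExperimentConfig",
    "run_ensemble_experiment",
    "summarize_convergence",
    "coverage_check",
]

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["n", "replicate", "seed", "R", "r_star", "lower", "upper"]


def _spec_from_config(d) -> DistributionSpec:
    if isinstance(d, (int, float)):
        return DistributionSpec("constant", {"value": float(d)})
    return DistributionSpec.from_dict(d)


@dataclass(frozen=True)
class ExperimentConfig:
    """One ensemble experiment.

    ``rates`` / ``capacities`` are distribution declarations: either a single
    spec dict (i.i.d. across indices), a bare number (constant), or a list of
    ``{"spec": ..., "fraction": f}`` blocks whose fractions sum to 1 and are
    laid out contiguously over the index set (fractions resolve per n).
    """

    rates: object
    capacities: object
    dims: tuple
    replicates: int
    seed: int = 0
    tol: float | None = None
    attach_bounds: bool = False
    permute_rates: bool = False
    permute_capacities: bool = False
    label: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(self.dims) == 0:
            raise ValueError("dims must be nonempty")
        object.__setattr__(self, "dims", tuple(int(n) for n in self.dims))

    def to_dict(self) -> dict:
        return {
            "rates": self.rates,
            "capacities": self.capacities,
            "dims": list(self.dims),
            "replicates": self.replicates,
            "seed": self.seed,
            "tol": self.tol,
            "attach_bounds": self.attach_bounds,
            "permute_rates": self.permute_rates,
            "permute_capacities": self.permute_capacities,
            "label": self.label,
            "extra": self.extra,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["dims"] = tuple(d["dims"])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            text = fh.read()
        data = yaml.safe_load(text)  # YAML superset covers JSON configs too
        return cls.from_dict(data)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def _ensemble(self, declaration, size: int, permute: bool, rng) -> EnsembleSpec:
        if isinstance(declaration, list):
            blocks = []
            assigned = 0
            for j, block in enumerate(declaration):
                spec = _spec_from_config(block["spec"])
                if j == len(declaration) - 1:
                    count = size - assigned
                else:
                    count = int(round(block["fraction"] * size))
                blocks.append((spec, count))
                assigned += count
            permutation = tuple(rng.permutation(size)) if permute else None
            return EnsembleSpec.blocks(blocks, permutation=permutation)
        spec = _spec_from_config(declaration)
        permutation = tuple(rng.permutation(size)) if permute else None
        ens = EnsembleSpec.iid(spec, size)
        if permutation is not None:
            ens = EnsembleSpec(assignment=ens.assignment, permutation=permutation)
        return ens

    def draw_instance(self, n: int, rng) -> RFMDParams:
        lam = self._ensemble(self.rates, n + 1, self.permute_rates, rng).sample(rng)
        q = self._ensemble(self.capacities, n, self.permute_capacities, rng).sample(rng)
        return RFMDParams(lam, q)


def run_ensemble_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run the Monte Carlo experiment and return the sample table.

    One row per (n, replicate).  Solver failures are logged and skipped; if
    more than 1% of replicates fail the experiment errors out.
    """
    rows = []
    failures = 0
    total = len(config.dims) * config.replicates
    for n in config.dims:
        logger.info("ensemble %s: n=%d, %d replicates", config.label, n, config.replicates)
        for rep in range(config.replicates):
            ss = np.random.SeedSequence((config.seed, n, rep))
            rng = np.random.default_rng(ss)
            rep_seed = int(ss.generate_state(1)[0])
            try:
                params = config.draw_instance(n, rng)
                state = steady_rate(params, tol=config.tol)
            except Exception:  # noqa: BLE001 - per-replicate isolation
                logger.exception("replicate (n=%d, rep=%d) failed", n, rep)
                failures += 1
                continue
            lower = upper = np.nan
            if config.attach_bounds:
                report = realized_bounds_full(params.lam, params.q)
                lower, upper = report.lower, report.upper
            rows.append((n, rep, rep_seed, state.R, state.r_star, lower, upper))
            logger.debug("n=%d rep=%d R=%.6g", n, rep, state.R)
    if failures > 0.01 * total:
        raise RuntimeError(f"{failures}/{total} replicates failed")
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    table.attrs["config_hash"] = config.config_hash()
    table.attrs["package_version"] = __version__
    return table


def summarize_convergence(table: pd.DataFrame, limit: float) -> pd.DataFrame:
    """Per-n sample mean, sd, and mean absolute deviation from ``limit``."""
    if table.empty:
        raise ValueError("sample table is empty")
    grouped = table.groupby("n")["R"]
    summary = pd.DataFrame(
        {
            "mean": grouped.mean(),
            "std": grouped.std(ddof=1).fillna(0.0),
            "mad_from_limit": grouped.apply(lambda r: float(np.mean(np.abs(r - limit)))),
            "replicates": grouped.size(),
        }
    ).reset_index()
    summary["limit"] = limit
    return summary


def histogram_data(table: pd.DataFrame, bins: int = 50) -> pd.DataFrame:
    """Binned flow-rate counts per n — figure data without the figure.

    Columns: n, bin_left, bin_right, count.  Bin edges are shared across all
    n so histograms are directly comparable.
    """
    if table.empty:
        raise ValueError("sample table is empty")
    edges = np.histogram_bin_edges(table["R"], bins=bins)
    rows = []
    for n, group in table.groupby("n"):
        counts, _ = np.histogram(group["R"], bins=edges)
        for left, right, count in zip(edges[:-1], edges[1:], counts):
            rows.append((n, left, right, int(count)))
    return pd.DataFrame(rows, columns=["n", "bin_left", "bin_right", "count"])


def coverage_check(table: pd.DataFrame) -> float:
    """Fraction of replicates whose R lies inside the attached bounds."""
    if "lower" not in table or table["lower"].isna().all():
        raise ValueError("table has no attached bounds")
    ok = (table["R"] >= table["lower"]) & (table["R"] <= table["upper"])
    return float(ok.mean())
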