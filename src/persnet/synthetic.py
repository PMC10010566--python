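"""Random-network generators and simulation drivers.

Complete graphs with iid edge weights from named distributions, Gaussian
noise perturbations of a fixed base graph, and a table-experiment driver
that averages group-test p-values over repeated experiments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .graphcore import WeightedNetwork
from .inference import permutation_test, wilcoxon_auc_test
from .orderstats import BetaDistribution, DistributionSpec, Uniform01

__all__ = [
    "named_distribution",
    "generate_iid_network",
    "generate_noisy_group",
    "SimulationConfig",
    "run_table_experiment",
]

_BETA_RE = re.compile(r"^beta\(\s*([0-9.eE+-]+)\s*,\s*([0-9.eE+-]+)\s*\)$")


def named_distribution(name: str | DistributionSpec) -> DistributionSpec:
    """Resolve a distribution name like ``uniform01`` or ``beta(5,2)``."""
    if isinstance(name, DistributionSpec):
        return name
    key = name.strip().lower()
    if key in ("uniform01", "uniform(0,1)", "uniform"):
        return Uniform01()
    m = _BETA_RE.match(key)
    if m:
        return BetaDistribution(float(m.group(1)), float(m.group(2)))
    raise ValueError(f"unknown distribution name: {name!r}")


def _as_rng(seed: int | np.random.Generator | np.random.SeedSequence | None):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_iid_network(
    p: int,
    dist: str | DistributionSpec,
    seed: int | np.random.Generator | None = None,
) -> WeightedNetwork:
    """Complete graph on p nodes with q = p(p-1)/2 iid edge weights."""
    rng = _as_rng(seed)
    dist = named_distribution(dist)
    q = p * (p - 1) // 2
    return WeightedNetwork(p, dist.sample(q, rng))


def generate_noisy_group(
    base: WeightedNetwork,
    n: int,
    sigma: float,
    seed: int | np.random.Generator | None = None,
) -> list[WeightedNetwork]:
    """n copies of ``base`` with iid N(0, sigma^2) perturbations per edge.

    Perturbed weights may leave the base distribution's support; they are
    deliberately not clipped, since the filtration is defined for any real
    weights.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = _as_rng(seed)
    return [
        WeightedNetwork(base.p, base.weights + rng.normal(0.0, sigma, base.q))
        for _ in range(n)
    ]


@dataclass
class SimulationConfig:
    """Configuration of a table experiment.

    ``pairs`` lists (name_a, name_b) distribution pairs forming the table
    rows; ``group_sizes`` the per-group network counts forming the columns.
    A master ``seed`` spawns independent substreams per (pair, size, repeat)
    cell so every cell is reproducible in isolation.
    """

    p: int = 10
    pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("beta(1,1)", "beta(5,2)")]
    )
    group_sizes: list[int] = field(default_factory=lambda: [6])
    stat: Literal["etl", "maxgap", "auc"] = "etl"
    n_perm: int = 10_000
    n_repeats: int = 10
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "pairs" in d:
            d["pairs"] = [tuple(pair) for pair in d["pairs"]]
        return cls(**d)


def _single_cell_p(
    p: int,
    dist_a: DistributionSpec,
    dist_b: DistributionSpec,
    n_networks: int,
    stat: str,
    n_perm: int,
    seed_seq: np.random.SeedSequence,
) -> float:
    gen_seed_a, gen_seed_b, perm_seed = seed_seq.spawn(3)
    rng_a = np.random.default_rng(gen_seed_a)
    rng_b = np.random.default_rng(gen_seed_b)
    nets_a = [generate_iid_network(p, dist_a, rng_a) for _ in range(n_networks)]
    nets_b = [generate_iid_network(p, dist_b, rng_b) for _ in range(n_networks)]
    if stat == "auc":
        return wilcoxon_auc_test(nets_a, nets_b).p_value
    result = permutation_test(
        nets_a,
        nets_b,
        statistic=stat,
        n_perm=n_perm,
        seed=int(perm_seed.generate_state(1)[0]),
    )
    return result.p_value


def run_table_experiment(cfg: SimulationConfig) -> pd.DataFrame:
    """Mean p-values over repeated experiments, one row per distribution pair.

    For every (pair, group size) cell, ``n_repeats`` independent experiments
    are run — fresh networks each time — and the resulting p-values are
    averaged.  Returns a DataFrame indexed by "A vs. B" row labels with one
    column per group size.
    """
    if cfg.p < 3:
        raise ValueError("p must be at least 3 for nontrivial cycles")
    master = np.random.SeedSequence(cfg.seed)
    cell_seeds = master.spawn(len(cfg.pairs) * len(cfg.group_sizes) * cfg.n_repeats)
    table = np.empty((len(cfg.pairs), len(cfg.group_sizes)))
    idx = 0
    for row, (name_a, name_b) in enumerate(cfg.pairs):
        dist_a, dist_b = named_distribution(name_a), named_distribution(name_b)
        for col, n_networks in enumerate(cfg.group_sizes):
            pvals = []
            for _ in range(cfg.n_repeats):
                pvals.append(
                    _single_cell_p(
                        cfg.p, dist_a, dist_b, n_networks, cfg.stat,
                        cfg.n_perm, cell_seeds[idx],
                    )
                )
                idx += 1
            table[row, col] = float(np.mean(pvals))
    return pd.DataFrame(
        table,
        index=[f"{a} vs. {b}" for a, b in cfg.pairs],
        columns=[f"{size} networks" for size in cfg.group_sizes],
    )
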