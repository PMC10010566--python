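"""Expected order statistics, expected barcodes, and confidence bands.

The k-th smallest of q iid edge weights with cdf F has expectation
approximately F^{-1}(k/(q+1)); plugging the birth/death ranks of the
decomposition into this quantile map yields the expected persistent
barcode.  The asymptotic-normal variance r(1-r) / ((q+1) f(F^{-1}(r))^2),
r = k/(q+1), supplies per-rank confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy import stats

from .graphcore import Barcode, WeightedNetwork, birth_death_decomposition

__all__ = [
    "DistributionSpec",
    "Uniform01",
    "BetaDistribution",
    "PointMass",
    "EmpiricalDistribution",
    "ExpectedBarcode",
    "expected_order_stat",
    "order_stat_variance",
    "expected_barcode",
    "estimate_group_distribution",
    "confidence_bands",
    "ExtremeRankWarning",
    "WideIntervalWarning",
]


class ExtremeRankWarning(UserWarning):
    """The asymptotic-normal approximation is weakest at the extreme ranks."""


class WideIntervalWarning(UserWarning):
    """KDE density near zero at a requested quantile; interval unbounded."""


class DistributionSpec:
    """Edge-weight distribution: cdf, generalized inverse cdf, density.

    The generalized inverse satisfies ``ppf(x) = inf{t : cdf(t) >= x}`` for
    x in (0, 1).  Subclasses without a density raise ``NotImplementedError``
    from :meth:`pdf`.
    """

    def cdf(self, x: ArrayLike) -> NDArray[np.float64]:
        raise NotImplementedError

    def ppf(self, u: ArrayLike) -> NDArray[np.float64]:
        raise NotImplementedError

    def pdf(self, x: ArrayLike) -> NDArray[np.float64]:
        raise NotImplementedError(f"{type(self).__name__} has no density")

    def sample(self, size: int, rng: np.random.Generator) -> NDArray[np.float64]:
        raise NotImplementedError


class Uniform01(DistributionSpec):
    """Uniform distribution on [0, 1]."""

    def cdf(self, x):
        return np.clip(np.asarray(x, dtype=float), 0.0, 1.0)

    def ppf(self, u):
        return np.asarray(u, dtype=float)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where((x >= 0) & (x <= 1), 1.0, 0.0)

    def sample(self, size, rng):
        return rng.uniform(0.0, 1.0, size)

    def __repr__(self):
        return "Uniform01()"


class BetaDistribution(DistributionSpec):
    """Beta(a, b) distribution on (0, 1)."""

    def __init__(self, a: float, b: float) -> None:
        if a <= 0 or b <= 0:
            raise ValueError(f"Beta shape parameters must be positive, got ({a}, {b})")
        self.a = float(a)
        self.b = float(b)
        self._frozen = stats.beta(a, b)

    def cdf(self, x):
        return self._frozen.cdf(x)

    def ppf(self, u):
        return self._frozen.ppf(u)

    def pdf(self, x):
        return self._frozen.pdf(x)

    def sample(self, size, rng):
        return rng.beta(self.a, self.b, size)

    def __repr__(self):
        return f"BetaDistribution({self.a:g}, {self.b:g})"


class PointMass(DistributionSpec):
    """Degenerate distribution with all mass at a single point."""

    def __init__(self, c: float) -> None:
        self.c = float(c)

    def cdf(self, x):
        return (np.asarray(x, dtype=float) >= self.c).astype(float)

    def ppf(self, u):
        return np.full_like(np.asarray(u, dtype=float), self.c)

    def sample(self, size, rng):
        return np.full(size, self.c)

    def __repr__(self):
        return f"PointMass({self.c:g})"


class EmpiricalDistribution(DistributionSpec):
    """Empirical cdf of a sample with a Gaussian-KDE density.

    cdf(x) = (1/q) sum I{sample_i <= x}; the generalized inverse maps
    u in (0, 1] to the ceil(u*q)-th smallest sample value, and u above
    1 - 1/q (in particular u -> 1) to the sample maximum.  The density is a
    Gaussian kernel estimate on the same sample with Silverman's bandwidth
    by default; a float ``bandwidth`` is interpreted as the absolute kernel
    width h.
    """

    def __init__(self, sample: ArrayLike, bandwidth: str | float = "silverman") -> None:
        sample = np.asarray(sample, dtype=float)
        if sample.ndim != 1 or sample.size == 0:
            raise ValueError("sample must be a non-empty 1-D vector")
        if not np.all(np.isfinite(sample)):
            raise ValueError("sample values must be finite")
        self.sample_values = np.sort(sample)
        self.bandwidth = bandwidth
        self._kde = None

    @property
    def n(self) -> int:
        return self.sample_values.size

    def cdf(self, x):
        return np.searchsorted(self.sample_values, np.asarray(x, dtype=float), side="right") / self.n

    def ppf(self, u):
        u = np.asarray(u, dtype=float)
        if np.any(u <= 0):
            raise ValueError("generalized inverse requires u > 0")
        k = np.minimum(np.ceil(u * self.n).astype(np.intp), self.n)
        return self.sample_values[k - 1]

    def _fit_kde(self) -> stats.gaussian_kde:
        if self._kde is None:
            if isinstance(self.bandwidth, str):
                bw = self.bandwidth
            else:
                sd = float(np.std(self.sample_values, ddof=1))
                if sd == 0:
                    raise ValueError("degenerate sample: cannot set absolute bandwidth")
                bw = float(self.bandwidth) / sd
            self._kde = stats.gaussian_kde(self.sample_values, bw_method=bw)
        return self._kde

    def pdf(self, x):
        return self._fit_kde()(np.atleast_1d(np.asarray(x, dtype=float)))

    def sample(self, size, rng):
        return rng.choice(self.sample_values, size=size, replace=True)

    def __repr__(self):
        return f"EmpiricalDistribution(n={self.n}, bandwidth={self.bandwidth!r})"


@dataclass(frozen=True)
class ExpectedBarcode:
    """Quantile-mapped expected births/deaths with their source ranks.

    Variances are the asymptotic-normal per-value variances when the
    distribution exposes a density, else NaN.
    """

    expected_births: NDArray[np.float64]
    expected_deaths: NDArray[np.float64]
    birth_ranks: NDArray[np.intp]
    death_ranks: NDArray[np.intp]
    birth_variances: NDArray[np.float64]
    death_variances: NDArray[np.float64]

    @property
    def m0(self) -> int:
        return self.expected_births.size

    @property
    def m1(self) -> int:
        return self.expected_deaths.size


def _check_rank(k: int, q: int) -> None:
    if not (1 <= k <= q):
        raise ValueError(f"rank k={k} outside 1..q={q}")


def expected_order_stat(dist: DistributionSpec, k: int, q: int) -> float:
    """Approximate E[W_(k)] of q iid draws: F^{-1}(k/(q+1)).

    Exact for Uniform(0,1), where the k-th order statistic is
    Beta(k, q+1-k) with mean k/(q+1).
    """
    _check_rank(k, q)
    return float(dist.ppf(k / (q + 1)))


def order_stat_variance(dist: DistributionSpec, k: int, q: int) -> float:
    """Asymptotic variance of W_(k): r(1-r) / ((q+1) f(F^{-1}(r))^2)."""
    _check_rank(k, q)
    if k in (1, q):
        warnings.warn(
            f"rank k={k} is extreme; the asymptotic-normal variance is least "
            "accurate in the tails",
            ExtremeRankWarning,
            stacklevel=2,
        )
    r = k / (q + 1)
    try:
        f = float(np.asarray(dist.pdf(dist.ppf(r))).reshape(()))
    except NotImplementedError as exc:
        raise ValueError(
            f"{dist!r} exposes no density; the variance approximation is "
            "undefined"
        ) from exc
    if not np.isfinite(f) or f <= 0:
        raise ValueError(
            f"density is {f} at the rank-{k} quantile; the variance "
            "approximation is invalid there"
        )
    return r * (1 - r) / ((q + 1) * f * f)


def expected_barcode(
    dist: DistributionSpec,
    birth_ranks: ArrayLike | Barcode,
    death_ranks: ArrayLike | None = None,
    q: int | None = None,
    with_variances: bool = True,
) -> ExpectedBarcode:
    """Map a rank partition through the quantile approximation.

    ``birth_ranks`` and ``death_ranks`` must partition {1, ..., q}.  A
    :class:`~persnet.graphcore.Barcode` may be passed as ``birth_ranks``
    (then ``death_ranks`` is ignored).  ``with_variances=False`` skips the
    per-rank variance computation (all NaN), which matters when expected
    barcodes are built in bulk.
    """
    if isinstance(birth_ranks, Barcode):
        bar = birth_ranks
        birth_ranks, death_ranks = bar.birth_ranks, bar.death_ranks
    br = np.asarray(birth_ranks, dtype=np.intp)
    dr = np.asarray(death_ranks, dtype=np.intp)
    n_ranks = br.size + dr.size
    if q is None:
        q = n_ranks
    if not np.array_equal(np.sort(np.concatenate([br, dr])), np.arange(1, q + 1)):
        raise ValueError("birth and death ranks must partition {1, ..., q}")

    eb = np.asarray(dist.ppf(br / (q + 1)), dtype=float)
    ed = np.asarray(dist.ppf(dr / (q + 1)), dtype=float)

    def variances(ranks: NDArray[np.intp]) -> NDArray[np.float64]:
        out = np.full(ranks.size, np.nan)
        if not with_variances:
            return out
        r = ranks / (q + 1)
        try:
            f = np.asarray(dist.pdf(dist.ppf(r)), dtype=float)
        except NotImplementedError:
            return out
        good = np.isfinite(f) & (f > 0)
        out[good] = r[good] * (1 - r[good]) / ((q + 1) * f[good] ** 2)
        return out

    return ExpectedBarcode(
        expected_births=eb,
        expected_deaths=ed,
        birth_ranks=br,
        death_ranks=dr,
        birth_variances=variances(br),
        death_variances=variances(dr),
    )


def estimate_group_distribution(
    nets: Sequence[WeightedNetwork],
    bandwidth: str | float = "silverman",
    pool: bool = False,
) -> EmpiricalDistribution:
    """Empirical-cdf / KDE spec from the element-wise average weight vector.

    The sample is the length-q averaged weight vector w-bar (the printed
    formulas sum over its q entries); ``pool=True`` instead concatenates all
    n*q weights into one sample.
    """
    if len(nets) == 0:
        raise ValueError("need at least one network")
    p = nets[0].p
    if any(net.p != p for net in nets):
        raise ValueError("all networks in a group must share the same node count")
    W = np.stack([net.weights for net in nets])
    sample = W.ravel() if pool else W.mean(axis=0)
    return EmpiricalDistribution(sample, bandwidth=bandwidth)


def confidence_bands(
    nets: Sequence[WeightedNetwork],
    alpha_pct: float = 95.0,
    bandwidth: str | float = "silverman",
) -> pd.DataFrame:
    """Per-rank z-intervals for the expected birth and death values.

    For each rank k the centre is the empirical quantile of the averaged
    weight vector at k/(q+1) and the half-width is z * sigma_k with sigma_k
    from the asymptotic-normal variance evaluated on the KDE density.  Ranks
    are labelled birth or death via the decomposition of the averaged
    network.  Returns a DataFrame with columns
    ``rank, role, mu_hat, sigma_hat, lo, hi``.
    """
    if len(nets) < 2:
        raise ValueError("confidence bands require at least two networks")
    if not (0 < alpha_pct < 100):
        raise ValueError(f"alpha_pct must lie in (0, 100), got {alpha_pct}")
    spec = estimate_group_distribution(nets, bandwidth=bandwidth)
    q = spec.n
    z = float(stats.norm.ppf(0.5 + alpha_pct / 200.0))

    mean_net = WeightedNetwork(nets[0].p, spec.sample_values.copy())
    bar = birth_death_decomposition(mean_net)
    role = np.empty(q, dtype=object)
    role[bar.birth_ranks - 1] = "birth"
    role[bar.death_ranks - 1] = "death"

    ranks = np.arange(1, q + 1)
    r = ranks / (q + 1)
    mu = spec.ppf(r)
    dens = np.asarray(spec.pdf(mu), dtype=float)
    sigma = np.full(q, np.inf)
    tiny = np.finfo(float).tiny ** 0.5
    bad = ~(np.isfinite(dens) & (dens > tiny))
    if np.any(bad):
        warnings.warn(
            f"KDE density vanishes at {int(bad.sum())} quantile(s); the "
            "corresponding intervals are unbounded",
            WideIntervalWarning,
            stacklevel=2,
        )
    good = ~bad
    sigma[good] = np.sqrt(r[good] * (1 - r[good]) / ((q + 1) * dens[good] ** 2))

    return pd.DataFrame(
        {
            "rank": ranks,
            "role": role,
            "mu_hat": mu,
            "sigma_hat": sigma,
            "lo": mu - z * sigma,
            "hi": mu + z * sigma,
        }
    )
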