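"""Readers, writers and correlation-network construction."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .graphcore import Barcode, WeightedNetwork, edge_pairs

__all__ = [
    "TimeSeriesMatrix",
    "correlation_network",
    "read_adjacency",
    "write_adjacency",
    "read_edgelist",
    "read_timeseries",
    "read_group",
    "write_barcode",
    "read_barcode",
]

_SYMMETRY_TOL = 1e-8


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """T x p matrix of region time series with column labels."""

    values: NDArray[np.float64]
    labels: list[str]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("time series must be a 2-D matrix (T rows x p columns)")
        if values.shape[0] < 2:
            raise ValueError("need at least two time points")
        if len(self.labels) != values.shape[1]:
            raise ValueError("one label per column required")
        object.__setattr__(self, "values", values)

    @property
    def T_points(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def correlation_network(ts: TimeSeriesMatrix, zscore: bool = False) -> WeightedNetwork:
    """Pearson correlation network of the columns of a time-series matrix.

    The upper triangle of the p x p correlation matrix becomes the weight
    vector.  Constant columns have undefined correlations and are rejected
    with the offending region named.
    """
    values = ts.values
    sd = values.std(axis=0)
    constant = np.where(sd == 0)[0]
    if constant.size:
        names = ", ".join(ts.labels[i] for i in constant)
        raise ValueError(f"constant time series (zero variance) for region(s): {names}")
    if zscore:
        values = (values - values.mean(axis=0)) / sd
    corr = np.corrcoef(values, rowvar=False)
    return WeightedNetwork.from_adjacency(corr)


def read_adjacency(path: str | Path) -> WeightedNetwork:
    """Read a dense symmetric adjacency CSV; diagonal ignored.

    Asymmetries up to 1e-8 are averaged away with a warning; larger ones are
    an error.
    """
    A = np.loadtxt(path, delimiter=",", ndmin=2)
    if A.shape[0] != A.shape[1]:
        raise ValueError(f"{path}: adjacency matrix must be square, got {A.shape}")
    if np.isnan(A).any():
        raise ValueError(f"{path}: adjacency matrix contains NaN entries")
    asym = np.max(np.abs(A - A.T)) if A.size else 0.0
    if asym > _SYMMETRY_TOL:
        raise ValueError(f"{path}: matrix asymmetry {asym:g} exceeds tolerance {_SYMMETRY_TOL:g}")
    if asym > 0:
        warnings.warn(f"{path}: symmetrizing matrix (max asymmetry {asym:g})", stacklevel=2)
        A = (A + A.T) / 2
    return WeightedNetwork.from_adjacency(A)


def write_adjacency(net: WeightedNetwork, path: str | Path) -> None:
    """Write a network as a dense adjacency CSV (full precision)."""
    np.savetxt(path, net.adjacency(), delimiter=",", fmt="%.17g")


def read_edgelist(path: str | Path) -> WeightedNetwork:
    """Read an edge-list TSV (node_i, node_j, weight; 0-based nodes).

    Every node pair must appear exactly once, in any row order; the result
    is placed in canonical edge order.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["i", "j", "weight"],
        float_precision="round_trip",
    )
    i = df["i"].to_numpy(dtype=int)
    j = df["j"].to_numpy(dtype=int)
    w = df["weight"].to_numpy(dtype=float)
    if np.any(i == j):
        raise ValueError(f"{path}: self-loops are not allowed")
    p = int(max(i.max(), j.max())) + 1
    q = p * (p - 1) // 2
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    flat = lo * p - lo * (lo + 1) // 2 + (hi - lo - 1)
    if np.unique(flat).size != q or flat.size != q:
        raise ValueError(f"{path}: edge list must cover each of the {q} node pairs exactly once")
    weights = np.empty(q)
    weights[flat] = w
    return WeightedNetwork(p, weights)


def read_timeseries(path: str | Path) -> TimeSeriesMatrix:
    """Read a time-series CSV (T rows x p columns, header row of labels)."""
    df = pd.read_csv(path)
    return TimeSeriesMatrix(df.to_numpy(dtype=float), [str(c) for c in df.columns])


def read_group(directory: str | Path, pattern: str = "*.csv") -> list[WeightedNetwork]:
    """Read every adjacency CSV in a directory (sorted by file name)."""
    directory = Path(directory)
    paths = sorted(directory.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no files matching {pattern!r} in {directory}")
    nets = [read_adjacency(path) for path in paths]
    sizes = {net.p for net in nets}
    if len(sizes) > 1:
        raise ValueError(f"{directory}: inconsistent node counts {sorted(sizes)} within group")
    return nets


def write_barcode(bar: Barcode, path: str | Path) -> None:
    """Write a barcode as JSON (p, births, deaths, birth_ranks, death_ranks)."""
    payload = {
        "p": bar.p,
        "births": bar.births.tolist(),
        "deaths": bar.deaths.tolist(),
        "birth_ranks": bar.birth_ranks.tolist(),
        "death_ranks": bar.death_ranks.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_barcode(path: str | Path) -> Barcode:
    payload = json.loads(Path(path).read_text())
    return Barcode(
        births=np.asarray(payload["births"], dtype=float),
        deaths=np.asarray(payload["deaths"], dtype=float),
        birth_ranks=np.asarray(payload["birth_ranks"], dtype=np.intp),
        death_ranks=np.asarray(payload["death_ranks"], dtype=np.intp),
    )
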