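"""Signed weighted co-expression network construction.

Pipeline stages: Pearson correlation -> signed power adjacency ->
topological overlap (TOM) -> connectivity, plus scale-free soft-threshold
selection.  All matrices are dense and symmetric; gene identity travels
with the values so downstream stages never rely on positional alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _spstats

__all__ = [
    "CorrelationMatrix",
    "AdjacencyMatrix",
    "TOMMatrix",
    "ConnectivityVector",
    "PowerSelection",
    "correlation_matrix",
    "filter_zero_variance",
    "signed_adjacency",
    "scale_free_fit",
    "pick_soft_threshold",
    "topological_overlap",
    "connectivity",
]


def _check_square(values: np.ndarray, gene_ids: Sequence[str]) -> None:
    n = len(gene_ids)
    if values.shape != (n, n):
        raise ValueError(f"matrix shape {values.shape} does not match {n} gene ids")


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    gene_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_square(self.values, self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Signed adjacency a_ij = ((1 + cor_ij) / 2) ** beta, values in [0, 1].

    The diagonal is stored as 1 but is excluded from every connectivity sum.
    """

    gene_ids: tuple[str, ...]
    values: np.ndarray
    beta: int

    def __post_init__(self) -> None:
        _check_square(self.values, self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)


@dataclass(frozen=True)
class TOMMatrix:
    """Topological overlap matrix, values in [0, 1], diagonal reported as 1."""

    gene_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_square(self.values, self.gene_ids)

    def dissimilarity(self) -> np.ndarray:
        """1 - TOM with an exactly-zero diagonal, ready for clustering."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return np.clip(d, 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)


@dataclass(frozen=True)
class ConnectivityVector:
    """Per-gene connectivity k_i = sum_{j != i} a_ij."""

    gene_ids: tuple[str, ...]
    k: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(self.k, index=self.gene_ids, name="k")


@dataclass
class PowerSelection:
    """Scale-free fit diagnostics for each candidate soft-threshold power."""

    candidate_powers: list[int]
    r2_signed: list[float]
    slope: list[float]
    mean_connectivity: list[float]
    chosen_power: int
    reached_cutoff: bool
    degenerate: list[bool] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "power": self.candidate_powers,
                "r2_signed": self.r2_signed,
                "slope": self.slope,
                "mean_connectivity": self.mean_connectivity,
            }
        )


def filter_zero_variance(expr: pd.DataFrame) -> pd.DataFrame:
    """Drop genes (rows) with zero variance across samples, warning per drop."""
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    bad = sd == 0.0
    if bad.any():
        dropped = list(expr.index[bad])
        warnings.warn(
            f"dropping {len(dropped)} zero-variance gene(s): {dropped[:10]}",
            stacklevel=2,
        )
        expr = expr.loc[~bad]
    return expr


def correlation_matrix(expr: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson correlation between genes (rows) across samples.

    Raises if fewer than 3 samples or if any gene has zero variance; use
    :func:`filter_zero_variance` first when constant genes are expected.
    """
    if expr.shape[1] < 3:
        raise ValueError(f"need >= 3 samples, got {expr.shape[1]}")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if (sd == 0.0).any():
        offenders = list(expr.index[sd == 0.0])
        raise ValueError(
            f"zero-variance gene(s) {offenders[:10]}; filter before correlating"
        )
    cor = np.corrcoef(values)
    cor = np.clip((cor + cor.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return CorrelationMatrix(tuple(map(str, expr.index)), cor)


def signed_adjacency(cor: CorrelationMatrix, beta: int) -> AdjacencyMatrix:
    """Signed adjacency ((1 + cor) / 2) ** beta; monotone in cor, in [0, 1]."""
    if int(beta) != beta or beta < 1:
        raise ValueError(f"beta must be an integer >= 1, got {beta}")
    adj = ((1.0 + cor.values) / 2.0) ** int(beta)
    np.fill_diagonal(adj, 1.0)
    return AdjacencyMatrix(cor.gene_ids, adj, int(beta))


def connectivity(adj: AdjacencyMatrix) -> ConnectivityVector:
    """Row sums of the adjacency excluding the self term."""
    k = adj.values.sum(axis=1) - np.diag(adj.values)
    return ConnectivityVector(adj.gene_ids, k)


def topological_overlap(adj: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    l_ij sums a_iu * a_uj over shared neighbours u distinct from i and j;
    connectivity k excludes the self term. Diagonal is reported as 1.
    """
    a = adj.values.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a  # zero diagonal of `a` removes u == i and u == j terms
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom = np.where(denom <= 0.0, 0.0, tom)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return TOMMatrix(adj.gene_ids, tom)


def scale_free_fit(
    k: ConnectivityVector | np.ndarray, n_bins: int = 10
) -> tuple[float, float, bool]:
    """Scale-free topology fit of the connectivity distribution.

    Bins k into ``n_bins`` equal-width bins, regresses log10(frequency) on
    log10(mean k) over non-empty bins, and returns
    ``(r2_signed, slope, degenerate)`` where r2_signed = -sign(slope) * R^2.
    Fewer than two usable bins (or all-equal k) is degenerate: (0.0, 0.0, True).
    """
    if n_bins < 3:
        raise ValueError(f"n_bins must be >= 3, got {n_bins}")
    kv = k.k if isinstance(k, ConnectivityVector) else np.asarray(k, dtype=float)
    kv = kv[kv > 0]
    if kv.size < 2 or np.ptp(kv) == 0.0:
        return 0.0, 0.0, True
    counts, edges = np.histogram(kv, bins=n_bins)
    # mean connectivity per bin, over members
    idx = np.clip(np.digitize(kv, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        if counts[b] == 0:
            continue
        mean_k = kv[idx == b].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(counts[b] / kv.size))
    if len(xs) < 2 or np.ptp(xs) == 0.0:
        return 0.0, 0.0, True
    fit = _spstats.linregress(xs, ys)
    r2 = float(fit.rvalue**2)
    slope = float(fit.slope)
    return -np.sign(slope) * r2, slope, False


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    r2_cutoff: float = 0.8,
    n_bins: int = 10,
) -> PowerSelection:
    """Pick the smallest candidate power whose signed scale-free R^2 reaches
    ``r2_cutoff``; fall back to the argmax candidate with a warning flag."""
    powers = [int(p) for p in candidate_powers]
    if not powers:
        raise ValueError("candidate_powers must be non-empty")
    if sorted(powers) != powers:
        raise ValueError("candidate_powers must be sorted ascending")
    cor = correlation_matrix(expr)
    r2s, slopes, means, degs = [], [], [], []
    for p in powers:
        adj = signed_adjacency(cor, p)
        kv = connectivity(adj)
        r2, slope, deg = scale_free_fit(kv, n_bins=n_bins)
        r2s.append(r2)
        slopes.append(slope)
        means.append(float(kv.k.mean()))
        degs.append(deg)
    qualifying = [p for p, r2 in zip(powers, r2s) if r2 >= r2_cutoff]
    if qualifying:
        chosen = qualifying[0]
        reached = True
    else:
        chosen = powers[int(np.argmax(r2s))]
        reached = False
        warnings.warn(
            f"no candidate power reached r2_cutoff={r2_cutoff}; "
            f"falling back to argmax power {chosen}",
            stacklevel=2,
        )
    return PowerSelection(powers, r2s, slopes, means, chosen, reached, degs)
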