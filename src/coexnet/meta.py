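"""Higher-order analysis of module eigengenes.

The eigengene matrix is treated exactly like an expression matrix: the same
correlation -> signed adjacency -> TOM -> average linkage -> tree cut chain
is reused (no duplicated math), just at a gentler power and a tiny minimum
module size so that pairs of modules can form a meta-module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _spstats

from .detect import (
    CutParams,
    EigengeneSet,
    ModulePartition,
    average_linkage_dendrogram,
    dynamic_tree_cut,
)
from .network import (
    AdjacencyMatrix,
    connectivity,
    correlation_matrix,
    signed_adjacency,
    topological_overlap,
)

__all__ = [
    "MetaNetwork",
    "eigengene_meta_modules",
    "module_global_connectivity",
    "top_edges",
    "connectivity_group_test",
]


@dataclass
class MetaNetwork:
    """Module-level network: signed adjacency between eigengenes, global
    module connectivity, and the meta-module partition."""

    adjacency: AdjacencyMatrix
    partition: ModulePartition
    meta_power: int

    @property
    def module_labels(self) -> tuple[str, ...]:
        return self.adjacency.gene_ids

    def global_connectivity(self) -> pd.Series:
        return connectivity(self.adjacency).to_series()


def eigengene_meta_modules(
    eigengenes: EigengeneSet,
    meta_power: int = 3,
    minModuleSize: int = 2,
    cut_params: CutParams | None = None,
) -> MetaNetwork:
    """Cluster module eigengenes into meta-modules.

    Runs the gene-network chain on the modules x samples eigengene matrix:
    correlation -> signed adjacency at ``meta_power`` -> TOM -> average
    linkage -> dynamic tree cut with ``minModuleSize`` (default 2).
    """
    n_modules = eigengenes.values.shape[0]
    if n_modules < 3:
        raise ValueError(f"need >= 3 modules, got {n_modules}")
    if n_modules <= minModuleSize:
        raise ValueError(
            f"minModuleSize={minModuleSize} requires more than that many modules"
        )
    cor = correlation_matrix(eigengenes.values)
    adj = signed_adjacency(cor, meta_power)
    tom = topological_overlap(adj)
    dend = average_linkage_dendrogram(tom.dissimilarity(), list(tom.gene_ids))
    params = cut_params or CutParams(
        minModuleSize=minModuleSize, deepSplit=2, cut_height_fraction=0.995,
        gap_threshold=0.05,
    )
    params.minModuleSize = minModuleSize
    partition = dynamic_tree_cut(dend, params)
    return MetaNetwork(adj, partition, int(meta_power))


def module_global_connectivity(meta: MetaNetwork) -> pd.DataFrame:
    """Modules ranked by global connectivity (descending; ties by label)."""
    k = meta.global_connectivity()
    frame = k.rename("k").to_frame()
    frame["module"] = frame.index
    frame = frame.sort_values(["k", "module"], ascending=[False, True])
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame[["module", "k", "rank"]].reset_index(drop=True)


def top_edges(meta: MetaNetwork, n_edges: int = 100) -> pd.DataFrame:
    """The n_edges heaviest unordered module pairs, ties by (label_i, label_j)."""
    if n_edges < 1:
        raise ValueError(f"n_edges must be >= 1, got {n_edges}")
    labels = meta.module_labels
    n = len(labels)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sorted((labels[i], labels[j]))
            rows.append((a, b, float(meta.adjacency.values[i, j])))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    n_pairs = len(rows)
    if n_edges > n_pairs:
        warnings.warn(
            f"requested {n_edges} edges but only {n_pairs} pairs exist; returning all",
            stacklevel=2,
        )
        n_edges = n_pairs
    return pd.DataFrame(rows[:n_edges], columns=["module_i", "module_j", "weight"])


def connectivity_group_test(
    group_a: np.ndarray | list, group_b: np.ndarray | list
) -> tuple[float, float]:
    """Welch two-sample t-test (unequal variances), two-sided.

    Two zero-variance groups with equal means return (0.0, 1.0) by
    convention instead of NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = _spstats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
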