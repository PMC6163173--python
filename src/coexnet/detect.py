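"""Module detection: average-linkage clustering of TOM dissimilarity,
a dynamic tree cut variant, and module eigengenes.

The cut procedure is a documented simplification of adaptive dendrogram
cutting: a static cut close to the root proposes candidate branches, small
branches fall into the reserved ``grey`` label, branches are recursively
split where both sides are large enough, and each terminal branch is
trimmed at the first clear jump in its merge heights so that leaves
chained on above the tight core go grey.  Recovery of planted modules, not
equivalence with any other cutter, is the contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform

from ._colors import GREY_LABEL, module_color_names

__all__ = [
    "Dendrogram",
    "CutParams",
    "ModulePartition",
    "EigengeneSet",
    "average_linkage_dendrogram",
    "dynamic_tree_cut",
    "module_eigengenes",
]


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge tree over gene leaves.

    ``merges`` is the standard (n-1) x 4 linkage matrix (left, right,
    height, size); ``leaf_ids`` maps leaf index -> gene id.
    """

    merges: np.ndarray
    leaf_ids: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def max_height(self) -> float:
        return float(self.merges[-1, 2]) if len(self.merges) else 0.0

    def leaf_order(self) -> list[int]:
        return list(leaves_list(self.merges))


@dataclass
class CutParams:
    minModuleSize: int = 30
    deepSplit: int = 2
    cut_height_fraction: float = 0.995
    gap_threshold: float = 0.05

    def validate(self) -> None:
        if self.minModuleSize < 2:
            raise ValueError(f"minModuleSize must be >= 2, got {self.minModuleSize}")
        if not 0 <= self.deepSplit <= 4:
            raise ValueError(f"deepSplit must be in 0..4, got {self.deepSplit}")
        if not 0.0 < self.cut_height_fraction <= 1.0:
            raise ValueError("cut_height_fraction must lie in (0, 1]")
        if self.gap_threshold < 0:
            raise ValueError("gap_threshold must be >= 0")


@dataclass
class ModulePartition:
    """gene -> module label; ``grey`` is reserved for unassigned genes."""

    assignments: dict[str, str]

    @property
    def module_labels(self) -> list[str]:
        """Assigned module labels, largest module first (grey excluded)."""
        sizes = self.module_sizes()
        return list(sizes.index)

    def module_sizes(self) -> pd.Series:
        s = pd.Series(self.assignments, name="module")
        counts = s[s != GREY_LABEL].value_counts()
        return counts.sort_values(ascending=False)

    def genes_in(self, label: str) -> list[str]:
        return [g for g, m in self.assignments.items() if m == label]

    def n_grey(self) -> int:
        return sum(1 for m in self.assignments.values() if m == GREY_LABEL)

    def to_series(self) -> pd.Series:
        return pd.Series(self.assignments, name="module")


@dataclass
class EigengeneSet:
    """Module eigengenes (first right singular vectors, unit norm over
    samples, sign-aligned with the mean standardized module profile)."""

    values: pd.DataFrame  # modules x samples
    variance_explained: dict[str, float]
    sign_flipped: dict[str, bool] = field(default_factory=dict)

    @property
    def module_labels(self) -> list[str]:
        return list(self.values.index)

    def eigengene(self, label: str) -> pd.Series:
        return self.values.loc[label]


def average_linkage_dendrogram(dissim: np.ndarray | pd.DataFrame,
                               gene_ids: list[str] | None = None) -> Dendrogram:
    """UPGMA merge tree from a symmetric dissimilarity matrix with zero diagonal."""
    if isinstance(dissim, pd.DataFrame):
        gene_ids = list(map(str, dissim.index))
        dissim = dissim.to_numpy(dtype=float)
    else:
        dissim = np.asarray(dissim, dtype=float)
        if gene_ids is None:
            gene_ids = [str(i) for i in range(dissim.shape[0])]
    if dissim.ndim != 2 or dissim.shape[0] != dissim.shape[1]:
        raise ValueError(f"dissimilarity must be square, got {dissim.shape}")
    if not np.allclose(dissim, dissim.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if (dissim < 0).any():
        raise ValueError("dissimilarity values must be non-negative")
    condensed = squareform(np.ascontiguousarray((dissim + dissim.T) / 2.0),
                           checks=False)
    merges = linkage(condensed, method="average")
    return Dendrogram(merges, tuple(gene_ids))


def _node_leaves(node) -> list[int]:
    """Iterative leaf collection (recursion-free for deep trees)."""
    out: list[int] = []
    stack = [node]
    while stack:
        nd = stack.pop()
        if nd.is_leaf():
            out.append(nd.id)
        else:
            stack.append(nd.left)
            stack.append(nd.right)
    return out


def _static_cut(root, height: float) -> list:
    """Maximal subtrees whose top merge height is <= height."""
    out = []
    stack = [root]
    while stack:
        nd = stack.pop()
        if nd.is_leaf() or nd.dist <= height:
            out.append(nd)
        else:
            stack.append(nd.left)
            stack.append(nd.right)
    return out


def _spine_split(node, min_size: int):
    """First node, descending through merges whose smaller side holds fewer
    than ``min_size`` leaves, at which both children are large; None if the
    subtree never balances (pure accretion)."""
    current = node
    while not current.is_leaf():
        left, right = current.left, current.right
        big, small = (left, right) if left.count >= right.count else (right, left)
        if small.count >= min_size:
            return current
        if big.count < min_size:
            return None
        current = big
    return None


def _subtree_heights(node) -> list[float]:
    out: list[float] = []
    stack = [node]
    while stack:
        nd = stack.pop()
        if not nd.is_leaf():
            out.append(nd.dist)
            stack.append(nd.left)
            stack.append(nd.right)
    return sorted(out)


def _jump_accept(node, min_size: int, gap: float) -> list:
    """Accept a branch as module(s), stripping leaves chained on above the
    tight core: cut at the first jump >= gap in the sorted merge heights and
    keep the resulting subtrees with >= min_size leaves.  No jump (or no
    surviving core) accepts the whole branch."""
    heights = _subtree_heights(node)
    cut = None
    for lo, hi in zip(heights, heights[1:]):
        if hi - lo >= gap:
            cut = lo
            break
    if cut is None:
        return [node]
    cores = [nd for nd in _static_cut(node, cut) if nd.count >= min_size]
    return cores or [node]


def _carve(node, min_size: int, gap: float, depth: int) -> list:
    split = _spine_split(node, min_size) if depth > 0 else None
    if split is not None:
        return _carve(split.left, min_size, gap, depth - 1) + _carve(
            split.right, min_size, gap, depth - 1
        )
    return _jump_accept(node, min_size, gap)


def dynamic_tree_cut(dend: Dendrogram, params: CutParams | None = None) -> ModulePartition:
    """Cut the dendrogram into modules.

    Three stages: (1) a static cut at ``cut_height_fraction * max_height``
    proposes candidate branches; branches smaller than ``minModuleSize`` go
    grey. (2) Each branch is recursively split, up to ``deepSplit`` levels,
    at the first descendant merge where both sides hold at least
    ``minModuleSize`` leaves (descending through chain merges whose smaller
    side is below that size; chained leaves above a taken split go grey).
    (3) Each terminal branch is accepted after stripping leaves chained on
    above its tight core: the branch is cut at the first jump of at least
    ``gap_threshold`` in its sorted merge heights and subtrees with at
    least ``minModuleSize`` leaves survive as modules.  Labels are color
    names assigned by decreasing module size (ties broken by smallest leaf
    index) for readability and determinism.
    """
    params = params or CutParams()
    params.validate()
    if params.minModuleSize >= dend.n_leaves:
        raise ValueError(
            f"minModuleSize={params.minModuleSize} must be < n_leaves={dend.n_leaves}"
        )
    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 4 * dend.n_leaves + 100))
    try:
        root = to_tree(dend.merges)
    finally:
        sys.setrecursionlimit(old_limit)
    height = params.cut_height_fraction * dend.max_height
    branches = _static_cut(root, height)

    module_nodes = []
    for node in branches:
        if node.count >= params.minModuleSize:
            module_nodes.extend(
                _carve(node, params.minModuleSize, params.gap_threshold, params.deepSplit)
            )
    if not module_nodes:
        # every merge can sit at max height (equidistant leaves); the static
        # cut then lands below the root — carve the whole tree instead
        module_nodes = _carve(root, params.minModuleSize, params.gap_threshold,
                              params.deepSplit)

    modules = [sorted(_node_leaves(nd)) for nd in module_nodes]
    modules.sort(key=lambda leaves: (-len(leaves), leaves[0]))
    names = module_color_names(len(modules))
    assignments = {g: GREY_LABEL for g in dend.leaf_ids}
    for name, leaves in zip(names, modules):
        for leaf in leaves:
            assignments[dend.leaf_ids[leaf]] = name
    return ModulePartition(assignments)


def _standardize(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    return (values - mean) / sd


def module_eigengenes(expr: pd.DataFrame, partition: ModulePartition) -> EigengeneSet:
    """First principal component of each module's standardized expression.

    Per module: genes are z-scored across samples; the eigengene is the
    first right singular vector of the genes x samples block (unit
    Euclidean norm over samples); variance_explained is the first squared
    singular value over the total.  The sign is chosen so the eigengene
    correlates non-negatively with the module's mean standardized profile.
    Zero-variance member genes are dropped with a warning; a module left
    empty is an error.
    """
    rows: dict[str, np.ndarray] = {}
    varexp: dict[str, float] = {}
    flipped: dict[str, bool] = {}
    for label in partition.module_labels:
        genes = [g for g in partition.genes_in(label) if g in expr.index]
        missing = set(partition.genes_in(label)) - set(genes)
        if missing:
            raise KeyError(f"module {label!r} genes missing from expression: {sorted(missing)[:5]}")
        if not genes:
            raise ValueError(f"module {label!r} is empty")
        block = expr.loc[genes].to_numpy(dtype=float)
        sd = block.std(axis=1)
        if (sd == 0.0).any():
            bad = [g for g, s in zip(genes, sd) if s == 0.0]
            warnings.warn(
                f"module {label!r}: dropping zero-variance gene(s) {bad[:5]}",
                stacklevel=2,
            )
            block = block[sd > 0.0]
            if block.shape[0] < 2:
                raise ValueError(f"module {label!r} has < 2 usable genes")
        z = _standardize(block)
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        varexp[label] = float(s[0] ** 2 / np.sum(s**2))
        mean_profile = z.mean(axis=0)
        align = float(np.dot(eig, mean_profile))
        flip = align < 0
        if flip:
            eig = -eig
        flipped[label] = flip
        rows[label] = eig
    values = pd.DataFrame(rows, index=expr.columns).T
    values.index.name = "module"
    return EigengeneSet(values, varexp, flipped)
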