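"""Synthetic expression data with planted co-expression modules.

A latent-factor block model: every planted module shares one latent factor
per sample, member genes load on it with strength ``factor_strength``
(optionally jittered so hub structure has a ground truth), and expression is
exponentiated so the matrix is strictly positive like MAS5-summarised
arrays.  The generator also emits matched gene sets and genomic positions so
enrichment code can be tested against a known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "BACKGROUND_LABEL",
    "generate_expression",
    "generate_gene_sets",
    "generate_positions",
]

BACKGROUND_LABEL = "background"


@dataclass
class SyntheticConfig:
    """Parameters of the planted-module generator.

    ``condition_labels`` assigns one label per sample (in column order);
    ``condition_shifts`` maps ``(module_label, condition_label)`` to an
    additive shift of that module's factor mean under that condition.
    ``loading_spread`` draws per-gene loadings uniformly from
    ``factor_strength * [1 - spread, 1 + spread]`` (0 = identical loadings).
    """

    n_samples: int = 120
    module_sizes: Sequence[int] = (50, 50, 50)
    n_background: int = 100
    factor_strength: float = 1.0
    noise_sd: float = 0.3
    condition_labels: Sequence[str] | None = None
    condition_shifts: Mapping[tuple[str, str], float] | None = None
    loading_spread: float = 0.0
    position_clustering: float = 1.0
    n_chromosomes: int = 6
    baseline_log_range: tuple[float, float] = (math.log(50.0), math.log(5000.0))
    seed: int = 0

    def module_labels(self) -> list[str]:
        return [f"M{i + 1}" for i in range(len(self.module_sizes))]

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if not self.module_sizes:
            raise ValueError("module_sizes must be non-empty")
        for s in self.module_sizes:
            if s < 2:
                raise ValueError(f"every module size must be >= 2, got {s}")
        if self.n_background < 0:
            raise ValueError(f"n_background must be >= 0, got {self.n_background}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.factor_strength <= 0:
            raise ValueError(f"factor_strength must be > 0, got {self.factor_strength}")
        if not 0.0 <= self.position_clustering <= 1.0:
            raise ValueError("position_clustering must lie in [0, 1]")
        if not 0.0 <= self.loading_spread < 1.0:
            raise ValueError("loading_spread must lie in [0, 1)")
        if self.condition_labels is not None and len(self.condition_labels) != self.n_samples:
            raise ValueError(
                f"condition_labels has {len(self.condition_labels)} entries "
                f"for {self.n_samples} samples"
            )
        if self.condition_shifts:
            labels = set(self.condition_labels or [])
            modules = set(self.module_labels())
            for module, cond in self.condition_shifts:
                if module not in modules:
                    raise ValueError(f"condition shift references unknown module {module!r}")
                if cond not in labels:
                    raise ValueError(f"condition shift references unknown condition {cond!r}")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated matrix.

    partition maps every gene to its planted module (``background`` for
    noise genes); factors holds the per-module latent sample profiles
    (zero mean over samples); loadings holds each module gene's factor
    loading; positions is filled by :func:`generate_positions`.
    """

    partition: dict[str, str]
    factors: pd.DataFrame  # modules x samples
    loadings: dict[str, float]
    positions: pd.DataFrame | None = None
    config: SyntheticConfig | None = None

    def module_genes(self, label: str) -> list[str]:
        return [g for g, m in self.partition.items() if m == label]

    def module_labels(self) -> list[str]:
        seen: list[str] = []
        for m in self.partition.values():
            if m != BACKGROUND_LABEL and m not in seen:
                seen.append(m)
        return seen


def _gene_ids(n: int) -> list[str]:
    # integer IDs styled like Entrez GeneIDs
    return [str(170_000 + i) for i in range(n)]


def generate_expression(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a strictly positive genes x samples expression matrix.

    Module gene g in module m: x_gs = exp(mu_g + beta_g * f_m(s) + eps_gs)
    with eps ~ Normal(0, noise_sd); background genes drop the factor term.
    Baseline mu_g is log-uniform over ``baseline_log_range``. Deterministic
    for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = config.module_labels()
    n_module_genes = int(sum(config.module_sizes))
    n_genes = n_module_genes + config.n_background
    genes = _gene_ids(n_genes)
    samples = [f"S{j + 1:04d}" for j in range(config.n_samples)]

    lo, hi = config.baseline_log_range
    mu = rng.uniform(lo, hi, size=n_genes)

    factors = rng.standard_normal((len(labels), config.n_samples))
    if config.condition_shifts:
        cond = np.asarray(config.condition_labels)
        for (module, label), shift in config.condition_shifts.items():
            factors[labels.index(module), cond == label] += shift
    factors -= factors.mean(axis=1, keepdims=True)

    partition: dict[str, str] = {}
    loadings: dict[str, float] = {}
    log_expr = np.empty((n_genes, config.n_samples))
    row = 0
    for m, (label, size) in enumerate(zip(labels, config.module_sizes)):
        if config.loading_spread > 0:
            betas = config.factor_strength * rng.uniform(
                1.0 - config.loading_spread, 1.0 + config.loading_spread, size=size
            )
        else:
            betas = np.full(size, config.factor_strength)
        for b in betas:
            partition[genes[row]] = label
            loadings[genes[row]] = float(b)
            log_expr[row] = mu[row] + b * factors[m]
            row += 1
    for _ in range(config.n_background):
        partition[genes[row]] = BACKGROUND_LABEL
        loadings[genes[row]] = 0.0
        log_expr[row] = mu[row]
        row += 1

    if config.noise_sd > 0:
        log_expr += rng.normal(0.0, config.noise_sd, size=log_expr.shape)

    expr = pd.DataFrame(np.exp(log_expr), index=genes, columns=samples)
    expr.index.name = "gene_id"
    truth = SyntheticTruth(
        partition=partition,
        factors=pd.DataFrame(factors, index=labels, columns=samples),
        loadings=loadings,
        config=config,
    )
    return expr, truth


def generate_gene_sets(
    truth: SyntheticTruth, n_decoy_sets: int, seed: int
) -> dict[str, set[str]]:
    """One exact gene set per planted module plus random decoys of matched sizes."""
    if n_decoy_sets < 0:
        raise ValueError(f"n_decoy_sets must be >= 0, got {n_decoy_sets}")
    if not truth.partition:
        raise ValueError("truth has no genes")
    rng = np.random.default_rng(seed)
    all_genes = np.array(sorted(truth.partition))
    sets: dict[str, set[str]] = {}
    module_sizes = []
    for label in truth.module_labels():
        members = truth.module_genes(label)
        sets[f"true_{label}"] = set(members)
        module_sizes.append(len(members))
    for d in range(n_decoy_sets):
        size = module_sizes[d % len(module_sizes)]
        members = rng.choice(all_genes, size=size, replace=False)
        sets[f"decoy_{d + 1}"] = set(map(str, members))
    return sets


def generate_positions(
    truth: SyntheticTruth,
    n_chromosomes: int,
    seed: int,
    position_clustering: float | None = None,
    locus_span: int = 1500,
    locus_step: int = 2000,
) -> pd.DataFrame:
    """Assign every gene a chromosome and a non-overlapping half-open interval.

    For each module, a ``position_clustering`` fraction of its genes is laid
    out as one contiguous run of loci on a single chromosome; all remaining
    genes are scattered uniformly. Defaults to the clustering fraction of
    the generating config. Returns a BED-like frame (gene_id, chromosome,
    start, end) and stores it on ``truth.positions``.
    """
    if n_chromosomes < 1:
        raise ValueError(f"n_chromosomes must be >= 1, got {n_chromosomes}")
    if position_clustering is None:
        position_clustering = truth.config.position_clustering if truth.config else 1.0
    rng = np.random.default_rng(seed)

    # items: clustered module runs (kept contiguous) and single scattered genes
    items: list[list[str]] = []
    for label in truth.module_labels():
        members = truth.module_genes(label)
        n_clustered = int(round(position_clustering * len(members)))
        if n_clustered >= 2:
            picked = rng.choice(len(members), size=n_clustered, replace=False)
            run = [members[i] for i in sorted(picked)]
            items.append(run)
            rest = [m for m in members if m not in set(run)]
        else:
            rest = list(members)
        items.extend([[g] for g in rest])
    items.extend([[g] for g in truth.module_genes(BACKGROUND_LABEL)])
    order = rng.permutation(len(items))
    items = [items[i] for i in order]

    n_genes = len(truth.partition)
    capacity = [math.ceil(n_genes / n_chromosomes)] * n_chromosomes
    chrom_items: list[list[list[str]]] = [[] for _ in range(n_chromosomes)]
    # largest-remaining-capacity placement keeps clustered runs on one chromosome
    for item in sorted(items, key=len, reverse=True):
        c = int(np.argmax(capacity))
        chrom_items[c].append(item)
        capacity[c] -= len(item)
    for c in range(n_chromosomes):
        perm = rng.permutation(len(chrom_items[c]))
        chrom_items[c] = [chrom_items[c][i] for i in perm]

    rows = []
    for c, chrom in enumerate(chrom_items):
        pos = 0
        for item in chrom:
            for gene in item:
                start = pos * locus_step
                rows.append((gene, f"chr{c + 1}", start, start + locus_span))
                pos += 1
    positions = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])
    truth.positions = positions
    return positions
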