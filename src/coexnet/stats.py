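"""Per-module diagnostics: within-module connectivity and hub genes,
half-sample connectivity stability, relative standard deviation of
expression, and module-condition association.

Connectivity here is computed per module: the signed adjacency is built
among the module's genes only and row-summed without the self term.  The
stability resample repeats that on random half-samples and correlates each
module's resampled connectivity with the full-data one.

Note the scale convention: connectivity/stability operate on whatever
expression scale the caller correlates on (the pipeline log2-transforms
first), whereas :func:`module_rsd` requires the positive raw scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._colors import GREY_LABEL
from .detect import EigengeneSet, ModulePartition
from .network import connectivity, correlation_matrix, signed_adjacency

__all__ = [
    "StabilityParams",
    "StabilityReport",
    "within_module_connectivity",
    "hub_genes",
    "stability_resampling",
    "module_rsd",
    "condition_association",
]


@dataclass
class StabilityParams:
    n_iterations: int = 1000
    sample_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ValueError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if not 0.0 < self.sample_fraction < 1.0:
            raise ValueError("sample_fraction must lie in (0, 1)")


@dataclass
class StabilityReport:
    """Per-module mean and SD of the correlation between full-data and
    resampled within-module connectivity."""

    mean_correlation: dict[str, float]
    sd_correlation: dict[str, float]
    skipped_modules: list[str]
    params: StabilityParams

    def to_frame(self) -> pd.DataFrame:
        modules = list(self.mean_correlation)
        return pd.DataFrame(
            {
                "module": modules,
                "mean_correlation": [self.mean_correlation[m] for m in modules],
                "sd_correlation": [self.sd_correlation[m] for m in modules],
            }
        )


def _module_connectivity(values: np.ndarray, gene_ids: list[str], beta: int) -> pd.Series:
    expr = pd.DataFrame(values, index=gene_ids)
    adj = signed_adjacency(correlation_matrix(expr), beta)
    return connectivity(adj).to_series()


def within_module_connectivity(
    expr: pd.DataFrame, partition: ModulePartition, beta: int
) -> dict[str, pd.Series]:
    """Per-module signed connectivity: adjacency among module genes only,
    row-summed excluding self.  Grey genes are ignored; size-1 modules get
    connectivity 0 with a warning."""
    out: dict[str, pd.Series] = {}
    for label in partition.module_labels:
        genes = partition.genes_in(label)
        if len(genes) == 1:
            warnings.warn(f"module {label!r} has a single gene; connectivity is 0",
                          stacklevel=2)
            out[label] = pd.Series([0.0], index=genes, name="k")
            continue
        block = expr.loc[genes]
        out[label] = _module_connectivity(block.to_numpy(dtype=float), genes, beta)
    return out


def hub_genes(
    connectivity_by_module: dict[str, pd.Series], top_n: int = 10
) -> dict[str, pd.Series]:
    """Top-connectivity genes per module; descending k, ties by gene id."""
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    out = {}
    for label, k in connectivity_by_module.items():
        order = sorted(k.index, key=lambda g: (-k[g], g))
        out[label] = k.loc[order[:top_n]]
    return out


def stability_resampling(
    expr: pd.DataFrame,
    partition: ModulePartition,
    beta: int,
    params: StabilityParams | None = None,
) -> StabilityReport:
    """Correlate full-data within-module connectivity against connectivity
    recomputed on random half-samples.

    Each iteration draws floor(n_samples * sample_fraction) samples without
    replacement, recomputes per-module connectivity, and Pearson-correlates
    it with the full-data connectivity over the module's genes.  Modules
    with fewer than 3 genes are skipped (correlation undefined).
    """
    params = params or StabilityParams()
    params.validate()
    n_samples = expr.shape[1]
    if n_samples < 6:
        raise ValueError(f"need >= 6 samples for half-sample resampling, got {n_samples}")
    n_draw = int(np.floor(n_samples * params.sample_fraction))
    rng = np.random.default_rng(params.seed)

    modules = [m for m in partition.module_labels]
    full_k: dict[str, pd.Series] = {}
    blocks: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for label in modules:
        genes = partition.genes_in(label)
        if len(genes) < 3:
            skipped.append(label)
            continue
        blocks[label] = expr.loc[genes].to_numpy(dtype=float)
        full_k[label] = _module_connectivity(blocks[label], genes, beta)

    cors: dict[str, list[float]] = {m: [] for m in full_k}
    for _ in range(params.n_iterations):
        cols = rng.choice(n_samples, size=n_draw, replace=False)
        for label, block in blocks.items():
            sub = block[:, cols]
            sd = sub.std(axis=1)
            if (sd == 0.0).any():  # degenerate draw; treat as uninformative
                cors[label].append(np.nan)
                continue
            genes = list(full_k[label].index)
            sub_k = _module_connectivity(sub, genes, beta)
            kf = full_k[label].to_numpy()
            ks = sub_k.to_numpy()
            # near-constant connectivity (perfectly inter-correlated module):
            # Pearson on float jitter is meaningless, the pattern is preserved
            scale = max(abs(kf).max(), 1.0)
            if kf.std() < 1e-9 * scale or ks.std() < 1e-9 * scale:
                cors[label].append(1.0 if np.allclose(kf, ks, rtol=1e-6) else np.nan)
            else:
                cors[label].append(float(np.corrcoef(kf, ks)[0, 1]))

    mean = {m: float(np.nanmean(v)) for m, v in cors.items()}
    sd = {m: float(np.nanstd(v, ddof=0)) for m, v in cors.items()}
    return StabilityReport(mean, sd, skipped, params)


def module_rsd(expr: pd.DataFrame, partition: ModulePartition) -> pd.DataFrame:
    """Relative standard deviation per gene (sample SD / mean, n-1
    denominator, positive raw scale) plus the member-gene average per module.

    Returns a frame with per-gene rows (gene_id, module, rsd); the
    per-module means are exposed via the ``module_rsd`` attribute column
    ``mean_rsd`` of the returned frame's ``.attrs['module_means']``.
    """
    values = expr.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError(
            "expression must be strictly positive (RSD is defined on the raw scale; "
            "a log-transformed matrix was probably passed by mistake)"
        )
    sd = values.std(axis=1, ddof=1)
    mean = values.mean(axis=1)
    rsd = pd.Series(sd / mean, index=expr.index, name="rsd")
    assign = partition.to_series()
    frame = pd.DataFrame({"rsd": rsd})
    frame["module"] = assign.reindex(frame.index)
    member = frame[frame["module"].notna() & (frame["module"] != GREY_LABEL)]
    module_means = member.groupby("module")["rsd"].mean().rename("mean_rsd")
    frame.attrs["module_means"] = module_means.sort_values()
    return frame


def condition_association(
    eigengenes: EigengeneSet, condition_labels: pd.Series | dict
) -> pd.DataFrame:
    """Per-module mean eigengene under each condition and the argmax label.

    Ties break lexicographically; every sample must be labeled.
    """
    labels = pd.Series(condition_labels)
    samples = list(eigengenes.values.columns)
    missing = [s for s in samples if s not in labels.index or pd.isna(labels[s])]
    if missing:
        raise ValueError(f"unlabeled sample(s): {missing[:5]}")
    labels = labels.loc[samples]
    means = eigengenes.values.T.groupby(labels).mean().T  # modules x conditions
    means = means[sorted(means.columns)]
    best = means.idxmax(axis=1)  # idxmax takes the first (lexicographic) on ties
    out = means.copy()
    out.insert(0, "best_condition", best)
    return out
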