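"""Log-space hypergeometric over-representation statistics.

All tail probabilities are computed with log-gamma arithmetic and
log-sum-exp so p-values far below double-precision underflow (observed
overlaps can sit near 10**-300) remain exact in log10 space.  The
convention is the upper tail P(X >= k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "hypergeom_log_tail",
    "bh_adjust",
    "enrich_gene_sets",
    "positional_enrichment",
    "overlap_comparison",
    "OverlapResult",
    "load_module_annotation",
    "count_modules_by_term",
]

_LN10 = np.log(10.0)


def _log_comb(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_log_tail(N: int, K: int, n: int, k: int) -> float:
    """log10 of P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: background size, K: marked items, n: draws, k: observed overlap.
    Exact in log space via log-gamma terms and log-sum-exp over the tail.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(n, K):
        raise ValueError(f"k={k} exceeds min(n, K)={min(n, K)}")
    if k <= max(0, n + K - N):
        return 0.0  # the whole support is in the tail: P = 1
    i = np.arange(k, min(n, K) + 1, dtype=float)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(logsumexp(log_terms) / _LN10)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved.

    adj_i = min_{j >= i} (p_(j) * m / j), capped at 1, where p_(j) are the
    sorted raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def enrich_gene_sets(
    query: set[str],
    collection: dict[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each collection set in the query.

    The query must be a subset of the background; collection sets are
    intersected with the background first, and sets that do not intersect
    it are skipped with a warning.  Returns one row per tested term with
    (term, K, k, log10_p, p, adjusted_p), sorted by p ascending.
    """
    query = set(query)
    background = set(background)
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    stray = query - background
    if stray:
        raise ValueError(f"query gene(s) not in background: {sorted(stray)[:5]}")
    N = len(background)
    n = len(query)
    rows = []
    for term, members in collection.items():
        members = set(members) & background
        if not members:
            warnings.warn(f"term {term!r} does not intersect the background; skipped",
                          stacklevel=2)
            continue
        K = len(members)
        k = len(query & members)
        log10_p = hypergeom_log_tail(N, K, n, k)
        rows.append((term, K, k, log10_p))
    if not rows:
        return pd.DataFrame(columns=["term", "K", "k", "log10_p", "p", "adjusted_p"])
    table = pd.DataFrame(rows, columns=["term", "K", "k", "log10_p"])
    table["p"] = np.power(10.0, table["log10_p"])
    table["adjusted_p"] = bh_adjust(table["p"].to_numpy())
    table = table.sort_values(["log10_p", "term"]).reset_index(drop=True)
    table.attrs["background_size"] = N
    table.attrs["query_size"] = n
    return table


def positional_enrichment(
    module_genes: set[str],
    positions: pd.DataFrame,
    window_size: int = 50,
    step: int = 25,
    p_threshold: float = 7e-7,
) -> pd.DataFrame:
    """Sliding-window chromosomal over-representation of a gene set.

    Genes are ranked by start coordinate per chromosome; each window of
    ``window_size`` consecutive genes (stride ``step``), plus every whole
    chromosome, is tested with the upper-tail hypergeometric against
    N = all positioned genes.  Windows below ``p_threshold`` are merged per
    chromosome when they overlap.  Returns (chromosome, start, end,
    n_window, k, log10_p, whole_chromosome) rows for significant regions.
    """
    if window_size < 2:
        raise ValueError(f"window_size must be >= 2, got {window_size}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    module_genes = set(module_genes)
    positioned = set(positions["gene_id"].astype(str))
    missing = module_genes - positioned
    if missing:
        raise ValueError(f"unpositioned module gene(s): {sorted(missing)[:10]}")
    N = len(positioned)
    n = len(module_genes)
    degenerate = n == N
    if degenerate:
        warnings.warn("module covers every positioned gene; result is degenerate",
                      stacklevel=2)
    log_thresh = np.log10(p_threshold)
    hits = []
    for chrom, sub in positions.groupby("chromosome", sort=True):
        sub = sub.sort_values(["start", "gene_id"]).reset_index(drop=True)
        genes = sub["gene_id"].astype(str).to_numpy()
        member = np.isin(genes, list(module_genes))
        n_chrom = len(genes)
        windows = []
        if n_chrom >= window_size:
            starts = list(range(0, n_chrom - window_size + 1, step))
            if starts[-1] != n_chrom - window_size:
                starts.append(n_chrom - window_size)
            windows = [(s, s + window_size, False) for s in starts]
        windows.append((0, n_chrom, True))
        for lo, hi, whole in windows:
            K = hi - lo
            k = int(member[lo:hi].sum())
            log10_p = hypergeom_log_tail(N, K, n, k)
            if log10_p < log_thresh or (degenerate and whole):
                hits.append(
                    dict(chromosome=chrom, lo=lo, hi=hi,
                         start=int(sub["start"].iloc[lo]),
                         end=int(sub["end"].iloc[hi - 1]),
                         n_window=K, k=k, log10_p=log10_p,
                         whole_chromosome=whole)
                )
    merged = _merge_windows(hits)
    return pd.DataFrame(
        merged,
        columns=["chromosome", "start", "end", "n_window", "k", "log10_p",
                 "whole_chromosome"],
    )


def _merge_windows(hits: list[dict]) -> list[dict]:
    """Merge overlapping significant windows per chromosome (whole-chromosome
    hits are kept separate)."""
    out = []
    windows = sorted(
        (h for h in hits if not h["whole_chromosome"]),
        key=lambda h: (h["chromosome"], h["lo"], h["hi"]),
    )
    current = None
    for h in windows:
        if (
            current is not None
            and h["chromosome"] == current["chromosome"]
            and h["lo"] < current["hi"]
        ):
            current["hi"] = max(current["hi"], h["hi"])
            current["end"] = max(current["end"], h["end"])
            current["n_window"] = current["hi"] - current["lo"]
            current["k"] = max(current["k"], h["k"])
            current["log10_p"] = min(current["log10_p"], h["log10_p"])
        else:
            if current is not None:
                out.append(current)
            current = dict(h)
    if current is not None:
        out.append(current)
    out.extend(h for h in hits if h["whole_chromosome"])
    return [
        {k: v for k, v in h.items() if k not in ("lo", "hi")}
        for h in out
    ]


@dataclass(frozen=True)
class OverlapResult:
    """Upper-tail hypergeometric comparison of two gene sets."""

    N: int
    n_a: int
    n_b: int
    k: int
    log10_p: float

    @property
    def fraction_of_a(self) -> float:
        return self.k / self.n_a if self.n_a else 0.0

    @property
    def p(self) -> float:
        return float(10.0**self.log10_p)


def overlap_comparison(set_a: set[str], set_b: set[str], N: int) -> OverlapResult:
    """Significance of |set_a & set_b| on a background of N genes."""
    set_a, set_b = set(set_a), set(set_b)
    if N < len(set_a | set_b):
        raise ValueError(
            f"background N={N} smaller than the union size {len(set_a | set_b)}"
        )
    k = len(set_a & set_b)
    log10_p = hypergeom_log_tail(N, len(set_b), len(set_a), k)
    return OverlapResult(N, len(set_a), len(set_b), k, log10_p)


_FIXTURE_FIELDS = {
    "BP": "bp_term",
    "CC": "cc_term",
    "MF": "mf_term",
    "chromosome": "chromosome",
}


def load_module_annotation() -> pd.DataFrame:
    """Packaged 48-module GO/chromosome annotation table."""
    with resources.files("coexnet.data").joinpath("module_annotation.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t", dtype={"module": str})
    if len(table) != 48:
        raise RuntimeError(f"annotation fixture has {len(table)} rows, expected 48")
    return table


def count_modules_by_term(fixture: pd.DataFrame, field: str, term: str) -> int:
    """Number of fixture modules whose chosen annotation equals ``term``
    (case-insensitive; p-values ignored). ``field`` is BP, CC, MF or
    chromosome."""
    if field not in _FIXTURE_FIELDS:
        raise ValueError(f"unknown field {field!r}; choose from {sorted(_FIXTURE_FIELDS)}")
    col = fixture[_FIXTURE_FIELDS[field]].fillna("")
    return int((col.str.strip().str.lower() == term.strip().lower()).sum())
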