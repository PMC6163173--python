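"""Optional diagnostic charts (requires matplotlib).

Two plots mirror the pipeline's headline per-module summaries: a mean +- SD
bar chart of connectivity stability and a radar chart of module expression
variation (RSD).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def stability_bars(report, path=None, ax=None):
    """Bar chart of per-module stability (mean connectivity correlation +- SD)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    frame = report.to_frame().sort_values("mean_correlation", ascending=False)
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.3 * len(frame)), 4))
    ax.bar(
        frame["module"],
        frame["mean_correlation"],
        yerr=frame["sd_correlation"],
        capsize=2,
        color="steelblue",
    )
    ax.axhline(0.8, color="grey", linestyle="--", linewidth=1)
    ax.set_ylabel("connectivity correlation (mean ± SD)")
    ax.set_ylim(0, 1.05)
    ax.tick_params(axis="x", rotation=90)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


def rsd_radar(module_means: pd.Series, path=None):
    """Radar chart of per-module mean RSD, sorted descending."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    values = module_means.sort_values(ascending=False)
    n = len(values)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    fig, ax = plt.subplots(subplot_kw=dict(polar=True), figsize=(6, 6))
    ax.plot(np.append(angles, angles[0]), np.append(values.to_numpy(), values.iloc[0]),
            "o-", color="royalblue", linewidth=1)
    ax.set_xticks(angles)
    ax.set_xticklabels(values.index, fontsize=7)
    ax.set_title("module expression variation (mean RSD)")
    if path is not None:
        fig.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(fig)
    return ax
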