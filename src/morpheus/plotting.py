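"""Optional graphical side outputs.

Plots are strictly derived artifacts: every figure's underlying numbers
exist in a TSV first. All functions write a file and return its path.
"""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .occupancy import OccupancyResult
from .roc import RocResult
from .scanner import SiteHit, score_histogram, score_profile


def plot_score_profile(
    hits: Sequence[SiteHit], seq_length: int, path, title: str = ""
) -> str:
    """Per-position site scores of one sequence, one trace per strand."""
    prof = score_profile(hits, seq_length)
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(prof["starts"], prof["forward"], ".", ms=4, label="+ strand")
    ax.plot(prof["starts"], prof["reverse"], ".", ms=4, label="- strand")
    ax.set_xlabel("window start (0-based)")
    ax.set_ylabel("score")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def plot_score_histogram(
    hits: Sequence[SiteHit], bin_width: float, path, title: str = ""
) -> str:
    edges, counts = score_histogram(hits, bin_width)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    if counts.size:
        ax.bar(edges[:-1], counts, width=bin_width, align="edge", edgecolor="k")
    ax.set_xlabel("score")
    ax.set_ylabel("site count")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def plot_occupancy_bars(results: Sequence[OccupancyResult], path) -> str:
    """Occupancy comparison between DNA regions."""
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(results)), 3.5))
    ax.bar(range(len(results)), [r.occupancy for r in results], edgecolor="k")
    ax.set_xticks(range(len(results)))
    ax.set_xticklabels([r.seq_id for r in results], rotation=90, fontsize=7)
    ax.set_ylabel("predicted occupancy")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def plot_roc(result: RocResult, path) -> str:
    """ROC curve with its AUC, plus the two-class statistic histograms."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    pts = np.asarray(result.points)
    ax1.plot(pts[:, 0], pts[:, 1], "-o", ms=3)
    ax1.plot([0, 1], [0, 1], "--", color="grey", lw=1)
    ax1.set_xlabel("false positive rate")
    ax1.set_ylabel("true positive rate")
    ax1.set_title(f"AUC = {result.auc:.4f} ({result.statistic})")
    both = result.pos_values + result.neg_values
    bins = np.histogram_bin_edges(both, bins=30) if both else 10
    ax2.hist(result.pos_values, bins=bins, alpha=0.6, label=f"bound (n={result.n_pos})")
    ax2.hist(
        result.neg_values, bins=bins, alpha=0.6, label=f"unbound (n={result.n_neg})"
    )
    ax2.set_xlabel(result.statistic)
    ax2.set_ylabel("sequences")
    ax2.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
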