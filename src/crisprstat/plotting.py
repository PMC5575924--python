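"""Figure builders: box plots, fitted histograms, CDF overlays, polar and
probability plots, and the multiplicity histograms.

Every function returns a matplotlib Figure so callers decide whether to
save or show; the report writer saves PNGs.
"""
from __future__ import annotations

from typing import Dict, Optional, Sequence

import matplotlib

matplotlib.use("Agg")  # headless-safe; report generation never needs a display
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .location import PolarHistogram
from .sizedist import SizeSample, family_cdf, probability_plot_points


def boxplots(samples: Sequence[SizeSample], log10: bool = False):
    """Side-by-side box plots of spacer counts per group."""
    fig, ax = plt.subplots(figsize=(1.2 * max(len(samples), 4) + 2, 4))
    data = [np.log10(s.counts) if log10 else s.counts for s in samples]
    ax.boxplot(data, tick_labels=[s.label for s in samples])
    ax.set_ylabel("log10 spacers per array" if log10 else "spacers per array")
    ax.set_title("CRISPR array size by group")
    fig.tight_layout()
    return fig


def size_histogram(sample: SizeSample, fits: Dict[str, float]):
    """Histogram of counts with fitted pmf curves overlaid.

    ``fits`` maps family name to its fitted parameter.
    """
    from scipy import stats

    fig, ax = plt.subplots(figsize=(7, 4.5))
    xmax = int(sample.counts.max())
    bins = np.arange(-0.5, xmax + 1.5)
    ax.hist(sample.counts, bins=bins, density=True, alpha=0.5,
            color="steelblue", label="observed")
    support = np.arange(0, xmax + 1)
    for family, theta in fits.items():
        if family == "geometric":
            pmf = stats.geom.pmf(support + 1, theta)
        else:
            pmf = stats.poisson.pmf(support, theta)
        ax.plot(support, pmf, label=f"{family} ({theta:.4g})")
    ax.set_xlabel("spacers per array")
    ax.set_ylabel("probability")
    ax.set_title(f"Array size distribution: {sample.label}")
    ax.legend()
    fig.tight_layout()
    return fig


def cdf_comparison(sample: SizeSample, fits: Dict[str, float]):
    """Empirical CDF against the fitted cumulative curves."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    xmax = int(sample.counts.max())
    support = np.arange(0, xmax + 1)
    femp = np.searchsorted(np.sort(sample.counts), support, side="right") / sample.n
    ax.step(support, femp, where="post", color="black", label="empirical")
    for family, theta in fits.items():
        ax.step(support, family_cdf(family, theta, support), where="post",
                label=f"{family} ({theta:.4g})")
    ax.set_xlabel("spacers per array")
    ax.set_ylabel("cumulative probability")
    ax.set_title(f"Cumulative fit: {sample.label}")
    ax.legend()
    fig.tight_layout()
    return fig


def probability_plot(sample: SizeSample, family: str, theta: float):
    pts = probability_plot_points(sample, family, theta)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pts[:, 0], pts[:, 1], s=8, alpha=0.6)
    lim = max(pts.max(), 1)
    ax.plot([0, lim], [0, lim], color="grey", lw=1, ls="--")
    ax.set_xlabel(f"{family} quantile")
    ax.set_ylabel("observed order statistic")
    ax.set_title(f"Probability plot: {sample.label} vs {family}")
    fig.tight_layout()
    return fig


def polar_plot(hist: PolarHistogram, title: Optional[str] = None):
    """Circular histogram of standardized array start positions."""
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="polar")
    theta = np.deg2rad(np.arange(360))
    ax.bar(theta, hist.bin_counts, width=np.deg2rad(1.0), color="firebrick"
           if hist.strand == "-" else "steelblue")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    label = title or f"Array start positions (strand {hist.strand}, n={hist.total})"
    ax.set_title(label)
    fig.tight_layout()
    return fig


def multiplicity_histograms(curve: pd.DataFrame):
    """Genome counts and largest-proximal proportion by array multiplicity."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].bar(curve["n_arrays"], curve["n_genomes"], color="steelblue")
    axes[0].set_xlabel("arrays per genome")
    axes[0].set_ylabel("genomes")
    axes[0].set_title("Array multiplicity")
    axes[1].bar(curve["n_arrays"], curve["proportion"], color="seagreen")
    axes[1].set_xlabel("arrays per genome")
    axes[1].set_ylabel("proportion proximal largest")
    axes[1].set_ylim(0, 1.05)
    axes[1].set_title("Largest-proximal proportion")
    fig.tight_layout()
    return fig
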