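"""Basic diagnostic figures for fitted objects and pooled duration samples."""

from __future__ import annotations

import numpy as np

from .rivalry import normalize_pooled_durations


def plot_phase_histogram(d_de_sample, d_nde_sample, d_de_median, ax=None, bins=30):
    """Pooled per-eye phase-duration histograms, normalised by the dominant-eye
    median so the dominant-eye sample has median 1."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    de = normalize_pooled_durations(d_de_sample, d_de_median)
    nde = normalize_pooled_durations(d_nde_sample, d_de_median)
    edges = np.histogram_bin_edges(np.concatenate([de, nde]), bins=bins)
    ax.hist(de, bins=edges, alpha=0.6, label="dominant eye", color="seagreen")
    ax.hist(nde, bins=edges, alpha=0.6, label="non-dominant eye", color="steelblue")
    ax.set_xlabel("phase duration / median dominant-eye duration")
    ax.set_ylabel("count")
    ax.legend()
    return ax


def plot_correlation(x, y, result, ax=None, xlabel=None, ylabel=None):
    """Scatter with the best-fitting line and the correlation annotation."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ax.scatter(x, y, color="k")
    slope, intercept = np.polyfit(x, y, 1)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, slope * xs + intercept, color="crimson")
    ax.set_xlabel(xlabel or result.measure_x)
    ax.set_ylabel(ylabel or result.measure_y)
    ax.set_title(f"{result.method} r = {result.r:.2f}, p = {result.p:.3f} (n={result.n})")
    return ax
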