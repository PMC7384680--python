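"""Publication-style figures for ensemble results.

All functions take an ``ax`` keyword or create their own figure and return
it; callers save with ``fig.savefig``.  Uses the non-interactive backend.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def plot_likelihood_profiles(profiles: dict, threshold: float = -140.0, ax=None,
                             only_passing: bool = True):
    """Descending TLL profiles per scenario (highest-ranked members first)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label in sorted(profiles):
        tll = np.asarray(profiles[label], dtype=float)
        tll = tll[np.isfinite(tll)]
        if only_passing:
            tll = tll[tll > threshold]
        if len(tll) == 0:
            continue
        ax.plot(np.arange(1, len(tll) + 1), tll, label=f"scenario {label}")
    ax.axhline(threshold, color="k", ls="--", lw=0.8)
    ax.set_xlabel("model rank")
    ax.set_ylabel("total log-likelihood")
    if ax.get_legend_handles_labels()[0]:
        ax.legend(fontsize=8)
    return ax


def plot_bin_enrichment(bins, param_name: str = "", prior_values=None, ax=None):
    """Fig-6-style bar plot: per-bin log-ratio, significant bins highlighted.

    ``bins`` is the frame from :func:`gblnet.enrichment.bin_enrichment`;
    ``prior_values`` (optional) adds the sampled prior density in the
    background.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    centers = np.sqrt(bins["bin_lo"] * bins["bin_hi"])
    widths = (bins["bin_hi"] - bins["bin_lo"]) * 0.85
    colors = np.where(bins["significant"], "#7b3294", "#bdbdbd")
    lr = bins["log_ratio"].replace([np.inf, -np.inf], np.nan).fillna(0.0)
    ax.bar(centers, lr, width=widths, color=colors, edgecolor="none")
    if prior_values is not None:
        ax2 = ax.twinx()
        ax2.hist(prior_values, bins=np.asarray(
            list(bins["bin_lo"]) + [bins["bin_hi"].iloc[-1]]),
            histtype="step", color="#9ecae1", density=True)
        ax2.set_yticks([])
    ax.set_xscale("log")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel(param_name or "parameter value")
    ax.set_ylabel("log2(observed / expected)")
    return ax


def plot_growth_fit(results, ax=None):
    """Observed cell counts with the fitted curve and the confidence set."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t_obs = results.model.time_min
    grid = np.linspace(0.0, float(t_obs.max()), 300)
    for gp, _ in results.confidence_set:
        from .growth import population
        n, _mu = population(grid, gp)
        ax.plot(grid / 60.0, n, color="#cccccc", lw=0.7)
    ax.plot(grid / 60.0, results.predict(grid), color="#d95f02", lw=1.6,
            label="best fit")
    ax.plot(t_obs / 60.0, results.model.cells, "o", color="k", ms=4,
            label="observations")
    ax.set_yscale("log")
    ax.set_xlabel("time [h]")
    ax.set_ylabel("cells")
    ax.legend(fontsize=8)
    return ax
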