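"""Parameter-enrichment statistics over the high-likelihood ensemble members.

Three complementary analyses identify parameters that shape model quality:

* per-parameter two-sample Kolmogorov–Smirnov tests comparing the selected
  (high-TLL) members with the full sampled ensemble, family-wise error
  controlled by a strict Bonferroni correction over the number of sampled
  parameters (44 in the default configuration);
* per-bin enrichment: the parameter range is split into (log-spaced) bins,
  expected bin probabilities come from the full ensemble's empirical
  distribution, observed counts from the selected members, and each bin gets
  a two-tailed binomial test with Benjamini–Hochberg FDR control at 0.05
  across the bins of that parameter (a Bonferroni option is provided);
* two-sample K–S tests for the six growth-curve parameters, which are fitted
  rather than sampled, Bonferroni-corrected over the six tests.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .growth import FIELD_NAMES as GROWTH_FIELDS
from .growth import GrowthParams

__all__ = [
    "benjamini_hochberg",
    "ks_enrichment",
    "bin_enrichment",
    "growth_param_enrichment",
]

logger = logging.getLogger(__name__)


def benjamini_hochberg(pvals: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """BH step-up procedure: boolean rejection flags controlling FDR at ``alpha``."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def ks_enrichment(ens, selected: Sequence[int], alpha: float = 0.05) -> pd.DataFrame:
    """Two-sample K–S test per sampled parameter: selected members vs full ensemble.

    ``selected`` holds member indices (a non-empty strict subset).  The
    significance level is ``alpha`` divided by the number of parameters
    tested (strict Bonferroni).  Returns a frame indexed by parameter with
    the K–S statistic, raw p-value and Bonferroni flag.
    """
    selected = np.asarray(sorted(set(int(i) for i in selected)), dtype=int)
    if len(selected) == 0:
        raise ValueError("no members selected: cannot test enrichment")
    if len(selected) >= ens.n:
        raise ValueError("selection must be a strict subset of the ensemble")
    if selected.min() < 0 or selected.max() >= ens.n:
        raise ValueError("selected member index out of range")
    m = len(ens.param_ids)
    cutoff = alpha / m
    rows = []
    for j, pid in enumerate(ens.param_ids):
        full = ens.values[:, j]
        sel = full[selected]
        if np.ptp(full) == 0:  # degenerate prior: identical distributions
            stat, p = 0.0, 1.0
        else:
            res = stats.ks_2samp(sel, full, mode="auto")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"parameter": pid, "ks_statistic": stat, "pvalue": p,
                     "significant": p < cutoff})
    df = pd.DataFrame(rows).set_index("parameter")
    df.attrs["n_tests"] = m
    df.attrs["alpha"] = alpha
    return df


def bin_enrichment(prior_values: Sequence[float], selected_values: Sequence[float],
                   n_bins: int = 20, log_bins: bool = True, fdr: float = 0.05,
                   method: str = "bh") -> pd.DataFrame:
    """Bin-wise enrichment of selected parameter values over the full ensemble.

    Bins span the sampled range (log-spaced for rate-like parameters);
    expected bin probabilities are the full ensemble's empirical bin
    fractions; observed counts come from the selected members.  Each bin is
    tested with a two-tailed binomial test and flagged under BH FDR control
    (``method="bonferroni"`` divides by the bin count instead).  Bins with
    zero expected probability are merged into their neighbours.  The
    ``log_ratio`` column is log2(observed fraction / expected fraction).
    """
    full = np.asarray(prior_values, dtype=float)
    sel = np.asarray(selected_values, dtype=float)
    if n_bins < 3:
        raise ValueError("need at least 3 bins")
    if len(full) == 0 or len(sel) == 0:
        raise ValueError("empty value arrays")
    if method not in ("bh", "bonferroni"):
        raise ValueError("method must be 'bh' or 'bonferroni'")
    lo, hi = float(full.min()), float(full.max())
    if lo == hi:
        raise ValueError("degenerate parameter: all sampled values identical")
    if log_bins:
        if lo <= 0:
            raise ValueError("log-spaced bins require positive values")
        edges = np.geomspace(lo, hi, n_bins + 1)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)  # include the max value

    # merge empty expected bins into their neighbours
    while True:
        exp_counts, _ = np.histogram(full, bins=edges)
        if len(edges) <= 2 or np.all(exp_counts > 0):
            break
        i = int(np.flatnonzero(exp_counts == 0)[0])
        drop = i + 1 if i < len(exp_counts) - 1 else i
        logger.info("bin_enrichment: merging empty bin %d into its neighbour", i)
        edges = np.delete(edges, drop)

    exp_counts, _ = np.histogram(full, bins=edges)
    obs_counts, _ = np.histogram(sel, bins=edges)
    n_sel = len(sel)
    exp_p = exp_counts / len(full)
    obs_p = obs_counts / n_sel
    pvals = np.array([
        stats.binomtest(int(k), n_sel, p, alternative="two-sided").pvalue
        for k, p in zip(obs_counts, exp_p)])
    if method == "bh":
        flags = benjamini_hochberg(pvals, fdr)
    else:
        flags = pvals < fdr / len(pvals)
    with np.errstate(divide="ignore"):
        log_ratio = np.log2(obs_p / exp_p)
    return pd.DataFrame({
        "bin_lo": edges[:-1], "bin_hi": edges[1:],
        "expected_p": exp_p, "expected_count": exp_p * n_sel,
        "observed_count": obs_counts, "observed_p": obs_p,
        "log_ratio": log_ratio, "pvalue": pvals, "significant": flags,
    })


def growth_param_enrichment(initial_fits: Sequence[GrowthParams],
                            selected_fits: Sequence[GrowthParams],
                            alpha: float = 0.05) -> pd.DataFrame:
    """Two-sample K–S per growth parameter, Bonferroni over the six tests.

    Growth parameters are produced by multi-start curve fitting rather than
    prior sampling, so enrichment among high-TLL members is assessed by
    comparing the selected fits against the initial confidence set.
    """
    if len(initial_fits) < 2 or len(selected_fits) < 2:
        raise ValueError("need at least 2 parameter vectors in each set")
    init = np.array([gp.to_array() for gp in initial_fits])
    sel = np.array([gp.to_array() for gp in selected_fits])
    cutoff = alpha / len(GROWTH_FIELDS)
    rows = []
    for j, name in enumerate(GROWTH_FIELDS):
        if np.ptp(init[:, j]) == 0 and np.ptp(sel[:, j]) == 0 \
                and init[0, j] == sel[0, j]:
            stat, p = 0.0, 1.0
        else:
            res = stats.ks_2samp(sel[:, j], init[:, j], mode="auto")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"parameter": name, "ks_statistic": stat, "pvalue": p,
                     "significant": p < cutoff})
    df = pd.DataFrame(rows).set_index("parameter")
    df.attrs["n_tests"] = len(GROWTH_FIELDS)
    df.attrs["alpha"] = alpha
    return df
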