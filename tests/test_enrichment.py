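"""Parameter-enrichment statistics: K–S tests, binomial bins, BH control."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gblnet import sample_ensemble
from gblnet.enrichment import (
    benjamini_hochberg,
    bin_enrichment,
    growth_param_enrichment,
    ks_enrichment,
)
from gblnet.growth import GrowthParams


def _bh_bruteforce(pvals, alpha):
    """Literal step-up definition: find the largest k with p_(k) <= k/m * a,
    reject hypotheses with the k smallest p-values."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank / m * alpha:
            k_max = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


@settings(derandomize=True, max_examples=80)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40),
       st.sampled_from([0.01, 0.05, 0.1]))
def test_bh_agrees_with_bruteforce_stepup(pvals, alpha):
    got = benjamini_hochberg(pvals, alpha)
    ref = _bh_bruteforce(np.asarray(pvals), alpha)
    assert np.array_equal(got, ref)


def test_bh_empty_and_extremes():
    assert len(benjamini_hochberg([], 0.05)) == 0
    assert benjamini_hochberg([1e-10], 0.05)[0]
    assert not benjamini_hochberg([0.9], 0.05)[0]


def test_ks_enrichment_runs_44_tests(small_ensemble):
    report = ks_enrichment(small_ensemble, [0, 1, 2, 3, 4])
    assert len(report) == 44
    assert report.attrs["n_tests"] == 44


def test_ks_random_selection_finds_nothing(priors):
    """Null calibration: a uniformly random 10% selection should produce no
    Bonferroni-significant parameter in a typical seeded run."""
    ens = sample_ensemble(priors, 2000, seed=42)
    rng = np.random.default_rng(7)
    sel = rng.choice(ens.n, size=200, replace=False)
    report = ks_enrichment(ens, sel)
    assert int(report["significant"].sum()) == 0


def test_ks_flags_constructed_bias(priors):
    ens = sample_ensemble(priors, 2000, seed=42)
    d_a = ens.column("d_A")
    sel = np.flatnonzero(d_a > np.median(d_a))[:500]
    report = ks_enrichment(ens, sel)
    assert bool(report.loc["d_A", "significant"])
    # unrelated parameters stay clean
    assert not report.drop(index="d_A")["significant"].all()


def test_ks_selection_validation(small_ensemble):
    with pytest.raises(ValueError, match="no members"):
        ks_enrichment(small_ensemble, [])
    with pytest.raises(ValueError, match="strict subset"):
        ks_enrichment(small_ensemble, list(range(small_ensemble.n)))


def test_ks_type_one_error_calibrated(priors):
    """Repeated random selection: the fraction of runs with any Bonferroni
    hit stays within alpha plus Monte-Carlo slack."""
    ens = sample_ensemble(priors, 1000, seed=5)
    rng = np.random.default_rng(11)
    alpha = 0.05
    n_rep = 200
    hits = 0
    for _ in range(n_rep):
        sel = rng.choice(ens.n, size=100, replace=False)
        report = ks_enrichment(ens, sel, alpha=alpha)
        hits += int(report["significant"].any())
    frac = hits / n_rep
    mc_sd = np.sqrt(alpha * (1 - alpha) / n_rep)
    assert frac <= alpha + 3 * mc_sd


def test_bin_enrichment_self_comparison_is_null(rng):
    vals = rng.lognormal(-3, 1, size=3000)
    out = bin_enrichment(vals, vals, n_bins=15)
    assert np.allclose(out["log_ratio"], 0.0)
    assert not out["significant"].any()


def test_bin_enrichment_extreme_concentration(rng):
    full = rng.lognormal(-3, 1, size=3000)
    sel = full[(full > np.quantile(full, 0.4)) & (full < np.quantile(full, 0.45))]
    out = bin_enrichment(full, sel, n_bins=10)
    hot = out[out["observed_count"] > 0]
    assert (hot["log_ratio"] > 0).any()
    assert out.loc[out["log_ratio"].idxmax(), "significant"]
    cold = out[out["observed_count"] == 0]
    assert np.all(np.isneginf(cold["log_ratio"]))


def test_bin_enrichment_flags_fast_scba_degradation(priors):
    """Constructed positive control: selecting members with fast ScbA
    turnover (d_A > 0.01 1/min) must enrich the high-d_A bins."""
    ens = sample_ensemble(priors, 4000, seed=13)
    d_a = ens.column("d_A")
    sel = d_a[d_a > 0.01]
    out = bin_enrichment(d_a, sel, n_bins=20)
    enriched = out[(out["significant"]) & (out["log_ratio"] > 0)]
    assert len(enriched) > 0
    assert np.all(enriched["bin_lo"] > 0.005)
    depleted = out[(out["significant"]) & (out["log_ratio"] < 0)]
    assert np.all(depleted["bin_hi"] <= 0.011)


def test_bin_log_ratio_antisymmetry(rng):
    """Swapping the 'selected' and 'expected' roles negates every finite
    log-ratio (same bin support: the subset shares the sample's extremes)."""
    a = np.sort(rng.lognormal(0, 1, size=2001))
    b = a[::2]  # includes both extremes, so bins coincide in both directions
    ab = bin_enrichment(a, b, n_bins=8)
    ba = bin_enrichment(b, a, n_bins=8)
    assert np.allclose(ab["bin_lo"], ba["bin_lo"])
    fwd = ab["log_ratio"].to_numpy()
    rev = ba["log_ratio"].to_numpy()
    finite = np.isfinite(fwd) & np.isfinite(rev)
    assert finite.any()
    assert np.allclose(fwd[finite], -rev[finite])


def test_bin_enrichment_merges_empty_bins(rng):
    low = rng.uniform(1.0, 2.0, size=500)
    high = rng.uniform(100.0, 200.0, size=500)
    full = np.concatenate([low, high])
    out = bin_enrichment(full, full[:500], n_bins=12)
    assert np.all(out["expected_p"] > 0)
    assert len(out) < 12  # the gap bins were merged away


def test_bin_enrichment_validation(rng):
    vals = rng.lognormal(0, 1, 100)
    with pytest.raises(ValueError, match="3 bins"):
        bin_enrichment(vals, vals, n_bins=2)
    with pytest.raises(ValueError, match="identical"):
        bin_enrichment(np.ones(10), np.ones(5))
    with pytest.raises(ValueError, match="method"):
        bin_enrichment(vals, vals, method="holm")


def _growth_set(rng, n, lam_mu=600.0):
    out = []
    for _ in range(n):
        out.append(GrowthParams(
            K=float(rng.uniform(7.14e12, 9e12)),
            N0=float(rng.uniform(5e10, 2e11)),
            mu_max=float(rng.uniform(0.0034, 0.0075)),
            v=float(rng.uniform(0.0015, 0.58)),
            m=float(rng.uniform(0.47, 2.46)),
            lam=float(rng.uniform(0.6, 1.4) * lam_mu)))
    return out


def test_growth_enrichment_null_and_positive_control(rng):
    initial = _growth_set(rng, 120)
    null = growth_param_enrichment(initial, initial)
    assert not null["significant"].any()
    assert (null["pvalue"] == 1.0).all()
    assert null.attrs["n_tests"] == 6
    # top-quartile lag selection flags lambda (Bonferroni over 6 tests)
    lams = np.array([g.lam for g in initial])
    sel = [g for g in initial if g.lam >= np.quantile(lams, 0.75)]
    pos = growth_param_enrichment(initial, sel)
    assert bool(pos.loc["lam", "significant"])


def test_growth_enrichment_needs_two_per_set(rng):
    initial = _growth_set(rng, 10)
    with pytest.raises(ValueError, match="at least 2"):
        growth_param_enrichment(initial, initial[:1])
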