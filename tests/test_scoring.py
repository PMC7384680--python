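"""Total log-likelihood, ranking, predictive density, threshold extraction."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from gblnet import total_log_likelihood
from gblnet.network import IDX, SPECIES
from gblnet.scoring import (
    TargetFeatures,
    TargetSeries,
    activation_threshold,
    max_achievable_tll,
    predictive_density,
    rank_and_count,
)
from gblnet.simulate import SimResult


def _fake_sim(t, values_by_species, member=0, scenario="C"):
    y = np.zeros((len(SPECIES), len(t)))
    for sp, vals in values_by_species.items():
        y[IDX[sp]] = vals
    return SimResult(member, scenario, "ok", np.asarray(t, float), y)


def test_zero_residual_tll_is_the_normalisation_sum(noiseless_study):
    """A member reproducing the targets exactly scores the sum of Gaussian
    normalisation constants — the maximal achievable TLL."""
    s = noiseless_study
    tll = total_log_likelihood(s.true_sim, s.targets, s.true_params)
    assert tll == pytest.approx(max_achievable_tll(s.targets), abs=1e-3)


def test_tll_matches_bruteforce_point_loop(study):
    sim, targets, params = study.true_sim, study.targets, study.true_params
    expected = 0.0
    for name, sp, sc in (("scbr", "r", "s_r"), ("scba", "a", "s_a")):
        series = getattr(targets, name)
        for t, v, sd in zip(series.times, series.values, series.sds):
            pred = float(np.interp(t, sim.t, sim.species(sp))) * params[sc]
            expected += norm.logpdf(pred, loc=v, scale=sd)
    thr = activation_threshold(sim, params)
    expected += norm.logpdf(thr, loc=targets.threshold_nM,
                            scale=targets.threshold_sd)
    got = total_log_likelihood(sim, targets, params)
    assert got == pytest.approx(expected, rel=1e-12)


def test_tll_decreases_when_any_residual_grows(study):
    base = total_log_likelihood(study.true_sim, study.targets, study.true_params)
    t = study.targets
    for i in (0, 10, 30):
        values = t.scbr.values.copy()
        values[i] += 5 * t.scbr.sds[i]
        worse = TargetFeatures(TargetSeries(t.scbr.times, values, t.scbr.sds),
                               t.scba, t.threshold_nM, t.threshold_sd)
        assert total_log_likelihood(study.true_sim, worse,
                                    study.true_params) < base


def test_failed_simulation_scores_minus_infinity(study):
    failed = SimResult(0, "C", "solver_failed", np.array([0.0, 1.0]),
                       np.empty((len(SPECIES), 0)))
    assert total_log_likelihood(failed, study.targets, study.true_params) \
        == -math.inf


def test_pass_threshold_is_strict():
    scores = pd.DataFrame({
        "member": [0, 1, 2], "scenario": ["C"] * 3,
        "status": ["ok"] * 3, "tll": [-139.5, -140.0, -math.inf],
        "passed": [None] * 3})
    out = rank_and_count(scores, threshold=-140.0)
    assert int(out["pass_counts"]["C"]) == 1
    table = out["table"].set_index("member")
    assert bool(table.loc[0, "passed"]) is True
    assert bool(table.loc[1, "passed"]) is False  # boundary fails
    assert bool(table.loc[2, "passed"]) is False


def test_counts_invariant_under_member_reordering(rng):
    tll = rng.normal(-150, 30, size=60)
    scores = pd.DataFrame({"member": np.arange(60), "scenario": "C",
                           "status": "ok", "tll": tll, "passed": False})
    shuffled = scores.sample(frac=1.0, random_state=1).reset_index(drop=True)
    a = rank_and_count(scores)
    b = rank_and_count(shuffled)
    assert a["pass_counts"].equals(b["pass_counts"])
    assert np.array_equal(a["profiles"]["C"], b["profiles"]["C"])


def test_identical_trajectories_give_identical_profiles(study, small_ensemble):
    """Two scenarios whose added mechanism is inert produce overlapping
    likelihood profiles (the identical-curves phenomenon)."""
    from gblnet import score_ensemble, simulate

    sims_c, sims_g = [], []
    for i in range(4):
        p = small_ensemble.member(i).replace(f_Ract=1.0)
        sims_c.append(simulate(p, "C", study.true_growth, member=i))
        sims_g.append(simulate(p, "G", study.true_growth, member=i))
    sc = score_ensemble(sims_c, study.targets, small_ensemble)
    sg = score_ensemble(sims_g, study.targets, small_ensemble)
    assert np.allclose(sc["tll"].to_numpy(), sg["tll"].to_numpy(),
                       equal_nan=True)


def test_predictive_density_edge_cases():
    one = pd.DataFrame({"member": [0], "scenario": ["C"], "status": ["ok"],
                        "tll": [0.0], "passed": [True]})
    pd_one = predictive_density(one)
    assert pd_one.loc["C", "predictive_density"] == pytest.approx(1.0)
    dead = pd.DataFrame({"member": [0, 1], "scenario": "D", "status": "solver_failed",
                         "tll": [-math.inf, -math.inf], "passed": False})
    assert predictive_density(dead).loc["D", "predictive_density"] == 0.0


def test_predictive_density_matches_high_precision_sum(rng):
    """Log-sum-exp result equals a naive extended-precision average."""
    tll = rng.uniform(-250, -50, size=100)
    scores = pd.DataFrame({"member": np.arange(100), "scenario": "C",
                           "status": "ok", "tll": tll, "passed": False})
    lpd = predictive_density(scores).loc["C", "log_predictive_density"]
    naive = np.longdouble(0)
    for v in tll:
        naive += np.exp(np.longdouble(v))
    naive = float(np.log(naive / 100))
    assert lpd == pytest.approx(naive, abs=1e-10)


def test_activation_threshold_from_constructed_crossing(true_params):
    """Hand-built trajectory: O_A free fraction dips then recovers through
    50% while C ramps linearly — the threshold is C at the interpolated
    upcrossing, in nM."""
    from gblnet.parameters import nm_per_molecule

    t = np.arange(0.0, 11.0)
    oa_free = np.array([1.0, 0.8, 0.4, 0.2, 0.1, 0.2, 0.4, 0.45, 0.6, 0.8, 0.9])
    c = t * 10.0
    sim = _fake_sim(t, {"OA_free": oa_free, "OA_1": 1.0 - oa_free, "C": c})
    # last upcrossing of 0.5 is between t=7 (0.45) and t=8 (0.6): w = 1/3
    expect_c = (7 + 1 / 3) * 10.0 * nm_per_molecule(true_params["V_cell"])
    thr = activation_threshold(sim, true_params)
    assert thr == pytest.approx(expect_c, rel=1e-9)


def test_activation_threshold_nan_when_never_activating(true_params):
    t = np.arange(0.0, 5.0)
    frac = np.array([1, 0.8, 0.4, 0.3, 0.2])
    sim = _fake_sim(t, {"OA_free": frac, "OA_1": 1.0 - frac, "C": t})
    assert math.isnan(activation_threshold(sim, true_params))


def test_never_activating_member_gets_fixed_penalty(study):
    t = study.targets
    frac = np.linspace(1, 0.1, 61)
    sim = _fake_sim(np.arange(0.0, 3601.0, 60.0),
                    {"OA_free": frac, "OA_1": 1.0 - frac})
    tll = total_log_likelihood(sim, t, study.true_params,
                               missing_threshold_penalty=-25.0)
    tll2 = total_log_likelihood(sim, t, study.true_params,
                                missing_threshold_penalty=-50.0)
    assert tll - tll2 == pytest.approx(25.0)


def test_target_features_frame_round_trip(study):
    df = study.targets.to_frame()
    back = TargetFeatures.from_frame(df)
    assert np.array_equal(back.scbr.values, study.targets.scbr.values)
    assert back.threshold_nM == study.targets.threshold_nM
    assert back.n_points() == study.targets.n_points()


def test_target_series_validation():
    with pytest.raises(ValueError, match="positive"):
        TargetSeries(np.array([0.0]), np.array([1.0]), np.array([0.0]))
    with pytest.raises(ValueError):
        TargetSeries(np.array([0.0, 1.0]), np.array([1.0]), np.array([1.0]))
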