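"""Reaction-network structure, scenario toggling and ODE right-hand side."""

import numpy as np
import pytest

from gblnet import ScenarioConfig, build_network, initial_state, rhs, simulate
from gblnet.growth import population
from gblnet.network import (
    IDX,
    SPECIES,
    _OPERATOR_GROUPS,
    compile_rhs,
    network_for,
)
from gblnet.parameters import SAMPLED_PARAMETERS

from conftest import random_parameter_sets


@pytest.mark.parametrize("label,ra,as_,ract", [
    ("A", False, False, False), ("B", True, False, False),
    ("C", False, True, False), ("D", False, False, True),
    ("E", True, True, False), ("F", True, False, True),
    ("G", False, True, True), ("H", True, True, True),
])
def test_scenario_label_flag_mapping(label, ra, as_, ract):
    sc = ScenarioConfig.from_label(label)
    assert (sc.RA, sc.AS, sc.Ract, sc.TI) == (ra, as_, ract, True)
    assert ScenarioConfig(RA=ra, AS=as_, Ract=ract).label == label


def test_interference_is_mandatory():
    with pytest.raises(ValueError, match="interference"):
        ScenarioConfig(TI=False)
    with pytest.raises(ValueError):
        ScenarioConfig.from_label("Z")


def test_meta_model_has_41_reactions_and_51_parameters():
    nw = build_network(ScenarioConfig.from_label("H"))
    assert len(nw.reactions) == 41
    assert len(nw.parameters) == 51
    for label in "ABCDEFG":
        sub = build_network(ScenarioConfig.from_label(label))
        # Ract contributes a rate-law fold, not reactions, so only scenarios
        # missing RA or AS shed reactions; every non-H scenario sheds parameters
        assert len(sub.reactions) <= 41
        if not (sub.scenario.RA and sub.scenario.AS):
            assert len(sub.reactions) < 41
        assert len(sub.parameters) < 51


def test_scenario_a_lacks_optional_mechanism_reactions():
    nw = build_network(ScenarioConfig.from_label("A"))
    rids = set(nw.reaction_ids())
    assert not any("ar" in r or "oap" in r.lower() for r in rids)
    assert "duplex" not in rids and "deg_ra" not in rids
    touched = {sp for rx in nw.reactions for sp in rx.stoich}
    assert {"ra", "AR", "OAp_free", "OAp_AR"}.isdisjoint(touched)


def test_c_and_e_differ_only_by_ar_reactions():
    c_ids = set(build_network(ScenarioConfig.from_label("C")).reaction_ids())
    e_ids = set(build_network(ScenarioConfig.from_label("E")).reaction_ids())
    assert c_ids < e_ids
    extra = e_ids - c_ids
    assert extra == {"ar_form", "ar_diss", "oap_bind", "oap_unbind", "deg_AR",
                     "rep_OAp_free", "rep_OAp_AR"}


@pytest.mark.parametrize("label", ["A", "C", "H"])
def test_initial_state_is_zero_except_operators(label):
    nw = build_network(ScenarioConfig.from_label(label))
    y0 = initial_state(nw)
    assert y0[IDX["OR_free"]] == 1.0 and y0[IDX["OA_free"]] == 1.0
    expect_oap = 1.0 if nw.scenario.RA else 0.0
    assert y0[IDX["OAp_free"]] == expect_oap
    others = [i for i, sp in enumerate(SPECIES)
              if sp not in ("OR_free", "OA_free", "OAp_free")]
    assert np.all(y0[others] == 0.0)
    # conservation at t=0: each operator's states sum to its copy number
    for op, states in _OPERATOR_GROUPS.items():
        total = sum(y0[IDX[s]] for s in states)
        assert total in (0.0, 1.0)


def test_operator_totals_change_only_by_replication(true_growth, rng):
    """Binding/unbinding moves operators between states; only DNA duplication
    changes the total, so summing S·v over an operator's rows must equal its
    replication flux for any state and parameters."""
    for params in random_parameter_sets(5, seed=42):
        f = compile_rhs(network_for("H"), params, true_growth)
        y = rng.uniform(0.0, 5.0, size=len(SPECIES))
        t = float(rng.uniform(0, 3600))
        v = f.rates(t, y)
        sv = f._s @ v
        rep = {rx.rid: v[j] for j, rx in enumerate(f.reactions)
               if rx.kind == "replication"}
        for op, states in _OPERATOR_GROUPS.items():
            rows = [IDX[s] for s in states]
            expected = sum(rep[f"rep_{s}"] for s in states)
            assert np.isclose(sv[rows].sum(), expected, rtol=1e-12, atol=1e-12)


def test_rhs_operator_sum_balances_in_stationary_phase(true_params, true_growth):
    """With growth exhausted (μ≈0) the total derivative of each operator
    group vanishes: replication balances dilution exactly."""
    y = initial_state(network_for("H"))
    y[IDX["R2"]] = 3.0
    dy = rhs(3600.0, y, true_params, true_growth, ScenarioConfig.from_label("H"))
    for op, states in _OPERATOR_GROUPS.items():
        rows = [IDX[s] for s in states]
        assert abs(dy[rows].sum()) < 1e-12


def test_rhs_validates_state(true_params, true_growth):
    sc = ScenarioConfig.from_label("A")
    y = initial_state(network_for("A"))
    y[0] = -1e-3
    with pytest.raises(ValueError, match="negative"):
        rhs(0.0, y, true_params, true_growth, sc)
    with pytest.raises(ValueError, match="components"):
        rhs(0.0, y[:5], true_params, true_growth, sc)


def test_structural_zeros_in_scenario_a(true_growth):
    for params in random_parameter_sets(3, seed=7):
        sim = simulate(params, "A", true_growth)
        if not sim.ok:
            continue
        for sp in ("ra", "AR", "OAp_free", "OAp_AR"):
            assert np.all(sim.species(sp) == 0.0)


def test_no_gbl_synthesis_keeps_signal_at_zero(true_params, true_growth):
    """k_C = 0 with C(0)=Ce(0)=0: no synthesis source, so the signalling
    branch stays identically zero and the repressor is never relieved."""
    sim = simulate(true_params.replace(k_C=0.0), "C", true_growth)
    assert sim.ok
    assert np.all(sim.species("C") == 0.0)
    assert np.all(sim.species("Ce") == 0.0)
    assert np.all(sim.species("C2R2") == 0.0)
    # and at the rhs level the derivative has no GBL component at all
    y = initial_state(network_for("C"))
    dy = rhs(100.0, y, true_params.replace(k_C=0.0), true_growth,
             ScenarioConfig.from_label("C"))
    assert dy[IDX["C"]] == 0.0 and dy[IDX["Ce"]] == 0.0


def test_scenario_nesting_is_exact(true_growth):
    """Disabling a mechanism's rate reproduces the reduced scenario exactly:
    A == C with duplex formation off; A == D with a neutral activation fold;
    A == B with AR formation off (up to the structural O_A' copy)."""
    for params in random_parameter_sets(3, seed=99):
        base = {}
        for label, kw in [("C", {"k_ds": 0.0}), ("D", {"f_Ract": 1.0}),
                          ("B", {"k_ARf": 0.0})]:
            p = params.replace(**kw)
            sim_a = simulate(p, "A", true_growth)
            sim_x = simulate(p, label, true_growth)
            assert sim_a.status == sim_x.status
            if not sim_a.ok:
                continue
            mask = np.ones(len(SPECIES), dtype=bool)
            if label == "B":  # O_A' operator exists only in RA scenarios
                mask[IDX["OAp_free"]] = False
            assert np.max(np.abs(sim_a.y[mask] - sim_x.y[mask])) == 0.0


def test_reduced_repressor_network_matches_closed_form(true_growth, rng):
    """On the sub-network r/R/R2/O_R (everything else zero and sourceless),
    the compiled rhs must agree with an independently hand-written
    mass-action derivative."""
    from gblnet.parameters import nm_per_molecule

    for params in random_parameter_sets(4, seed=5):
        p = params.replace(k_FA=0.0, k_trA=0.0, k_C=0.0, k_diff=0.0,
                           k_on1_A=0.0, k_on2_A=0.0, k_CR=0.0)
        y = np.zeros(len(SPECIES))
        y[IDX["r"]] = rng.uniform(0, 10)
        y[IDX["R"]] = rng.uniform(0, 50)
        y[IDX["R2"]] = rng.uniform(0, 20)
        y[IDX["OR_free"]] = 0.3
        y[IDX["OR_1"]] = 0.5
        y[IDX["OR_2"]] = 0.2
        t = float(rng.uniform(0, 3600))
        dy = rhs(t, y, p, true_growth, ScenarioConfig.from_label("A"))

        # ---- independent closed form ------------------------------------
        r_, R_, R2_ = y[IDX["r"]], y[IDX["R"]], y[IDX["R2"]]
        orf, or1, or2 = y[IDX["OR_free"]], y[IDX["OR_1"]], y[IDX["OR_2"]]
        _, mu = population(t, true_growth)
        fconv = nm_per_molecule(p["V_cell"])
        occ = orf + p["rho1_R"] * or1 + p["rho2_R"] * or2
        tx = p["k_FR"] * occ  # opposing promoter dead => no interference loss
        kd1 = p["k_on1_R"] * p["K_d1"] / fconv
        kd7 = p["k_on2_R"] * p["K_d7"] / fconv
        bind1 = p["k_on1_R"] * R2_ * orf
        unb1 = kd1 * or1
        bind2 = p["k_on2_R"] * R2_ * or1
        unb2 = kd7 * or2
        exp_dr = tx - p["d_r"] * r_ - mu * r_
        exp_dR = p["k_trR"] * r_ - 2 * p["k_dim"] * R_ ** 2 \
            + 2 * p["k_undim"] * R2_ - p["d_R"] * R_ - mu * R_
        exp_dR2 = p["k_dim"] * R_ ** 2 - p["k_undim"] * R2_ \
            - bind1 + unb1 - bind2 + unb2 - p["d_R2"] * R2_ - mu * R2_
        exp_dorf = -bind1 + unb1 + mu * orf - mu * orf
        exp_dor1 = bind1 - unb1 - bind2 + unb2 + mu * or1 - mu * or1
        exp_dor2 = bind2 - unb2 + mu * or2 - mu * or2

        for sp, expected in [("r", exp_dr), ("R", exp_dR), ("R2", exp_dR2),
                             ("OR_free", exp_dorf), ("OR_1", exp_dor1),
                             ("OR_2", exp_dor2)]:
            got = dy[IDX[sp]]
            assert got == pytest.approx(expected, rel=1e-10, abs=1e-12), sp


def test_network_json_dump_roundtrips():
    import json

    nw = build_network(ScenarioConfig.from_label("H"))
    doc = json.loads(nw.to_json())
    assert doc["scenario"] == "H"
    assert len(doc["reactions"]) == 41
    assert len(doc["parameters"]) == 51
    assert {s["id"] for s in doc["species"]} == set(SPECIES)
    assert all(s["compartment"] in ("cell", "environment") for s in doc["species"])
    # every rate-law parameter reference resolves
    for rx in doc["reactions"]:
        assert set(rx["parameters"]) <= set(doc["parameters"])


def test_parameter_set_invariants():
    from gblnet.parameters import ParameterSet

    base = {p: 0.5 for p in SAMPLED_PARAMETERS}
    ps = ParameterSet(dict(base))
    assert ps["chi"] == ps["k_FR"] / ps["k_FA"]
    assert ps["d_Ce"] == ps["d_C"]
    with pytest.raises(ValueError, match="missing"):
        ParameterSet({"k_FR": 1.0})
    bad = dict(base)
    bad["K_d1"] = -1.0
    with pytest.raises(ValueError, match="non-negative"):
        ParameterSet(bad)
    # repression factors are clamped to a physical ordering
    skew = dict(base)
    skew["rho1_R"], skew["rho2_R"] = 0.2, 0.8
    ps2 = ParameterSet(skew)
    assert ps2["rho2_R"] <= ps2["rho1_R"] <= 1.0
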