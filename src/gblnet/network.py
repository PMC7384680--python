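"""Reaction catalogue and ODE compilation for the scbR/scbA meta-model.

The meta-model (scenario H) describes the γ-butyrolactone circuit in two
compartments (cell, environment) with 41 reactions over 18 species and 51
parameters.  Four mechanisms can be toggled:

* **TI** — transcriptional interference of the convergent overlapping
  promoters (always on; it follows from the gene topology),
* **AS** — antisense pairing of the full-length *scbR*/*scbA* transcripts
  into a fast-degrading duplex,
* **RA** — formation of a ScbA–ScbR (AR) complex that sequesters the
  repressor and activates *scbA* via a hypothetical O_A' operator,
* **Ract** — ScbR acting as an activator of *scbA* while repressing itself.

Scenarios A–H are the eight combinations (A = TI only … H = all four).
Removing a mechanism removes its reactions, so its species lose every
production route and remain structurally zero.

Kinetics are elementary mass action; transcription uses the
occupancy-and-interference rate law of :mod:`gblnet.promoters`.  Cell growth
couples in three ways: intracellular species are diluted at the instantaneous
specific growth rate μ(t), operator copies are replicated at μ(t) (DNA
duplication keeps one copy per cell, exactly balancing dilution), and the
diffusion flux of GBL into the finite medium scales with the number of cells.
Intracellular amounts are molecules/cell (operators: copies/cell);
extracellular GBL is a concentration in nM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .growth import GrowthParams, population
from .parameters import ParameterSet, nm_per_molecule
from .promoters import effective_rates

__all__ = [
    "SPECIES",
    "CELL_SPECIES",
    "ScenarioConfig",
    "Reaction",
    "ReactionNetwork",
    "build_network",
    "initial_state",
    "compile_rhs",
    "rhs",
]

#: State-vector species, in canonical order.
SPECIES: tuple[str, ...] = (
    "r",        # scbR mRNA [molecules/cell]
    "a",        # scbA mRNA [molecules/cell]
    "ra",       # sense–antisense duplex [molecules/cell]
    "R",        # ScbR monomer [molecules/cell]
    "R2",       # ScbR homodimer [molecules/cell]
    "A",        # ScbA protein [molecules/cell]
    "C",        # intracellular GBL [molecules/cell]
    "Ce",       # extracellular GBL [nM]
    "C2R2",     # SCB-bound ScbR dimer [molecules/cell]
    "AR",       # ScbA–ScbR complex [molecules/cell]
    "OR_free", "OR_1", "OR_2",      # scbR operator states [copies/cell]
    "OA_free", "OA_1", "OA_2",      # scbA operator states [copies/cell]
    "OAp_free", "OAp_AR",           # hypothetical O_A' operator states
)

IDX: dict[str, int] = {s: i for i, s in enumerate(SPECIES)}

#: Species in the cell compartment (everything except extracellular GBL).
CELL_SPECIES: tuple[str, ...] = tuple(s for s in SPECIES if s != "Ce")

_OPERATOR_GROUPS: dict[str, tuple[str, ...]] = {
    "OR": ("OR_free", "OR_1", "OR_2"),
    "OA": ("OA_free", "OA_1", "OA_2"),
    "OAp": ("OAp_free", "OAp_AR"),
}

_LABELS: dict[str, tuple[bool, bool, bool]] = {
    # label: (RA, AS, Ract); TI is always on
    "A": (False, False, False),
    "B": (True, False, False),
    "C": (False, True, False),
    "D": (False, False, True),
    "E": (True, True, False),
    "F": (True, False, True),
    "G": (False, True, True),
    "H": (True, True, True),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Mechanism flags selecting one of the scenarios A–H (TI is mandatory)."""

    RA: bool = False
    AS: bool = False
    Ract: bool = False
    TI: bool = True

    def __post_init__(self) -> None:
        if not self.TI:
            raise ValueError(
                "transcriptional interference cannot be disabled: the scbR/scbA "
                "promoters overlap by 53 bp, so TI is present in every scenario")

    @property
    def label(self) -> str:
        for lab, flags in _LABELS.items():
            if flags == (self.RA, self.AS, self.Ract):
                return lab
        raise AssertionError("unreachable")

    @classmethod
    def from_label(cls, label: str) -> "ScenarioConfig":
        try:
            ra, as_, ract = _LABELS[label.upper()]
        except KeyError:
            raise ValueError(f"unknown scenario label {label!r}; expected A-H") from None
        return cls(RA=ra, AS=as_, Ract=ract)


@dataclass(frozen=True)
class Reaction:
    """One reaction: net stoichiometry, mass-action orders and rate constant.

    ``kind`` is ``"mass_action"`` for elementary steps (rate =
    ``rate_const(params) · ∏ y^order``) or one of the special rate laws
    ``"transcription_r"``, ``"transcription_a"`` (promoter model),
    ``"diffusion_out"``, ``"diffusion_in"`` (membrane transport) and
    ``"replication"`` (DNA duplication at μ(t)).  ``mechanism`` tags the
    reaction with the scenario flag that switches it (``"core"`` = always).
    """

    rid: str
    stoich: Mapping[str, int]
    orders: Mapping[str, int]
    params: tuple[str, ...]
    kind: str = "mass_action"
    mechanism: str = "core"
    rate_const: Callable[[Mapping[str, float]], float] | None = None


def _k(pid: str) -> Callable[[Mapping[str, float]], float]:
    return lambda p: p[pid]


def _koff(on: str, kd: str) -> Callable[[Mapping[str, float]], float]:
    # dissociation constant given in nM; convert to molecules/cell
    return lambda p: p[on] * p[kd] / nm_per_molecule(p["V_cell"])


def _catalogue() -> list[Reaction]:
    """The full (scenario H) reaction list: 41 reactions."""
    rx: list[Reaction] = []
    add = rx.append

    # transcription (lumped promoter rate law with interference)
    add(Reaction("tx_r", {"r": +1}, {}, (
        "k_FR", "k_FA", "chi", "rho1_R", "rho2_R", "rho1_A", "rho2_A",
        "aspect", "elong", "L_overlap", "L_r", "L_a"),
        kind="transcription_r"))
    add(Reaction("tx_a", {"a": +1}, {}, (
        "k_FR", "k_FA", "chi", "rho1_R", "rho2_R", "rho1_A", "rho2_A",
        "aspect", "elong", "L_overlap", "L_r", "L_a", "f_RA", "f_Ract"),
        kind="transcription_a"))
    # translation (mRNA is catalytic)
    add(Reaction("tl_R", {"R": +1}, {"r": 1}, ("k_trR",), rate_const=_k("k_trR")))
    add(Reaction("tl_A", {"A": +1}, {"a": 1}, ("k_trA",), rate_const=_k("k_trA")))
    # ScbR dimerisation
    add(Reaction("dim", {"R": -2, "R2": +1}, {"R": 2}, ("k_dim",), rate_const=_k("k_dim")))
    add(Reaction("undim", {"R2": -1, "R": +2}, {"R2": 1}, ("k_undim",), rate_const=_k("k_undim")))
    # sequential ScbR-dimer binding to the two operators
    for op, on1, kd1, on2, kd2 in (
            ("OR", "k_on1_R", "K_d1", "k_on2_R", "K_d7"),
            ("OA", "k_on1_A", "K_d2", "k_on2_A", "K_d8")):
        free, one, two = _OPERATOR_GROUPS[op]
        add(Reaction(f"bind_{op}_1", {"R2": -1, free: -1, one: +1},
                     {"R2": 1, free: 1}, (on1,), rate_const=_k(on1)))
        add(Reaction(f"unbind_{op}_1", {one: -1, "R2": +1, free: +1},
                     {one: 1}, (on1, kd1, "V_cell"), rate_const=_koff(on1, kd1)))
        add(Reaction(f"bind_{op}_2", {"R2": -1, one: -1, two: +1},
                     {"R2": 1, one: 1}, (on2,), rate_const=_k(on2)))
        add(Reaction(f"unbind_{op}_2", {two: -1, "R2": +1, one: +1},
                     {two: 1}, (on2, kd2, "V_cell"), rate_const=_koff(on2, kd2)))
    # GBL synthesis (ScbA catalytic; precursor supply absorbed into k_C)
    add(Reaction("gbl_syn", {"C": +1}, {"A": 1}, ("k_C",), rate_const=_k("k_C")))
    # SCB deactivation of the repressor: 2 C + R2 <-> C2R2
    add(Reaction("cr_bind", {"C": -2, "R2": -1, "C2R2": +1}, {"C": 2, "R2": 1},
                 ("k_CR",), rate_const=_k("k_CR")))
    add(Reaction("cr_unbind", {"C2R2": -1, "C": +2, "R2": +1}, {"C2R2": 1},
                 ("k_CRr",), rate_const=_k("k_CRr")))
    # passive membrane diffusion of GBL (flux into the medium scales with N(t))
    add(Reaction("diff_out", {"C": -1, "Ce": +1}, {"C": 1},
                 ("k_diff", "V_cell", "V_env"), kind="diffusion_out"))
    add(Reaction("diff_in", {"Ce": -1, "C": +1}, {"Ce": 1},
                 ("k_diff", "V_cell", "V_env"), kind="diffusion_in"))
    # first-order degradation (internal and external GBL share one rate)
    for sp, d in (("r", "d_r"), ("a", "d_a"), ("R", "d_R"), ("R2", "d_R2"),
                  ("A", "d_A"), ("C", "d_C"), ("Ce", "d_Ce")):
        add(Reaction(f"deg_{sp}", {sp: -1}, {sp: 1}, (d,), rate_const=_k(d)))
    # antisense duplex formation and its fast degradation
    add(Reaction("duplex", {"r": -1, "a": -1, "ra": +1}, {"r": 1, "a": 1},
                 ("k_ds",), mechanism="AS", rate_const=_k("k_ds")))
    add(Reaction("deg_ra", {"ra": -1}, {"ra": 1}, ("d_ra",), mechanism="AS",
                 rate_const=_k("d_ra")))
    # AR complex: sequesters R2 and activates scbA via O_A'
    add(Reaction("ar_form", {"A": -1, "R2": -1, "AR": +1}, {"A": 1, "R2": 1},
                 ("k_ARf",), mechanism="RA", rate_const=_k("k_ARf")))
    add(Reaction("ar_diss", {"AR": -1, "A": +1, "R2": +1}, {"AR": 1},
                 ("k_ARr",), mechanism="RA", rate_const=_k("k_ARr")))
    add(Reaction("oap_bind", {"AR": -1, "OAp_free": -1, "OAp_AR": +1},
                 {"AR": 1, "OAp_free": 1}, ("k_OApf",), mechanism="RA",
                 rate_const=_k("k_OApf")))
    add(Reaction("oap_unbind", {"OAp_AR": -1, "AR": +1, "OAp_free": +1},
                 {"OAp_AR": 1}, ("k_OApr",), mechanism="RA", rate_const=_k("k_OApr")))
    add(Reaction("deg_AR", {"AR": -1}, {"AR": 1}, ("d_AR",), mechanism="RA",
                 rate_const=_k("d_AR")))
    # DNA duplication: each operator state replicates at μ(t), balancing dilution
    for op, states in _OPERATOR_GROUPS.items():
        mech = "RA" if op == "OAp" else "core"
        for st in states:
            add(Reaction(f"rep_{st}", {st: +1}, {st: 1}, (), kind="replication",
                         mechanism=mech))
    return rx


def _stoich_matrix(reactions) -> np.ndarray:
    s = np.zeros((len(SPECIES), len(reactions)))
    for j, rx in enumerate(reactions):
        for sp, n in rx.stoich.items():
            s[IDX[sp], j] = n
    return s


def _prune_inert(reactions, y0: np.ndarray, p: Mapping[str, float]):
    """Drop reactions that can never fire from the canonical initial state.

    A reaction is inert if its rate constant is exactly zero (the switch-off
    limit of a mechanism) or if one of its rate-determining species can never
    become positive (no remaining production route and zero initially).
    Valid only for trajectories started from :func:`initial_state`; the
    general :func:`rhs` entry point compiles without pruning.  Pruning makes
    nested scenarios (e.g. the antisense scenario with duplex formation rate
    zero) compile to bit-identical right-hand sides.
    """
    active = list(reactions)
    while True:
        producible = {sp for sp in SPECIES if y0[IDX[sp]] > 0}
        changed = True
        while changed:
            changed = False
            for rx in active:
                if rx.kind == "mass_action" and rx.rate_const(p) == 0.0:
                    continue
                if all(sp in producible for sp in rx.orders):
                    new = {sp for sp, n in rx.stoich.items()
                           if n > 0 and sp not in producible}
                    if new:
                        producible |= new
                        changed = True
        kept = [rx for rx in active
                if not (rx.kind == "mass_action" and rx.rate_const(p) == 0.0)
                and all(sp in producible for sp in rx.orders)]
        if len(kept) == len(active):
            return tuple(kept)
        active = kept


@dataclass(frozen=True)
class ReactionNetwork:
    """Scenario-specific reaction network, compilable to an ODE right-hand side."""

    scenario: ScenarioConfig
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    parameters: tuple[str, ...]
    compartments: dict[str, str] = field(default_factory=dict)

    def stoichiometry_matrix(self) -> np.ndarray:
        """Net stoichiometry S (species × reactions)."""
        return _stoich_matrix(self.reactions)

    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(rx.rid for rx in self.reactions)

    def operator_totals(self) -> dict[str, float]:
        """Total copies per cell of each operator present in this scenario."""
        totals = {"OR": 1.0, "OA": 1.0}
        if self.scenario.RA:
            totals["OAp"] = 1.0
        return totals

    def to_json(self, **kwargs) -> str:
        """Introspection dump: species, compartments, reactions, parameters."""
        doc = {
            "scenario": self.scenario.label,
            "mechanisms": {"TI": True, "RA": self.scenario.RA,
                           "AS": self.scenario.AS, "Ract": self.scenario.Ract},
            "species": [
                {"id": sp, "compartment": self.compartments[sp]}
                for sp in self.species],
            "reactions": [
                {"id": rx.rid, "kind": rx.kind, "mechanism": rx.mechanism,
                 "stoichiometry": dict(rx.stoich), "rate_orders": dict(rx.orders),
                 "parameters": list(rx.params)}
                for rx in self.reactions],
            "parameters": list(self.parameters),
        }
        kwargs.setdefault("indent", 2)
        return json.dumps(doc, **kwargs)


def build_network(scenario: ScenarioConfig) -> ReactionNetwork:
    """Assemble the reaction network for one scenario.

    Reactions tagged with a disabled mechanism are removed, which removes the
    production routes of that mechanism's species (duplex, AR, O_A' states),
    so they stay at zero for all time.  Scenario H retains the full
    catalogue: 41 reactions, 51 parameters.
    """
    if not isinstance(scenario, ScenarioConfig):
        scenario = ScenarioConfig.from_label(str(scenario))
    enabled = {"core", "TI"}
    if scenario.RA:
        enabled.add("RA")
    if scenario.AS:
        enabled.add("AS")
    reactions = tuple(rx for rx in _catalogue() if rx.mechanism in enabled)

    params: list[str] = []

    def _use(pid: str) -> None:
        if pid not in params:
            params.append(pid)

    for rx in reactions:
        for pid in rx.params:
            if pid == "f_RA" and not scenario.RA:
                continue
            if pid == "f_Ract" and not scenario.Ract:
                continue
            _use(pid)
    if scenario.Ract:
        _use("f_Ract")  # rate-law fold; carries no reaction of its own
    for pid in ("V_cell", "V_env", "n_OR", "n_OA"):
        _use(pid)
    if scenario.RA:
        _use("n_OAp")
    _use("d_Ce")
    for pid in ("s_r", "s_a"):
        _use(pid)
    compartments = {sp: ("environment" if sp == "Ce" else "cell") for sp in SPECIES}
    return ReactionNetwork(scenario=scenario, species=SPECIES,
                           reactions=reactions, parameters=tuple(params),
                           compartments=compartments)


def initial_state(network: ReactionNetwork) -> np.ndarray:
    """Initial condition: everything zero except one copy of each operator.

    Only operators whose mechanism is part of the scenario get their copy
    (O_A' exists only when the AR mechanism is modelled).
    """
    y0 = np.zeros(len(SPECIES))
    y0[IDX["OR_free"]] = 1.0
    y0[IDX["OA_free"]] = 1.0
    if network.scenario.RA:
        y0[IDX["OAp_free"]] = 1.0
    return y0


class CompiledRHS:
    """Mass-action right-hand side compiled from a reaction network.

    Callable as ``f(t, y)``; ``rates(t, y)`` exposes the per-reaction fluxes
    and ``dilution(t, y)`` the growth-dilution term, so conservation
    properties can be checked against the stoichiometry matrix directly.
    The solver-facing entry point ``odeint_rhs(y, t)`` clips negative
    excursions instead of raising.
    """

    def __init__(self, network: ReactionNetwork, params: ParameterSet,
                 gp: GrowthParams, prune: bool = False):
        missing = [pid for pid in network.parameters if pid not in params]
        if missing:
            raise ValueError(f"parameter set missing entries: {missing}")
        self.network = network
        self.params = params
        self.gp = gp
        self._p = {pid: float(params[pid]) for pid in params}
        self._fconv = nm_per_molecule(params["V_cell"])
        reactions = network.reactions
        if prune:
            reactions = _prune_inert(reactions, initial_state(network), self._p)
        self.reactions = reactions
        self._s = _stoich_matrix(reactions)
        # mass-action reactions -> constant vector + up to 3 species factors
        ma_cols, ks, fac = [], [], []
        self._special: list[tuple[int, str, int | None]] = []
        one = len(SPECIES)  # index of the constant-1 slot in the extended state
        for j, rx in enumerate(reactions):
            if rx.kind == "mass_action":
                idxs = []
                for sp, order in rx.orders.items():
                    idxs.extend([IDX[sp]] * order)
                if len(idxs) > 3:
                    raise ValueError(f"reaction {rx.rid}: order > 3 not supported")
                idxs += [one] * (3 - len(idxs))
                ma_cols.append(j)
                ks.append(rx.rate_const(self._p))
                fac.append(idxs)
            elif rx.kind == "replication":
                st = next(iter(rx.stoich))
                self._special.append((j, "replication", IDX[st]))
            else:
                self._special.append((j, rx.kind, None))
        self._ma_cols = np.array(ma_cols, dtype=int)
        self._ma_k = np.array(ks)
        f = np.array(fac, dtype=int).reshape(len(ma_cols), 3)
        self._fa, self._fb, self._fc = f[:, 0], f[:, 1], f[:, 2]
        self._cell_idx = np.array([IDX[s] for s in CELL_SPECIES], dtype=int)
        self._i_C, self._i_Ce = IDX["C"], IDX["Ce"]
        self._or_idx = [IDX[s] for s in _OPERATOR_GROUPS["OR"]]
        self._oa_idx = [IDX[s] for s in _OPERATOR_GROUPS["OA"]]
        self._i_oap_ar, self._i_oap_free = IDX["OAp_AR"], IDX["OAp_free"]
        # pre-neutralise activation folds of disabled mechanisms
        ptx = dict(self._p)
        if not network.scenario.RA:
            ptx["f_RA"] = 1.0
        if not network.scenario.Ract:
            ptx["f_Ract"] = 1.0
        self._ptx = ptx
        self._yext = np.ones(len(SPECIES) + 1)

    # -- rate vector ----------------------------------------------------
    def rates(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self._ptx
        yext = self._yext
        yext[:-1] = y
        v = np.zeros(len(self.reactions))
        v[self._ma_cols] = self._ma_k * yext[self._fa] * yext[self._fb] * yext[self._fc]
        _, mu = population(float(t), self.gp)
        or_states = y[self._or_idx]
        oa_states = y[self._oa_idx]
        n_oap = y[self._i_oap_ar] + y[self._i_oap_free]
        oap_frac = y[self._i_oap_ar] / n_oap if n_oap > 0 else 0.0
        rate_r, rate_a = effective_rates(or_states, oa_states, oap_frac, p)
        for j, kind, arg in self._special:
            if kind == "transcription_r":
                v[j] = rate_r * or_states.sum()
            elif kind == "transcription_a":
                v[j] = rate_a * oa_states.sum()
            elif kind == "diffusion_out":
                v[j] = p["k_diff"] * y[self._i_C]
            elif kind == "diffusion_in":
                v[j] = p["k_diff"] * y[self._i_Ce] / self._fconv
            elif kind == "replication":
                v[j] = mu * y[arg]
        return v

    def dilution(self, t: float, y: np.ndarray) -> np.ndarray:
        _, mu = population(float(t), self.gp)
        d = np.zeros_like(y)
        d[self._cell_idx] = -mu * y[self._cell_idx]
        return d

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        v = self.rates(t, y)
        dy = self._s @ v
        n, mu = population(float(t), self.gp)
        dy[self._cell_idx] -= mu * y[self._cell_idx]
        # per-cell diffusion flux expressed in medium concentration units:
        # dCe/dt gains (flux out - flux in) · (nM per molecule) · N·V_cell/V_env
        net_out = self._p["k_diff"] * (y[self._i_C] - y[self._i_Ce] / self._fconv)
        pop_scale = self._fconv * n * self._p["V_cell"] / self._p["V_env"]
        dy[self._i_Ce] += net_out * (pop_scale - 1.0)  # S already carries ±1
        return dy

    def odeint_rhs(self, y: np.ndarray, t: float) -> np.ndarray:
        return self(t, np.maximum(y, 0.0))


def compile_rhs(network: ReactionNetwork, params: ParameterSet,
                gp: GrowthParams, prune: bool = False) -> CompiledRHS:
    """Compile a network to a fast ODE right-hand side ``f(t, y)``."""
    return CompiledRHS(network, params, gp, prune=prune)


_NETWORK_CACHE: dict[str, ReactionNetwork] = {}


def network_for(scenario: ScenarioConfig | str) -> ReactionNetwork:
    """Cached :func:`build_network` (networks are immutable per scenario)."""
    if not isinstance(scenario, ScenarioConfig):
        scenario = ScenarioConfig.from_label(str(scenario))
    return _NETWORK_CACHE.setdefault(scenario.label, build_network(scenario))


def rhs(t: float, state, params: ParameterSet, gp: GrowthParams,
        scenario: ScenarioConfig) -> np.ndarray:
    """Time derivative of the full state vector for one scenario.

    Validates non-negativity of the state (a negative component signals a
    solver excursion and is rejected here; the integrator wrapper clips
    instead).  For repeated evaluation compile once with :func:`compile_rhs`.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (len(SPECIES),):
        raise ValueError(f"state must have {len(SPECIES)} components")
    if np.any(state < 0):
        raise ValueError("negative state component: solver excursion")
    return compile_rhs(network_for(scenario), params, gp)(t, state)
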