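"""Kinetic parameter sets for the GBL circuit meta-model.

The full meta-model (scenario H) carries 51 parameters.  44 of them are
uncertain kinetic/transport/degradation quantities sampled from log-normal
priors; five are fixed structural constants (compartment volumes and operator
copy numbers); two are derived on construction:

* ``chi`` — the promoter heterogeneity factor, defined as the ratio of the
  *scbR* to *scbA* promoter firing rates, ``chi = k_FR / k_FA``;
* ``d_Ce`` — the extracellular GBL degradation rate, tied to the
  intracellular rate ``d_C`` (internal and external signal molecules are
  assumed to degrade at the same rate).

Units: first-order rates in 1/min, bimolecular rates in 1/(molecule·min),
dissociation constants in nM, volumes in litres, lengths in bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

AVOGADRO = 6.02214076e23

#: The 44 kinetic parameters sampled from priors, in canonical order.
SAMPLED_PARAMETERS: tuple[str, ...] = (
    "k_FR",      # scbR promoter firing rate [1/min]
    "k_FA",      # scbA promoter firing rate [1/min]
    "rho1_R",    # residual O_R activity with one ScbR dimer bound [-]
    "rho2_R",    # residual O_R activity with two dimers bound [-]
    "rho1_A",    # residual O_A activity with one dimer bound [-]
    "rho2_A",    # residual O_A activity with two dimers bound [-]
    "aspect",    # promoter aspect-ratio factor scaling the collision window [-]
    "elong",     # RNAP elongation rate [bp/min]
    "L_overlap", # convergent promoter overlap [bp]
    "L_r",       # scbR transcript length [bp]
    "L_a",       # scbA transcript length [bp]
    "k_on1_R",   # first ScbR dimer binding to O_R [1/(molecule·min)]
    "K_d1",      # dissociation constant, first dimer on O_R [nM]
    "k_on2_R",   # second dimer binding to occupied O_R [1/(molecule·min)]
    "K_d7",      # dissociation constant, second dimer on O_R [nM]
    "k_on1_A",   # first ScbR dimer binding to O_A [1/(molecule·min)]
    "K_d2",      # dissociation constant, first dimer on O_A [nM]
    "k_on2_A",   # second dimer binding to occupied O_A [1/(molecule·min)]
    "K_d8",      # dissociation constant, second dimer on O_A [nM]
    "k_trR",     # translation rate of r [1/min]
    "k_trA",     # translation rate of a [1/min]
    "k_dim",     # ScbR dimerisation [1/(molecule·min)]
    "k_undim",   # ScbR dimer dissociation [1/min]
    "k_C",       # GBL synthesis rate per ScbA [1/min]
    "k_CR",      # C2R2 complex association [1/(molecule^2·min)]
    "k_CRr",     # C2R2 complex dissociation [1/min]
    "k_diff",    # membrane diffusion rate of C [1/min]
    "k_ds",      # sense–antisense duplex formation [1/(molecule·min)]
    "d_ra",      # duplex degradation rate [1/min]
    "k_ARf",     # ScbA–ScbR (AR) complex formation [1/(molecule·min)]
    "k_ARr",     # AR complex dissociation [1/min]
    "k_OApf",    # AR binding to the hypothetical O_A' operator [1/(molecule·min)]
    "k_OApr",    # AR unbinding from O_A' [1/min]
    "f_RA",      # scbA activation fold when O_A' is AR-bound [-]
    "f_Ract",    # scbA activation fold from R2-occupied O_R (R_act) [-]
    "d_r",       # scbR mRNA degradation [1/min]
    "d_a",       # scbA mRNA degradation [1/min]
    "d_R",       # ScbR monomer degradation [1/min]
    "d_R2",      # ScbR dimer degradation [1/min]
    "d_A",       # ScbA protein degradation [1/min]
    "d_C",       # intracellular GBL degradation [1/min]
    "d_AR",      # AR complex degradation [1/min]
    "s_r",       # observation scale factor, r -> target units [-]
    "s_a",       # observation scale factor, a -> target units [-]
)

#: Fixed structural constants (not sampled, not K–S tested).
FIXED_PARAMETERS: dict[str, float] = {
    "V_cell": 1e-15,  # cell volume [L]
    "V_env": 0.05,    # culture medium volume [L]
    "n_OR": 1.0,      # scbR operator copies per cell
    "n_OA": 1.0,      # scbA operator copies per cell
    "n_OAp": 1.0,     # hypothetical O_A' operator copies per cell
}

#: Derived parameters, computed on construction.
DERIVED_PARAMETERS: tuple[str, ...] = ("chi", "d_Ce")

ALL_PARAMETERS: tuple[str, ...] = (
    SAMPLED_PARAMETERS + tuple(FIXED_PARAMETERS) + DERIVED_PARAMETERS
)


def nm_per_molecule(v_cell: float) -> float:
    """Concentration (nM) of a single molecule in a cell of volume ``v_cell`` litres."""
    return 1.0 / (v_cell * AVOGADRO * 1e-9)


@dataclass(frozen=True)
class ParameterSet(Mapping[str, float]):
    """One named vector of model parameters (one ensemble member's coordinates).

    Construction validates strict positivity, derives ``chi`` and ``d_Ce``,
    fills fixed structural constants, and clamps the promoter repression
    factors to the physical range (residual activity ≤ 1, double occupancy at
    most as active as single occupancy).
    """

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = dict(self.values)
        missing = [p for p in SAMPLED_PARAMETERS if p not in vals]
        if missing:
            raise ValueError(f"missing parameters: {missing}")
        for name, default in FIXED_PARAMETERS.items():
            vals.setdefault(name, default)
        # Prior draws are log-normal, hence strictly positive; exact zeros are
        # accepted only as the switch-off limit of a rate (used to verify that
        # scenarios nest into each other), never for structural quantities.
        for name, v in vals.items():
            if name in DERIVED_PARAMETERS:
                continue
            if not (v >= 0) or not math.isfinite(v):
                raise ValueError(f"parameter {name!r} must be non-negative and finite, got {v}")
        for name in ("V_cell", "V_env", "n_OR", "n_OA", "n_OAp"):
            if not vals[name] > 0:
                raise ValueError(f"structural parameter {name!r} must be strictly positive")
        # residual promoter activity is a fraction of the free-operator rate
        for gene in ("R", "A"):
            one, two = f"rho1_{gene}", f"rho2_{gene}"
            vals[one] = min(vals[one], 1.0)
            vals[two] = min(vals[two], vals[one])
        vals["chi"] = vals["k_FR"] / vals["k_FA"] if vals["k_FA"] > 0 else math.inf
        vals["d_Ce"] = vals["d_C"]
        object.__setattr__(self, "values", vals)

    # Mapping interface -------------------------------------------------
    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def replace(self, **updates: float) -> "ParameterSet":
        """Return a copy with the given entries replaced (derived entries recomputed)."""
        vals = {k: v for k, v in self.values.items() if k not in DERIVED_PARAMETERS}
        vals.update(updates)
        return ParameterSet(vals)

    @property
    def chi(self) -> float:
        return self.values["chi"]
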