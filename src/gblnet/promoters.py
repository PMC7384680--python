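"""Transcription initiation at the convergent, overlapping scbR/scbA promoters.

The two promoters overlap by ~53 bp and fire towards each other, so an RNA
polymerase elongating from one promoter can collide with (and abort)
initiation/elongation from the other — transcriptional interference (TI).
Each gene's full-length transcription rate is the product of

1. an occupancy-modulated firing rate: the promoter fires at its intrinsic
   rate ``k_F`` scaled by the residual activity of its current repression
   state (free, one ScbR dimer bound, two dimers bound), and for *scbA*
   optionally multiplied by activation folds from the AR–O_A' and R_act
   mechanisms; and
2. a collision-escape probability: polymerases initiating on gene *i* occupy
   the shared region for a window ``tau_i`` and are lost to collisions with
   opposing initiations (rate ``f_j``), giving ``escape_i = 1/(1 + tau_i·f_j)``.
   The window scales with the transcript length plus the promoter overlap
   divided by the elongation rate, times a dimensionless aspect-ratio factor.

The escape probability uses the *pre-interference* effective firing rate of
the opposing promoter, so the two rates are explicit functions of the
operator state (no fixed-point iteration); interference is mutual and each
rate is bounded by its interference-free value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PromoterState",
    "occlusion_window",
    "interference_escape",
    "transcription_rates",
    "effective_rates",
    "occupancy_fractions",
]


def occlusion_window(aspect: float, length: float, overlap: float, elong: float) -> float:
    """Time [min] a polymerase from the opposing gene occupies the shared region.

    ``aspect`` is the dimensionless promoter aspect-ratio factor, ``length``
    the transcript length of the *opposing* gene [bp], ``overlap`` the
    promoter overlap [bp] and ``elong`` the elongation rate [bp/min].
    """
    if elong <= 0:
        raise ValueError("elongation rate must be positive")
    return aspect * (length + overlap) / elong


def interference_escape(f_r: float, f_a: float, tau_r: float, tau_a: float):
    """Mutual collision-escape probabilities for the two convergent promoters.

    ``f_r``/``f_a`` are the occupancy-modulated (pre-interference) firing
    rates; ``tau_r`` is the occlusion window that *scbR* transcription suffers
    (set by the opposing *scbA* traffic) and vice versa.  With zero coupling
    both probabilities are exactly 1.
    """
    return 1.0 / (1.0 + tau_r * f_a), 1.0 / (1.0 + tau_a * f_r)


@dataclass(frozen=True)
class PromoterState:
    """Discrete promoter configuration used by the closed-form transcription rates.

    ``occ_r``/``occ_a`` count ScbR dimers bound to O_R/O_A (0, 1 or 2);
    repression factors are the residual activities of the occupied states.
    """

    occ_r: int
    occ_a: int
    k_fr: float                 # scbR firing rate [1/min]
    k_fa: float                 # scbA firing rate [1/min]
    rho1_r: float = 1.0
    rho2_r: float = 1.0
    rho1_a: float = 1.0
    rho2_a: float = 1.0
    tau_r: float = 0.0          # occlusion window on scbR [min]
    tau_a: float = 0.0          # occlusion window on scbA [min]
    act_a: float = 1.0          # activation fold on scbA (RA and/or R_act)

    def __post_init__(self) -> None:
        if self.occ_r not in (0, 1, 2) or self.occ_a not in (0, 1, 2):
            raise ValueError("occupancy class must be 0, 1 or 2 bound dimers")
        if not (self.k_fr > 0 and self.k_fa > 0):
            raise ValueError("promoter firing rates must be positive")
        for one, two in ((self.rho1_r, self.rho2_r), (self.rho1_a, self.rho2_a)):
            if not (0 <= two <= one <= 1):
                raise ValueError("repression factors must satisfy rho2 <= rho1 <= 1")

    @property
    def chi(self) -> float:
        return self.k_fr / self.k_fa


def _occupancy_factor(occ: int, rho1: float, rho2: float) -> float:
    return (1.0, rho1, rho2)[occ]


def transcription_rates(ps: PromoterState) -> tuple[float, float]:
    """Full-length transcription rates (rate_r, rate_a) [1/min] for one state."""
    f_r = ps.k_fr * _occupancy_factor(ps.occ_r, ps.rho1_r, ps.rho2_r)
    f_a = ps.k_fa * _occupancy_factor(ps.occ_a, ps.rho1_a, ps.rho2_a) * ps.act_a
    esc_r, esc_a = interference_escape(f_r, f_a, ps.tau_r, ps.tau_a)
    return f_r * esc_r, f_a * esc_a


def effective_rates(or_states, oa_states, oap_bound_frac, p) -> tuple[float, float]:
    """Population-averaged transcription rates from continuous operator states.

    ``or_states``/``oa_states`` are the (free, one-dimer, two-dimer) operator
    copy numbers from the ODE state; ``oap_bound_frac`` the AR-bound fraction
    of O_A' (0 disables the RA activation fold); ``p`` maps parameter ids to
    values and must carry the activation folds pre-neutralised (set to 1) for
    disabled mechanisms.  Used by the compiled ODE right-hand side.
    """
    n_or = or_states[0] + or_states[1] + or_states[2]
    n_oa = oa_states[0] + oa_states[1] + oa_states[2]
    occ_r = 0.0 if n_or <= 0 else (
        or_states[0] + p["rho1_R"] * or_states[1] + p["rho2_R"] * or_states[2]) / n_or
    occ_a = 0.0 if n_oa <= 0 else (
        oa_states[0] + p["rho1_A"] * oa_states[1] + p["rho2_A"] * oa_states[2]) / n_oa
    act = 1.0 + (p["f_RA"] - 1.0) * oap_bound_frac
    if n_or > 0:
        act *= 1.0 + (p["f_Ract"] - 1.0) * (or_states[1] + or_states[2]) / n_or
    f_r = p["k_FR"] * occ_r
    f_a = p["k_FA"] * occ_a * act
    if f_r == 0.0 and f_a == 0.0:
        return 0.0, 0.0  # silent promoters cannot collide
    tau_r = occlusion_window(p["aspect"], p["L_a"], p["L_overlap"], p["elong"])
    tau_a = occlusion_window(p["aspect"], p["L_r"], p["L_overlap"], p["elong"])
    esc_r, esc_a = interference_escape(f_r, f_a, tau_r, tau_a)
    return f_r * esc_r, f_a * esc_a


def occupancy_fractions(r2, kd_first, kd_second):
    """Equilibrium probabilities (p_free, p_one, p_two) of the operator states.

    Sequential two-site binding of the ScbR dimer at concentration ``r2`` with
    dissociation constants ``kd_first`` and ``kd_second`` (same units as
    ``r2``); the partition function is ``1 + r2/Kd1 + r2^2/(Kd1·Kd2)``.
    """
    r2 = np.asarray(r2, dtype=float)
    if np.any(r2 < 0):
        raise ValueError("repressor dimer concentration must be non-negative")
    if not (kd_first > 0 and kd_second > 0):
        raise ValueError("dissociation constants must be positive")
    w1 = r2 / kd_first
    w2 = w1 * r2 / kd_second
    z = 1.0 + w1 + w2
    out = (1.0 / z, w1 / z, w2 / z)
    if r2.ndim == 0:
        return tuple(float(x) for x in out)
    return out
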