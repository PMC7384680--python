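"""Log-normal parameter priors and reproducible ensemble sampling.

Each uncertain model parameter carries an independent log-normal prior,
elicited in the standard way for ensemble modelling of under-determined
biochemical networks: the most plausible literature value anchors the median
(``exp(location)``) and the plausible range is interpreted as the central 95%
interval, giving ``scale = ln(hi/lo) / (2·1.96)``.  Correlations between
parameters are not modelled.  An :class:`Ensemble` is a seeded matrix of
draws; the *same* ensemble is reused for every scenario so that pass counts
and likelihood profiles are comparable across mechanisms.

The default prior table below is a reconstructed, literature-plausible
elicitation spanning the ranges over which the enrichment analysis is
informative (e.g. ScbA degradation 10⁻³–10⁻¹ 1/min, GBL synthesis
10⁻³–10 1/min).  It is a package default, fully overridable from a
delimited-text prior table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .parameters import SAMPLED_PARAMETERS, ParameterSet

__all__ = [
    "PriorSpec",
    "Ensemble",
    "default_priors",
    "sample_ensemble",
    "constrain_ratio",
    "write_priors",
    "read_priors",
]


@dataclass(frozen=True)
class PriorSpec:
    """Log-normal prior for one parameter (location/scale on the log scale)."""

    param_id: str
    location: float     # ln(median)
    scale: float        # log-scale standard deviation, >= 0
    units: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("prior scale must be non-negative")
        if not math.isfinite(self.location):
            raise ValueError("prior location must be finite")

    @property
    def median(self) -> float:
        return math.exp(self.location)

    @classmethod
    def from_range(cls, param_id: str, median: float, lo95: float, hi95: float,
                   units: str = "", note: str = "") -> "PriorSpec":
        """Elicit from a most-plausible value and a central 95% range."""
        if not (0 < lo95 <= median <= hi95):
            raise ValueError(f"{param_id}: need 0 < lo95 <= median <= hi95")
        scale = math.log(hi95 / lo95) / (2.0 * 1.959963984540054)
        return cls(param_id, math.log(median), scale, units, note)

    def interval95(self) -> tuple[float, float]:
        h = 1.959963984540054 * self.scale
        return math.exp(self.location - h), math.exp(self.location + h)


def default_priors() -> dict[str, PriorSpec]:
    """Reconstructed default priors for the 44 sampled parameters."""
    r = PriorSpec.from_range
    specs = [
        r("k_FR", 0.2, 0.02, 2.0, "1/min", "scbR promoter firing rate"),
        r("k_FA", 0.1, 0.01, 1.0, "1/min", "scbA promoter firing rate"),
        r("rho1_R", 0.10, 0.01, 1.0, "-", "O_R residual activity, 1 dimer"),
        r("rho2_R", 0.01, 1e-3, 0.1, "-", "O_R residual activity, 2 dimers"),
        r("rho1_A", 0.10, 0.01, 1.0, "-", "O_A residual activity, 1 dimer"),
        r("rho2_A", 0.01, 1e-3, 0.1, "-", "O_A residual activity, 2 dimers"),
        r("aspect", 1.0, 0.1, 10.0, "-", "promoter aspect-ratio factor"),
        r("elong", 2400.0, 1200.0, 4800.0, "bp/min", "RNAP elongation rate"),
        PriorSpec("L_overlap", math.log(53.0), 0.0, "bp",
                  "promoter overlap, known exactly"),
        r("L_r", 700.0, 350.0, 1400.0, "bp", "scbR transcript length"),
        r("L_a", 1000.0, 500.0, 2000.0, "bp", "scbA transcript length"),
        r("k_on1_R", 0.01, 1e-3, 0.1, "1/(molecule·min)", "R2 + O_R on-rate"),
        r("K_d1", 10.0, 1.0, 100.0, "nM", "R2 on free O_R"),
        r("k_on2_R", 0.01, 1e-3, 0.1, "1/(molecule·min)", "R2 + R2:O_R on-rate"),
        r("K_d7", 50.0, 5.0, 500.0, "nM", "second R2 on O_R"),
        r("k_on1_A", 0.01, 1e-3, 0.1, "1/(molecule·min)", "R2 + O_A on-rate"),
        r("K_d2", 5.0, 0.5, 50.0, "nM", "R2 on free O_A"),
        r("k_on2_A", 0.01, 1e-3, 0.1, "1/(molecule·min)", "R2 + R2:O_A on-rate"),
        r("K_d8", 25.0, 2.5, 250.0, "nM", "second R2 on O_A"),
        r("k_trR", 0.3, 0.03, 3.0, "1/min", "translation of r"),
        r("k_trA", 0.3, 0.03, 3.0, "1/min", "translation of a"),
        r("k_dim", 0.01, 1e-3, 0.1, "1/(molecule·min)", "ScbR dimerisation"),
        r("k_undim", 0.01, 1e-3, 0.1, "1/min", "dimer dissociation"),
        r("k_C", 0.1, 1e-3, 10.0, "1/min", "GBL synthesis per ScbA"),
        r("k_CR", 1e-4, 1e-5, 1e-3, "1/(molecule^2·min)", "2C + R2 association"),
        r("k_CRr", 0.01, 1e-3, 0.1, "1/min", "C2R2 dissociation"),
        r("k_diff", 0.1, 0.01, 1.0, "1/min", "GBL membrane diffusion"),
        r("k_ds", 0.01, 1e-3, 0.1, "1/(molecule·min)", "antisense duplex formation"),
        r("d_ra", 0.5, 0.05, 5.0, "1/min", "duplex degradation (fast)"),
        r("k_ARf", 1e-3, 1e-4, 1e-2, "1/(molecule·min)", "AR complex formation"),
        r("k_ARr", 0.01, 1e-3, 0.1, "1/min", "AR dissociation"),
        r("k_OApf", 0.01, 1e-3, 0.1, "1/(molecule·min)", "AR + O_A' binding"),
        r("k_OApr", 0.1, 0.01, 1.0, "1/min", "AR:O_A' unbinding"),
        r("f_RA", 5.0, 1.0, 25.0, "-", "activation fold via O_A'"),
        r("f_Ract", 5.0, 1.0, 25.0, "-", "activation fold, R_act"),
        r("d_r", 0.1, 0.02, 0.5, "1/min", "r degradation (t1/2 ~ 7 min)"),
        r("d_a", 0.1, 0.02, 0.5, "1/min", "a degradation"),
        r("d_R", 0.01, 1e-3, 0.1, "1/min", "ScbR monomer degradation"),
        r("d_R2", 0.005, 5e-4, 0.05, "1/min", "ScbR dimer degradation"),
        r("d_A", 0.01, 1e-3, 0.1, "1/min", "ScbA degradation (enrichment window)"),
        r("d_C", 0.005, 5e-4, 0.05, "1/min", "GBL degradation (internal=external)"),
        r("d_AR", 0.01, 1e-3, 0.1, "1/min", "AR degradation"),
        r("s_r", 1.0, 0.5, 2.0, "-", "r observation scale factor"),
        r("s_a", 1.0, 0.5, 2.0, "-", "a observation scale factor"),
    ]
    priors = {s.param_id: s for s in specs}
    assert tuple(priors) == SAMPLED_PARAMETERS
    return priors


@dataclass(frozen=True)
class Ensemble:
    """A seeded matrix of independent prior draws, one row per member.

    The identical ensemble is reused across all scenarios, which is what
    makes pass counts and likelihood profiles comparable between mechanisms.
    """

    param_ids: tuple[str, ...]
    values: np.ndarray          # (n_members, n_params)
    seed: int
    priors: dict[str, PriorSpec] = field(repr=False, default_factory=dict)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, param_id: str) -> np.ndarray:
        return self.values[:, self.param_ids.index(param_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.param_ids))

    def member(self, i: int) -> ParameterSet:
        return ParameterSet(dict(zip(self.param_ids, self.values[i])))

    def members(self) -> Iterable[ParameterSet]:
        for i in range(self.n):
            yield self.member(i)


def sample_ensemble(priors: dict[str, PriorSpec], n: int, seed: int,
                    param_ids: Sequence[str] = SAMPLED_PARAMETERS) -> Ensemble:
    """Draw ``n`` parameter sets, each parameter independently log-normal.

    Deterministic: the same ``seed`` and priors give a bitwise-identical
    matrix.  Raises if any requested parameter lacks a prior.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    missing = [p for p in param_ids if p not in priors]
    if missing:
        raise ValueError(f"no prior defined for parameter(s): {missing}")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(param_ids)))
    loc = np.array([priors[p].location for p in param_ids])
    scale = np.array([priors[p].scale for p in param_ids])
    values = np.exp(loc + scale * z)
    return Ensemble(tuple(param_ids), values, seed, dict(priors))


def constrain_ratio(ens: Ensemble, param_a: str, param_b: str,
                    ratio_range: tuple[float, float], seed: int | None = None,
                    max_tries: int = 1000) -> Ensemble:
    """Enforce ``lo <= param_a/param_b <= hi`` by re-drawing the pair.

    Members violating the constraint get fresh draws of the two parameters
    from their own priors (rejection sampling), leaving every other
    parameter's draws untouched — this realises promoter-strength sweep arms
    such as k_FR/k_FA restricted to (1, 10) without disturbing the rest of
    the ensemble.
    """
    lo, hi = ratio_range
    if not (0 < lo <= hi):
        raise ValueError("ratio range must satisfy 0 < lo <= hi")
    for p in (param_a, param_b):
        if p not in ens.param_ids:
            raise ValueError(f"parameter {p!r} not in ensemble")
        if p not in ens.priors:
            raise ValueError(f"no prior recorded for {p!r}; cannot resample")
    ia, ib = ens.param_ids.index(param_a), ens.param_ids.index(param_b)
    values = ens.values.copy()
    rng = np.random.default_rng(ens.seed + 1 if seed is None else seed)
    pa, pb = ens.priors[param_a], ens.priors[param_b]
    if lo == hi and pa.scale == 0 and pb.scale == 0 and \
            not lo * 0.999 <= pa.median / pb.median <= hi * 1.001:
        raise ValueError("degenerate priors cannot satisfy the ratio constraint")
    bad = ~((values[:, ia] / values[:, ib] >= lo) &
            (values[:, ia] / values[:, ib] <= hi))
    if lo == hi:
        # zero-measure constraint: set a = lo * b exactly
        values[bad, ia] = lo * values[bad, ib]
        bad[:] = False
    tries = 0
    while bad.any():
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"ratio constraint {param_a}/{param_b} in [{lo}, {hi}] has "
                f"negligible prior mass ({int(bad.sum())} members unresolved)")
        k = int(bad.sum())
        za = np.exp(pa.location + pa.scale * rng.standard_normal(k))
        zb = np.exp(pb.location + pb.scale * rng.standard_normal(k))
        ok = (za / zb >= lo) & (za / zb <= hi)
        rows = np.flatnonzero(bad)[ok]
        values[rows, ia] = za[ok]
        values[rows, ib] = zb[ok]
        bad[rows] = False
    return Ensemble(ens.param_ids, values, ens.seed, ens.priors)


# ---------------------------------------------------------------------------
# Prior table I/O (tab-delimited text)
# ---------------------------------------------------------------------------

def write_priors(priors: dict[str, PriorSpec], path) -> None:
    """Write a prior table as tab-delimited text.

    Human-facing columns give median and 95% range; the exact log-scale
    ``location``/``scale`` are stored alongside so a round trip reproduces
    bitwise-identical draws.
    """
    rows = []
    for p in priors.values():
        lo, hi = p.interval95()
        rows.append({"parameter_id": p.param_id, "median": p.median,
                     "lo95": lo, "hi95": hi, "location": p.location,
                     "scale": p.scale, "units": p.units, "note": p.note})
    # %.17g is round-trip exact for doubles, so reloading reproduces draws
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_priors(path) -> dict[str, PriorSpec]:
    """Read a prior table; user tables may omit the location/scale columns."""
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    priors = {}
    for row in df.itertuples(index=False):
        units = "" if pd.isna(getattr(row, "units", "")) else str(row.units)
        note = "" if pd.isna(getattr(row, "note", "")) else str(row.note)
        pid = str(row.parameter_id)
        if hasattr(row, "location") and hasattr(row, "scale"):
            priors[pid] = PriorSpec(pid, float(row.location), float(row.scale),
                                    units, note)
            continue
        med, lo, hi = float(row.median), float(row.lo95), float(row.hi95)
        if hi == lo:
            priors[pid] = PriorSpec(pid, math.log(med), 0.0, units, note)
        else:
            priors[pid] = PriorSpec.from_range(pid, med, lo, hi, units, note)
    return priors
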