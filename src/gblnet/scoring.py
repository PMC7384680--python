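"""Total log-likelihood scoring of simulated trajectories against targets.

Each ensemble member is compared with the target features — the *scbR* and
*scbA* transcript time profiles and the GBL activation threshold — through a
total log-likelihood (TLL): the sum of independent Gaussian log-densities of
the residuals at every target point, normalisation constants included, so
TLL is an absolute quantity comparable across members and scenarios.  Values
closer to 0 mean a better overall fit; a member "accommodates the data" when
its TLL exceeds the pass threshold (default −140, strict inequality).

Simulated transcripts (molecules/cell) map to target units through the
per-member observation scale factors ``s_r``/``s_a`` (transcriptomics-style
intensities are not absolute concentrations).  The activation threshold is
extracted as the intracellular GBL concentration [nM] at the moment the
unrepressed fraction of the *scbA* operator last rises through 50%; members
that never activate receive a fixed penalty instead of a Gaussian term.
Failed simulations score −inf and never pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .parameters import ParameterSet, nm_per_molecule

__all__ = [
    "TargetSeries",
    "TargetFeatures",
    "activation_threshold",
    "total_log_likelihood",
    "score_ensemble",
    "rank_and_count",
    "predictive_density",
    "PASS_THRESHOLD",
]

#: Default TLL pass threshold (strict: a member passes iff TLL > threshold).
PASS_THRESHOLD = -140.0

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class TargetSeries:
    """Time-stamped target values with per-point uncertainties for one observable."""

    times: np.ndarray     # [min]
    values: np.ndarray    # target units
    sds: np.ndarray       # same units, > 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        s = np.asarray(self.sds, dtype=float)
        if not (t.shape == v.shape == s.shape) or t.ndim != 1:
            raise ValueError("times, values and sds must be equal-length 1-D arrays")
        if np.any(s <= 0):
            raise ValueError("target uncertainties must be positive")
        if np.any(t < 0):
            raise ValueError("target times must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sds", s)


@dataclass(frozen=True)
class TargetFeatures:
    """The comparison features: two transcript profiles plus the activation threshold."""

    scbr: TargetSeries
    scba: TargetSeries
    threshold_nM: float
    threshold_sd: float
    species_map: dict = field(default_factory=lambda: {"scbr": "r", "scba": "a"})
    scale_map: dict = field(default_factory=lambda: {"scbr": "s_r", "scba": "s_a"})

    def __post_init__(self) -> None:
        if not self.threshold_sd > 0:
            raise ValueError("threshold uncertainty must be positive")

    def n_points(self) -> int:
        return len(self.scbr.times) + len(self.scba.times) + 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, series in (("scbr", self.scbr), ("scba", self.scba)):
            for t, v, s in zip(series.times, series.values, series.sds):
                rows.append({"observable": name, "time_min": t, "value": v, "sd": s})
        rows.append({"observable": "activation_threshold", "time_min": np.nan,
                     "value": self.threshold_nM, "sd": self.threshold_sd})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TargetFeatures":
        series = {}
        for name in ("scbr", "scba"):
            sub = df[df["observable"] == name].sort_values("time_min")
            series[name] = TargetSeries(sub["time_min"].to_numpy(),
                                        sub["value"].to_numpy(),
                                        sub["sd"].to_numpy())
        thr = df[df["observable"] == "activation_threshold"].iloc[0]
        return cls(series["scbr"], series["scba"],
                   float(thr["value"]), float(thr["sd"]))


def activation_threshold(sim, params: ParameterSet) -> float:
    """GBL concentration [nM] at which the system switches on.

    Defined as the intracellular GBL concentration at the last upcrossing of
    the unrepressed-O_A fraction through 50% — the point where the rising
    signal has sequestered enough ScbR to free the *scbA* operator.  Returns
    NaN when the fraction never (re-)crosses 0.5 from below.
    """
    oa_free = sim.species("OA_free")
    oa_tot = oa_free + sim.species("OA_1") + sim.species("OA_2")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(oa_tot > 1e-12, oa_free / np.maximum(oa_tot, 1e-300), np.nan)
    below = frac < 0.5
    up = np.flatnonzero(below[:-1] & ~below[1:])
    if len(up) == 0:
        return float("nan")
    i = int(up[-1])
    f0, f1 = frac[i], frac[i + 1]
    w = 0.0 if f1 == f0 else (0.5 - f0) / (f1 - f0)
    c = sim.species("C")
    c_cross = c[i] + w * (c[i + 1] - c[i])
    return float(c_cross * nm_per_molecule(params["V_cell"]))


def _gauss_logpdf(x, mu, sd):
    z = (np.asarray(x) - mu) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def total_log_likelihood(sim, targets: TargetFeatures,
                         params: ParameterSet | None = None,
                         missing_threshold_penalty: float = -25.0,
                         log_scale: bool = False) -> float:
    """TLL of one simulation against the target features.

    Gaussian residuals on the linear scale by default; ``log_scale=True``
    instead treats values and uncertainties as multiplicative (residuals on
    log values, sds interpreted as log-scale sds).  Failed simulations
    return −inf.
    """
    if not sim.ok:
        return -math.inf
    if params is None:
        raise ValueError("params needed for observation scale factors")
    tll = 0.0
    for name in ("scbr", "scba"):
        series: TargetSeries = getattr(targets, name)
        scale = float(params[targets.scale_map[name]])
        traj = sim.species(targets.species_map[name]) * scale
        pred = np.interp(series.times, sim.t, traj)
        if log_scale:
            eps = 1e-12
            lp = _gauss_logpdf(np.log(pred + eps), np.log(series.values + eps),
                               series.sds)
        else:
            lp = _gauss_logpdf(pred, series.values, series.sds)
        tll += float(np.sum(lp))
    thr = activation_threshold(sim, params)
    if math.isnan(thr):
        tll += missing_threshold_penalty
    elif log_scale:
        tll += float(_gauss_logpdf(math.log(thr + 1e-12),
                                   math.log(targets.threshold_nM + 1e-12),
                                   targets.threshold_sd))
    else:
        tll += float(_gauss_logpdf(thr, targets.threshold_nM, targets.threshold_sd))
    return tll


def max_achievable_tll(targets: TargetFeatures, log_scale: bool = False) -> float:
    """TLL of a zero-residual member: the sum of Gaussian normalisation constants."""
    total = 0.0
    for series in (targets.scbr, targets.scba):
        total += float(np.sum(-np.log(series.sds) - 0.5 * _LOG_2PI))
    total += -math.log(targets.threshold_sd) - 0.5 * _LOG_2PI
    return total


def score_ensemble(results: Iterable, targets: TargetFeatures, ens,
                   threshold: float = PASS_THRESHOLD,
                   log_scale: bool = False) -> pd.DataFrame:
    """Score a list of simulation results into a tidy table.

    Columns: member, scenario, status, tll, passed (strict ``tll >
    threshold``).  Members are matched to their parameter sets through the
    ensemble, which supplies the per-member observation scale factors.
    """
    rows = []
    for sim in results:
        params = ens.member(sim.member) if sim.member >= 0 else None
        tll = total_log_likelihood(sim, targets, params, log_scale=log_scale) \
            if sim.ok else -math.inf
        rows.append({"member": sim.member, "scenario": sim.scenario,
                     "status": sim.status, "tll": tll,
                     "passed": bool(tll > threshold)})
    return pd.DataFrame(rows)


def rank_and_count(scores: pd.DataFrame,
                   threshold: float = PASS_THRESHOLD) -> dict:
    """Per-scenario pass counts and descending TLL profiles.

    Returns ``{"pass_counts": Series, "profiles": {label: sorted TLLs},
    "table": scores with per-scenario rank}``.  Because the same ensemble is
    used for every scenario, counts are directly comparable.
    """
    scores = scores.copy()
    scores["passed"] = scores["tll"] > threshold
    scores["rank"] = scores.groupby("scenario")["tll"] \
        .rank(ascending=False, method="first").astype(int)
    pass_counts = scores.groupby("scenario")["passed"].sum().astype(int)
    profiles = {label: np.sort(sub["tll"].to_numpy())[::-1]
                for label, sub in scores.groupby("scenario")}
    return {"pass_counts": pass_counts, "profiles": profiles, "table": scores}


def predictive_density(scores: pd.DataFrame) -> pd.DataFrame:
    """Ensemble-average likelihood per scenario (the predictive density).

    The mean of exp(TLL) over all members — failed members contribute zero —
    evaluated with log-sum-exp so the tiny densities do not underflow.
    Returns a frame with ``log_predictive_density`` (natural log of the mean
    likelihood) and its direct exponential.
    """
    rows = []
    for label, sub in scores.groupby("scenario"):
        tll = sub["tll"].to_numpy(dtype=float)
        n = len(tll)
        finite = tll[np.isfinite(tll)]
        if len(finite) == 0:
            lpd = -math.inf
        else:
            lpd = float(logsumexp(finite) - math.log(n))
        rows.append({"scenario": label, "n": n,
                     "log_predictive_density": lpd,
                     "predictive_density": math.exp(lpd) if np.isfinite(lpd) else 0.0})
    return pd.DataFrame(rows).set_index("scenario")
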