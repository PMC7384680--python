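"""Model/Results entry points for growth fitting and the ensemble check.

Two statsmodels-style pairs:

* :class:`BaranyiGrowthModel` — built from growth observations; ``fit()``
  runs the multi-start nonlinear least squares and returns
  :class:`BaranyiGrowthResults` with the best parameters, the confidence set
  of comparably good fits, and a ``summary()`` table.
* :class:`GBLEnsembleModel` — built from target features, growth parameters
  and priors; ``fit(n, seed)`` performs the prior predictive check (sample →
  simulate every scenario → score) and returns :class:`GBLEnsembleResults`
  carrying the score table, pass counts, predictive densities and the
  enrichment statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import enrichment as enr
from .growth import GrowthParams, fit_growth, population
from .network import ScenarioConfig
from .priors import Ensemble, PriorSpec, default_priors, sample_ensemble
from .scoring import (
    PASS_THRESHOLD,
    TargetFeatures,
    predictive_density,
    rank_and_count,
    score_ensemble,
)
from .simulate import default_grid, run_ensemble

__all__ = [
    "BaranyiGrowthModel",
    "BaranyiGrowthResults",
    "GBLEnsembleModel",
    "GBLEnsembleResults",
]


class BaranyiGrowthModel:
    """Baranyi–Roberts growth model for a sparse batch-culture time course."""

    def __init__(self, time_min, cells):
        self.time_min = np.asarray(time_min, dtype=float)
        self.cells = np.asarray(cells, dtype=float)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "time_min",
                       cells_col: str = "cells") -> "BaranyiGrowthModel":
        return cls(df[time_col].to_numpy(), df[cells_col].to_numpy())

    def fit(self, n_starts: int = 40, seed: int = 0,
            keep_factor: float = 1.05) -> "BaranyiGrowthResults":
        best, conf, sse, resid, degenerate = fit_growth(
            self.time_min, self.cells, n_starts=n_starts, seed=seed,
            keep_factor=keep_factor)
        return BaranyiGrowthResults(self, best, conf, sse, resid, degenerate)


@dataclass
class BaranyiGrowthResults:
    """Best fit plus the confidence set of comparably good growth fits."""

    model: BaranyiGrowthModel
    params: GrowthParams
    confidence_set: list           # [(GrowthParams, sse), ...] sorted by SSE
    sse: float
    resid: np.ndarray = field(repr=False, default=None)
    degenerate: bool = False

    def predict(self, t):
        n, _ = population(t, self.params)
        return n

    def mu(self, t):
        _, mu = population(t, self.params)
        return mu

    def param_ranges(self) -> pd.DataFrame:
        arr = np.array([gp.to_array() for gp, _ in self.confidence_set])
        from .growth import FIELD_NAMES
        return pd.DataFrame({
            "best": self.params.to_array(),
            "min": arr.min(axis=0), "max": arr.max(axis=0),
        }, index=list(FIELD_NAMES))

    def summary(self) -> str:
        from .growth import FIELD_NAMES
        units = {"K": "cells", "N0": "cells", "mu_max": "1/min",
                 "v": "1/min", "m": "-", "lam": "min"}
        lines = ["Baranyi-Roberts growth fit",
                 "=" * 54,
                 f"observations: {len(self.model.time_min)}   "
                 f"SSE(log): {self.sse:.4g}   "
                 f"confidence set: {len(self.confidence_set)} fits"]
        if self.degenerate:
            lines.append("WARNING: observations are flat - no lag/exponential "
                         "information (degenerate fit)")
        rng = self.param_ranges()
        lines.append(f"{'param':>8} {'best':>12} {'set min':>12} "
                     f"{'set max':>12}  units")
        for name in FIELD_NAMES:
            lines.append(f"{name:>8} {rng.loc[name, 'best']:>12.4g} "
                         f"{rng.loc[name, 'min']:>12.4g} "
                         f"{rng.loc[name, 'max']:>12.4g}  {units[name]}")
        return "\n".join(lines)


class GBLEnsembleModel:
    """Prior predictive check of the GBL circuit scenarios against target data.

    Parameters
    ----------
    targets : TargetFeatures
        Transcript profiles and activation threshold to score against.
    growth : GrowthParams
        Growth curve coupling μ(t) into the circuit ODEs.
    priors : dict[str, PriorSpec], optional
        Per-parameter log-normal priors (default: the package prior table).
    scenarios : sequence of scenario labels, default "A".."H".
    """

    def __init__(self, targets: TargetFeatures, growth: GrowthParams,
                 priors: dict[str, PriorSpec] | None = None,
                 scenarios: Sequence[str] = "ABCDEFGH",
                 tll_threshold: float = PASS_THRESHOLD,
                 rtol: float = 1e-6, atol: float = 1e-9,
                 grid_step: float = 5.0, log_scale: bool = False):
        self.targets = targets
        self.growth = growth
        self.priors = priors if priors is not None else default_priors()
        self.scenarios = [ScenarioConfig.from_label(s) if not isinstance(s, ScenarioConfig)
                          else s for s in scenarios]
        if len({s.label for s in self.scenarios}) != len(self.scenarios):
            raise ValueError("duplicate scenario labels")
        self.tll_threshold = float(tll_threshold)
        self.rtol, self.atol = rtol, atol
        self.grid_step = grid_step
        self.log_scale = log_scale

    def fit(self, n: int = 10_000, seed: int = 0,
            ensemble: Ensemble | None = None) -> "GBLEnsembleResults":
        """Sample (or reuse) the ensemble, simulate every scenario, score."""
        ens = ensemble if ensemble is not None else \
            sample_ensemble(self.priors, n, seed)
        grid = default_grid(self.grid_step)
        sims = run_ensemble(ens, self.scenarios, self.growth, grid,
                            rtol=self.rtol, atol=self.atol)
        scores = score_ensemble(sims, self.targets, ens,
                                threshold=self.tll_threshold,
                                log_scale=self.log_scale)
        return GBLEnsembleResults(self, ens, scores)


@dataclass
class GBLEnsembleResults:
    """Scored ensemble: per-(member, scenario) TLLs and derived statistics."""

    model: GBLEnsembleModel
    ensemble: Ensemble
    score_table: pd.DataFrame

    @property
    def scenario_labels(self) -> list[str]:
        return [s.label for s in self.model.scenarios]

    def pass_counts(self, threshold: float | None = None) -> pd.Series:
        thr = self.model.tll_threshold if threshold is None else threshold
        return rank_and_count(self.score_table, thr)["pass_counts"]

    def profiles(self, threshold: float | None = None) -> dict:
        thr = self.model.tll_threshold if threshold is None else threshold
        return rank_and_count(self.score_table, thr)["profiles"]

    def predictive_density(self) -> pd.DataFrame:
        return predictive_density(self.score_table)

    def passing_members(self, scenario: str,
                        threshold: float | None = None) -> np.ndarray:
        thr = self.model.tll_threshold if threshold is None else threshold
        sub = self.score_table
        sel = sub[(sub["scenario"] == scenario) & (sub["tll"] > thr)]
        return sel["member"].to_numpy()

    def ks_enrichment(self, scenario: str, alpha: float = 0.05,
                      threshold: float | None = None) -> pd.DataFrame:
        members = self.passing_members(scenario, threshold)
        return enr.ks_enrichment(self.ensemble, members, alpha=alpha)

    def bin_enrichment(self, scenario: str, param: str, n_bins: int = 20,
                       fdr: float = 0.05, threshold: float | None = None,
                       method: str = "bh") -> pd.DataFrame:
        members = self.passing_members(scenario, threshold)
        if len(members) == 0:
            raise ValueError(f"no members pass in scenario {scenario}")
        full = self.ensemble.column(param)
        return enr.bin_enrichment(full, full[members], n_bins=n_bins,
                                  fdr=fdr, method=method)

    def summary(self) -> str:
        pc = self.pass_counts()
        pdens = self.predictive_density()
        n_members = self.ensemble.n
        lines = ["GBL circuit ensemble prior predictive check",
                 "=" * 58,
                 f"members: {n_members}   scenarios: "
                 f"{', '.join(self.scenario_labels)}   "
                 f"TLL threshold: {self.model.tll_threshold:g}",
                 f"{'scenario':>9} {'passing':>8} {'failed_sims':>12} "
                 f"{'best TLL':>10} {'log pred.dens.':>15}"]
        for label in self.scenario_labels:
            sub = self.score_table[self.score_table["scenario"] == label]
            failed = int((sub["status"] != "ok").sum())
            best = sub["tll"].max()
            lpd = pdens.loc[label, "log_predictive_density"]
            best_s = f"{best:.1f}" if math.isfinite(best) else "-inf"
            lpd_s = f"{lpd:.1f}" if math.isfinite(lpd) else "-inf"
            lines.append(f"{label:>9} {int(pc.get(label, 0)):>8} {failed:>12} "
                         f"{best_s:>10} {lpd_s:>15}")
        return "\n".join(lines)
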