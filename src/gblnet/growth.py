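"""Baranyi–Roberts growth curve for the *Streptomyces* batch culture.

The cell population over the ~60 h culture is described by the six-parameter
Baranyi–Roberts model

.. math::

    \\frac{dN}{dt} = \\mu_{max}\\,\\alpha(t)\\,N\\,\\Bigl(1-\\bigl(N/K\\bigr)^m\\Bigr),
    \\qquad
    \\alpha(t) = \\frac{q(t)}{1+q(t)},\\quad q(t) = q_0 e^{vt},

where the adjustment function :math:`\\alpha` encodes the lag phase
(:math:`q_0 = 1/(e^{v\\lambda}-1)` so that the asymptote of the integrated
adjustment is :math:`t-\\lambda`) and :math:`m` is a Richards-type curvature
of the exponential→stationary transition.  Because the equation is separable
in the transformed time :math:`A(t)=\\int_0^t \\alpha`, the solution is
available in closed form and both :math:`N(t)` and the instantaneous specific
growth rate :math:`\\mu(t) = \\dot N/N` are evaluated exactly — the circuit
ODEs use :math:`\\mu(t)` for dilution and DNA replication.

Parameters (units): K [cells], N0 [cells], mu_max [1/min], v [1/min],
m [-], lam [min].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["GrowthParams", "adjustment", "population", "fit_growth", "GrowthFitError"]


class GrowthFitError(RuntimeError):
    """Raised when no multi-start fit of the growth curve converges."""


@dataclass(frozen=True)
class GrowthParams:
    """The six Baranyi–Roberts parameters."""

    K: float        # carrying capacity [cells]
    N0: float       # initial population [cells]
    mu_max: float   # maximum specific growth rate [1/min]
    v: float        # lag→exponential curvature [1/min]
    m: float        # exponential→stationary curvature [-]
    lam: float      # lag phase [min]

    def __post_init__(self) -> None:
        for name in ("K", "N0", "mu_max", "v", "m"):
            if not getattr(self, name) > 0:
                raise ValueError(f"growth parameter {name} must be positive")
        if self.lam < 0:
            raise ValueError("lag phase lam must be non-negative")
        if not self.N0 < self.K:
            raise ValueError("initial population N0 must be below carrying capacity K")

    def to_array(self) -> np.ndarray:
        return np.array([self.K, self.N0, self.mu_max, self.v, self.m, self.lam])

    @staticmethod
    def from_array(x) -> "GrowthParams":
        return GrowthParams(*(float(v) for v in x))


FIELD_NAMES = ("K", "N0", "mu_max", "v", "m", "lam")


def _log_q0(gp: GrowthParams) -> float:
    """log q0 with q0 = 1/(e^{v λ} - 1); +inf in the no-lag limit."""
    x = gp.v * gp.lam
    if x <= 0:
        return np.inf
    if x > 700.0:  # expm1 would overflow; log(e^x - 1) ~ x
        return -x
    return -np.log(np.expm1(x))


def adjustment(t, gp: GrowthParams):
    """Baranyi lag-phase adjustment α(t) = q(t)/(1+q(t)), in (0, 1]."""
    t = np.asarray(t, dtype=float)
    lq = _log_q0(gp)
    if np.isinf(lq):
        return np.ones_like(t)
    z = lq + gp.v * t
    # logistic function of z, numerically safe for large |z|
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _adjusted_time(t, gp: GrowthParams):
    """A(t) = ∫0^t α(s) ds = (1/v)·[softplus(log q0 + v t) − softplus(log q0)]."""
    t = np.asarray(t, dtype=float)
    lq = _log_q0(gp)
    if np.isinf(lq):
        return t.copy()
    return (np.logaddexp(0.0, lq + gp.v * t) - np.logaddexp(0.0, lq)) / gp.v


def population(t, gp: GrowthParams):
    """Population size N(t) and specific growth rate μ(t) = (dN/dt)/N.

    Returns a pair of arrays (or floats for scalar ``t``).  N(0) = N0 and
    N(t) → K; μ(t) = μ_max·α(t)·(1−(N/K)^m) is bounded by μ_max.
    """
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    a_t = _adjusted_time(t, gp)
    ratio_m = (gp.K / gp.N0) ** gp.m
    denom = 1.0 + (ratio_m - 1.0) * np.exp(-gp.m * gp.mu_max * a_t)
    n = gp.K * denom ** (-1.0 / gp.m)
    mu = gp.mu_max * adjustment(t, gp) * (1.0 - (n / gp.K) ** gp.m)
    if scalar:
        return float(n[0]), float(mu[0])
    return n, mu


# ---------------------------------------------------------------------------
# Nonlinear least-squares fitting
# ---------------------------------------------------------------------------

_LOG_BOUNDS = {
    "K": (1e10, 1e14),
    "N0": (1e8, 1e13),
    "mu_max": (1e-4, 0.1),
    "v": (1e-4, 10.0),
    "m": (0.1, 10.0),
    "lam": (1.0, 5000.0),
}


def _residuals(x, t, log_n):
    gp = GrowthParams.from_array(np.exp(x))
    n, _ = population(t, gp)
    return np.log(n) - log_n


def fit_growth(obs_t, obs_n, n_starts: int = 40, seed: int = 0,
               keep_factor: float = 1.05):
    """Multi-start nonlinear least squares fit of the Baranyi–Roberts curve.

    Residuals are taken on log population (multiplicative error), parameters
    are optimised in log space within positivity bounds.  All converged fits
    whose SSE is within ``keep_factor`` of the best form the confidence set —
    with few observations (the reference experiment has 11 points) many
    parameter combinations fit comparably well and the spread of this set is
    the reported uncertainty.

    Returns ``(best, confidence_set, best_sse, residuals)`` where ``best`` is a
    :class:`GrowthParams`, ``confidence_set`` a list of (GrowthParams, sse)
    pairs sorted by SSE, and ``residuals`` the log-scale residual vector of the
    best fit.  Raises :class:`ValueError` for under-determined input and
    :class:`GrowthFitError` if no start converges.
    """
    t = np.asarray(obs_t, dtype=float)
    n = np.asarray(obs_n, dtype=float)
    if t.shape != n.shape or t.ndim != 1:
        raise ValueError("observations must be two equal-length 1-D arrays")
    if len(t) < 7:
        raise ValueError(
            f"need at least 7 observations to fit 6 parameters, got {len(t)}")
    if np.any(n <= 0):
        raise ValueError("cell counts must be positive")
    log_n = np.log(n)
    degenerate = np.ptp(log_n) < 1e-3  # flat data: no lag/exponential information
    if degenerate:
        # no lag/exponential information: report a stationary culture at the
        # observed level rather than pretending the optimiser learned anything
        nbar = float(np.exp(log_n.mean()))
        gp = GrowthParams(K=nbar, N0=0.99 * nbar, mu_max=1e-4, v=1e-3,
                          m=1.0, lam=1.0)
        resid = np.log(population(t, gp)[0]) - log_n
        sse = float(np.sum(resid ** 2))
        return gp, [(gp, sse)], sse, resid, True

    lo = np.log([_LOG_BOUNDS[f][0] for f in FIELD_NAMES])
    hi = np.log([_LOG_BOUNDS[f][1] for f in FIELD_NAMES])
    rng = np.random.default_rng(seed)

    # First start from crude data-driven guesses, the rest random in the box.
    n_max, n_min = float(n.max()), float(n.min())
    guess = np.log(np.clip(
        [n_max * 1.05, max(n_min, 1e9), 0.005, 0.01, 1.0, max(t.max() / 6.0, 2.0)],
        np.exp(lo), np.exp(hi)))
    starts = [guess] + [rng.uniform(lo, hi) for _ in range(max(n_starts - 1, 0))]

    fits: list[tuple[GrowthParams, float, np.ndarray]] = []
    for x0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = least_squares(_residuals, x0, bounds=(lo, hi),
                                    args=(t, log_n), method="trf",
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                    max_nfev=2000)
        except (ValueError, FloatingPointError):
            continue
        if not sol.success:
            continue
        try:
            gp = GrowthParams.from_array(np.exp(sol.x))
        except ValueError:
            continue
        fits.append((gp, float(np.sum(sol.fun ** 2)), sol.fun))
    if not fits:
        raise GrowthFitError(
            f"none of {len(starts)} starts converged on {len(t)} observations")
    fits.sort(key=lambda f: f[1])
    best, best_sse, best_resid = fits[0]
    cutoff = max(keep_factor * best_sse, best_sse + 1e-12)
    conf = [(gp, sse) for gp, sse, _ in fits if sse <= cutoff]
    return best, conf, best_sse, best_resid, degenerate
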