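"""Deterministic mutation–selection dynamics for an engineered strain in culture.

Two strains grow logistically in batch culture: an *engineered* strain
carrying a foreign transgene, and a *revertant* (wild-type) strain that has
lost it.  The engineered strain pays a selective cost ``s`` (its per-capita
growth rate is ``r*(1-s)``) and loses the transgene with probability ``mu``
per replication; back mutation is ignored.  This module provides the full
two-type logistic ODE, its exponential-phase approximation for the transgene
frequency, the closed-form frequency trajectory, and half-life (t50)
predictions derived from it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "ModelParams",
    "PopulationState",
    "full_ode_rhs",
    "integrate_full_model",
    "frequency_ode_rhs",
    "frequency_trajectory",
    "half_life",
    "half_life_gain",
    "half_life_gain_grid",
]


@dataclass(frozen=True)
class ModelParams:
    """Growth and evolutionary parameters of the two-strain model.

    Parameters
    ----------
    r : float
        Wild-type per-capita growth rate, per hour.  Must be positive.
    s : float
        Selection coefficient against the transgene, in ``[0, 1)``.  The
        engineered strain grows at rate ``r * (1 - s)``.
    mu : float
        Per-replication probability that an engineered parent produces a
        transgene-free (revertant) offspring, in ``[0, 1)``.
    K : float
        Carrying capacity of the culture (cell count scale).  Must be
        positive.
    """

    r: float
    s: float
    mu: float
    K: float = 2e6

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"growth rate r must be positive, got {self.r}")
        if not 0 <= self.s < 1:
            raise ValueError(f"selection coefficient s must be in [0, 1), got {self.s}")
        if not 0 <= self.mu < 1:
            raise ValueError(f"mutation rate mu must be in [0, 1), got {self.mu}")
        if not self.K > 0:
            raise ValueError(f"carrying capacity K must be positive, got {self.K}")


@dataclass
class PopulationState:
    """Counts of engineered (``N_E``) and revertant (``N_R``) individuals at time ``t`` (hours)."""

    N_E: float
    N_R: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.N_E < 0 or self.N_R < 0:
            raise ValueError("population counts must be non-negative")

    @property
    def total(self) -> float:
        return self.N_E + self.N_R

    @property
    def frequency(self) -> float:
        """Frequency of the engineered strain, ``N_E / (N_E + N_R)``."""
        tot = self.total
        return self.N_E / tot if tot > 0 else np.nan


def full_ode_rhs(state: PopulationState, params: ModelParams) -> tuple[float, float]:
    """Time derivatives ``(dN_E/dt, dN_R/dt)`` of the two-type logistic model.

    Engineered births occur at rate ``r(1-s) N_E (1 - N/K)``; a fraction
    ``mu`` of those births are revertant offspring (mutational loss acts at
    replication).  Revertants grow at the full wild-type rate.  The logistic
    factor is shared by both strains and is *not* clamped at zero, so a
    population above ``K`` relaxes back toward it.
    """
    f = 1.0 - (state.N_E + state.N_R) / params.K
    births_E = params.r * (1.0 - params.s) * state.N_E * f
    dN_E = births_E * (1.0 - params.mu)
    dN_R = params.r * state.N_R * f + births_E * params.mu
    return dN_E, dN_R


def integrate_full_model(
    initial: PopulationState,
    params: ModelParams,
    t_end: float,
    *,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-8,
):
    """Numerically integrate the full two-type ODE from ``initial.t`` to ``t_end``.

    Returns
    -------
    scipy.integrate.OdeResult
        With ``.t`` (hours) and ``.y`` of shape ``(2, len(t))`` holding
        ``N_E`` and ``N_R``.  Raises ``RuntimeError`` with the solver
        message on failure.
    """
    if not t_end > initial.t:
        raise ValueError("t_end must exceed the initial time")

    def rhs(t, y):
        st = PopulationState.__new__(PopulationState)
        st.N_E, st.N_R, st.t = y[0], y[1], t
        return full_ode_rhs(st, params)

    sol = solve_ivp(
        rhs,
        (initial.t, t_end),
        [initial.N_E, initial.N_R],
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    # guard against tiny negative excursions from the solver
    sol.y = np.clip(sol.y, 0.0, None)
    return sol


def frequency_ode_rhs(p: float, params: ModelParams) -> float:
    """Instantaneous rate of change of the engineered frequency, exponential phase.

    ``dp/dt = -r p [mu + s (1 - p - mu)]``; non-positive on ``[0, 1]`` for
    valid parameters, so the transgene frequency only declines.
    """
    return -params.r * p * (params.mu + params.s * (1.0 - p - params.mu))


def frequency_trajectory(p0, params: ModelParams, t):
    """Closed-form engineered-strain frequency ``p(t)`` during exponential growth.

    With ``a = s(1-mu) + mu`` the solution of the frequency ODE is::

        p(t) = p0 * a * exp(-r*a*t) / (a - s*p0*(1 - exp(-r*a*t)))

    valid while the population is far below carrying capacity.  Vectorised
    over ``t`` (and over ``p0``).  Degenerate cases: ``s = mu = 0`` returns
    ``p0`` (the 0/0 limit); when ``exp(-r*a*t)`` underflows the result is 0,
    except for ``mu = 0, p0 = 1`` where the engineered strain is never lost
    and the value is 1.
    """
    t = np.asarray(t, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    s, mu = params.s, params.mu
    a = s * (1.0 - mu) + mu
    if a == 0.0:
        return np.broadcast_arrays(p0, t)[0].copy() if t.shape or p0.shape else float(p0)
    E = np.exp(-params.r * a * t)
    num = p0 * a * E
    den = a - s * p0 * (1.0 - E)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = num / den
    # num == den == 0 happens only when mu == 0, p0 == 1 and E underflowed;
    # the true limit there is 1 (no mutational pathway out).
    p = np.where(np.isnan(p), 1.0 if mu == 0.0 else 0.0, p)
    p = np.clip(p, 0.0, 1.0)
    return p if p.shape else float(p)


def _t50_pure(params: ModelParams) -> float:
    """Closed-form t50 from a pure engineered culture (p0 = 1)."""
    s, mu = params.s, params.mu
    a = s * (1.0 - mu) + mu
    inner = mu * (1.0 - s) / (mu * (1.0 - s) + a)
    if inner == 0.0:  # mu == 0: deterministically never lost
        return np.inf
    return np.log(inner) / (-params.r * a)


def half_life(params: ModelParams, p0: float = 1.0) -> float:
    """Hours until the engineered frequency first falls to 1/2.

    For ``p0 = 1`` this is the closed form

    ``t50 = ln[ mu(1-s) / (mu(1-s) + s(1-mu) + mu) ] / (-r [s(1-mu) + mu])``

    which reduces to ``ln(2)/(r*mu)`` when ``s = 0``.  For general ``p0`` the
    root of ``p(t) = 1/2`` is bracketed numerically.  ``p0 <= 1/2`` returns
    0 (already at or below half); ``mu = 0`` with ``p0 = 1`` returns ``inf``.

    Raises
    ------
    ValueError
        If ``s = mu = 0`` (the transgene is never lost).
    """
    if params.s == 0.0 and params.mu == 0.0:
        raise ValueError("s = mu = 0: transgene is never lost, t50 undefined")
    if p0 <= 0.5:
        return 0.0
    if p0 == 1.0:
        return _t50_pure(params)
    if params.mu == 0.0 and frequency_trajectory(p0, params, np.inf) >= 0.5:
        return np.inf
    hi = max(_t50_pure(params), 1.0)
    while frequency_trajectory(p0, params, hi) > 0.5:
        hi *= 2.0
        if hi > 1e12:
            return np.inf
    return brentq(lambda t: frequency_trajectory(p0, params, t) - 0.5, 0.0, hi, xtol=1e-12, rtol=1e-14)


def half_life_gain(base: ModelParams, k_mu: float = 1.0, k_s: float = 1.0) -> float:
    """Fold-increase in t50 when mutation is cut ``k_mu``-fold and selection ``k_s``-fold.

    Returns ``t50(mu/k_mu, s/k_s, r) / t50(mu, s, r)`` from a pure culture.
    Both factors must be >= 1; the ratio is >= 1 and non-decreasing in each
    factor.  Raises ``ValueError`` for a degenerate base (``s = mu = 0``).
    """
    if k_mu < 1.0 or k_s < 1.0:
        raise ValueError("reduction factors k_mu and k_s must be >= 1")
    t_base = half_life(base)
    improved = ModelParams(r=base.r, s=base.s / k_s, mu=base.mu / k_mu, K=base.K)
    return half_life(improved) / t_base


def half_life_gain_grid(
    base: ModelParams,
    k_max: float = 100.0,
    num: int = 50,
    *,
    k_mu_max: float | None = None,
    k_s_max: float | None = None,
):
    """Tidy grid of t50 gain ratios over log-spaced reduction factors.

    Evaluates :func:`half_life_gain` on a ``num x num`` lattice of factors
    log-spaced from 1 to ``k_max`` on each axis (per-axis maxima may be
    overridden).  Returns a pandas DataFrame with columns ``k_mu``, ``k_s``,
    ``ratio`` suitable for contour plotting.
    """
    import pandas as pd

    kmu = np.logspace(0.0, np.log10(k_mu_max or k_max), num)
    ks = np.logspace(0.0, np.log10(k_s_max or k_max), num)
    t_base = half_life(base)
    rows = []
    for km in kmu:
        improved_mu = base.mu / km
        for kv in ks:
            improved = ModelParams(r=base.r, s=base.s / kv, mu=improved_mu, K=base.K)
            rows.append((km, kv, half_life(improved) / t_base))
    return pd.DataFrame(rows, columns=["k_mu", "k_s", "ratio"])
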