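"""Stochastic simulation of serial-transfer (serial passage) experiments.

A culture founded from a bottleneck of ``beta`` individuals grows for ``T``
hours under the two-type logistic birth process, a fresh culture is founded
from a random sample of ``beta`` individuals, and ``n`` of those founders are
genotyped for the transgene.  Growth is simulated with a tau-leaping
acceleration of the Gillespie algorithm, falling back to the exact SSA for
small populations.  The three birth reactions (engineered birth, engineered
parent producing a revertant offspring, revertant birth) mirror the
deterministic model term-by-term; mutation redirects a birth, it never
converts a living individual.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelParams, PopulationState

__all__ = [
    "TransferDesign",
    "CountSeries",
    "simulate_culture_growth",
    "bottleneck_and_sample",
    "simulate_experiment",
]

# tau-leap control: largest step for which every propensity is expected to
# change by <= TAU_EPSILON; exact SSA below SSA_THRESHOLD individuals.
TAU_EPSILON = 0.05
SSA_THRESHOLD = 1000


@dataclass(frozen=True)
class TransferDesign:
    """Protocol of a serial-transfer experiment.

    Parameters
    ----------
    T : float
        Hours between transfers.
    beta : int
        Bottleneck: number of individuals transferred to found each culture.
    n : int
        Number of founders genotyped at each transfer (``n <= beta``).
    R : int
        Number of replicate lineages.
    duration : float
        Total experiment length in hours (default 3600 h = 150 days).
    initial_size : int or None
        Founding population of the first culture; defaults to ``beta``.
    initial_revertants : int
        Transgene-free individuals among the founders (impure start).
    truncation_freq : float or None
        If set, a replicate stops once the *sampled* frequency ``x/n`` falls
        to or below this threshold; the triggering sample is retained.
    seed : int
        Master seed; each replicate gets an independent spawned stream.
    """

    T: float = 24.0
    beta: int = 10_000
    n: int = 100
    R: int = 3
    duration: float = 3600.0
    initial_size: int | None = None
    initial_revertants: int = 0
    truncation_freq: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n > self.beta:
            raise ValueError(f"genotyped sample n={self.n} exceeds bottleneck beta={self.beta}")
        size = self.initial_size if self.initial_size is not None else self.beta
        if self.initial_revertants > size:
            raise ValueError("initial_revertants exceeds the founding population")
        if self.T <= 0 or self.duration <= 0:
            raise ValueError("T and duration must be positive")
        if self.truncation_freq is not None and not 0 < self.truncation_freq < 1:
            raise ValueError("truncation_freq must lie in (0, 1)")

    @property
    def founding_size(self) -> int:
        return self.initial_size if self.initial_size is not None else self.beta


@dataclass
class CountSeries:
    """One replicate's genotype counts over time: at each ``t`` (hours),
    ``x`` of ``n`` sampled individuals carried the transgene."""

    replicate: str
    t: np.ndarray
    n: np.ndarray
    x: np.ndarray
    truncated: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        self.x = np.asarray(self.x, dtype=int)
        if not (len(self.t) == len(self.n) == len(self.x)):
            raise ValueError("t, n, x must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if np.any(self.x < 0) or np.any(self.x > self.n):
            raise ValueError("counts must satisfy 0 <= x <= n")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def frequency(self) -> np.ndarray:
        return self.x / self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": self.replicate,
                "time_h": self.t,
                "n_sampled": self.n,
                "x_engineered": self.x,
            }
        )


def _ssa_step(NE, NR, params, t, t_end, rng):
    """One exact Gillespie event; returns updated (NE, NR, t)."""
    f = max(0.0, 1.0 - (NE + NR) / params.K)
    aE = params.r * (1.0 - params.s) * NE * f
    aR = params.r * NR * f
    A = aE + aR
    if A <= 0.0:
        return NE, NR, t_end
    dt = rng.exponential(1.0 / A)
    if t + dt > t_end:
        return NE, NR, t_end
    if rng.random() < aE / A:  # engineered parent
        if rng.random() < params.mu:
            NR += 1  # revertant offspring (loss at replication)
        else:
            NE += 1
    else:
        NR += 1
    return NE, NR, t + dt


def simulate_culture_growth(
    start: PopulationState,
    params: ModelParams,
    t_grow: float,
    rng: np.random.Generator,
) -> PopulationState:
    """Grow a culture stochastically for ``t_grow`` hours.

    Uses Poisson tau-leaping with an adaptive step chosen so each propensity
    changes by at most ~5% per leap, and exact SSA while the population is
    below 1000.  Propensities carry the clamped logistic factor
    ``max(0, 1 - N/K)``, so an overshoot of ``K`` (at most one leap's worth)
    simply halts growth.  Counts stay non-negative integers.
    """
    NE, NR = int(start.N_E), int(start.N_R)
    r, s, mu, K = params.r, params.s, params.mu, params.K
    t = 0.0
    while t < t_grow:
        N = NE + NR
        if N == 0:
            break
        if N < SSA_THRESHOLD:
            NE, NR, t = _ssa_step(NE, NR, params, t, t_grow, rng)
            continue
        f = 1.0 - N / K
        if f <= 0.0:
            break  # saturated; births only, so it stays saturated
        aE = r * (1.0 - s) * NE * f
        aR = r * NR * f
        A = aE + aR
        # relative propensity change per leap ~ dN*(1/N + 1/(K-N))
        dt = TAU_EPSILON / (A * (1.0 / N + 1.0 / (K - N)))
        dt = min(dt, t_grow - t)
        # midpoint leap: re-evaluate propensities at the deterministic
        # half-step state, removing the O(dt) bias of frozen propensities
        NE_mid = NE + 0.5 * dt * aE * (1.0 - mu)
        NR_mid = NR + 0.5 * dt * (aE * mu + aR)
        f_mid = max(0.0, 1.0 - (NE_mid + NR_mid) / K)
        aE = r * (1.0 - s) * NE_mid * f_mid
        aR = r * NR_mid * f_mid
        bE = rng.poisson(aE * (1.0 - mu) * dt)
        bM = rng.poisson(aE * mu * dt) if mu > 0.0 else 0
        bR = rng.poisson(aR * dt) if NR_mid > 0 else 0
        NE += bE
        NR += bM + bR
        t += dt
    return PopulationState(N_E=NE, N_R=NR, t=start.t + t_grow)


def bottleneck_and_sample(
    culture: PopulationState,
    beta: int,
    n: int,
    rng: np.random.Generator,
) -> tuple[PopulationState, tuple[int, int]]:
    """Found the next culture from ``beta`` random individuals and genotype ``n`` of them.

    Both draws are without replacement (hypergeometric): the founders from
    the culture, the genotyped subsample from the founders.  If ``beta``
    meets or exceeds the population, the whole culture transfers.
    """
    if n > beta:
        raise ValueError(f"genotyped sample n={n} exceeds bottleneck beta={beta}")
    NE, NR = int(culture.N_E), int(culture.N_R)
    total = NE + NR
    if beta >= total:
        fE, fR = NE, NR
    else:
        fE = int(rng.hypergeometric(NE, NR, beta))
        fR = beta - fE
    founders_total = fE + fR
    if n >= founders_total:
        x = fE
        n_eff = founders_total
    else:
        x = int(rng.hypergeometric(fE, fR, n))
        n_eff = n
    founders = PopulationState(N_E=fE, N_R=fR, t=culture.t)
    return founders, (n_eff, x)


def simulate_experiment(
    params: ModelParams,
    design: TransferDesign,
    rng: np.random.Generator | None = None,
) -> list[CountSeries]:
    """Simulate ``design.R`` replicate serial-transfer lineages.

    Each replicate founds a culture of ``design.founding_size`` individuals
    (with ``initial_revertants`` transgene-free), genotypes ``n`` of them for
    the t=0 sample, then alternates growth for ``T`` hours with a
    bottleneck-and-genotype transfer until ``duration`` is reached or the
    sampled frequency drops to the truncation threshold.  Replicates use
    independent RNG streams spawned from the design seed, so a fixed seed
    gives bit-identical output.
    """
    if rng is None:
        streams = np.random.SeedSequence(design.seed).spawn(design.R)
        rngs = [np.random.default_rng(s) for s in streams]
    else:
        rngs = [rng] * design.R

    out: list[CountSeries] = []
    for rep in range(design.R):
        g = rngs[rep]
        size = design.founding_size
        culture = PopulationState(
            N_E=size - design.initial_revertants,
            N_R=design.initial_revertants,
            t=0.0,
        )
        # t0 genotyping sample, drawn from the founding culture itself
        _, (n0, x0) = bottleneck_and_sample(culture, beta=max(design.beta, size), n=design.n, rng=g)
        times, ns, xs = [0.0], [n0], [x0]
        truncated = False
        t = 0.0
        while t + design.T <= design.duration + 1e-9:
            grown = simulate_culture_growth(culture, params, design.T, g)
            culture, (nj, xj) = bottleneck_and_sample(grown, design.beta, design.n, g)
            t += design.T
            times.append(t)
            ns.append(nj)
            xs.append(xj)
            if design.truncation_freq is not None and xj / nj <= design.truncation_freq:
                truncated = True
                break
        out.append(
            CountSeries(
                replicate=f"rep{rep + 1}",
                t=np.array(times),
                n=np.array(ns),
                x=np.array(xs),
                truncated=truncated,
                meta={
                    "seed": design.seed,
                    "replicate_index": rep,
                    "design": {
                        "T": design.T,
                        "beta": design.beta,
                        "n": design.n,
                        "R": design.R,
                        "duration": design.duration,
                        "initial_size": design.founding_size,
                        "initial_revertants": design.initial_revertants,
                        "truncation_freq": design.truncation_freq,
                    },
                    "params": {"r": params.r, "s": params.s, "mu": params.mu, "K": params.K},
                },
            )
        )
    return out
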