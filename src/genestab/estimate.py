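"""Maximum-likelihood estimation of mutation and selection from count series.

At each sampling time ``t_j`` a replicate contributes a binomial observation
``x_j ~ Binomial(n_j, p(t_j))``, with ``p(t)`` the closed-form exponential
phase frequency trajectory.  Minimising the pooled negative log-likelihood
over ``(mu, s)`` — with the per-hour growth rate ``r`` assumed known — gives
the joint estimate, profile likelihood gives approximate 95% confidence
intervals, and the fitted trajectory with binomial sampling noise gives a
model-fit envelope for plotting against data.

The estimator is exposed as a scikit-learn style class
(:class:`MutationSelectionMLE`); module-level functions are thin wrappers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar, brentq
from scipy.special import expit, gammaln, logit
from scipy.stats import binom, chi2
from sklearn.base import BaseEstimator

from .model import ModelParams, frequency_trajectory, half_life
from .simulate import CountSeries

__all__ = [
    "EstimateResult",
    "MutationSelectionMLE",
    "neg_log_likelihood",
    "fit_mle",
    "profile_confidence_intervals",
    "likelihood_surface",
    "fit_envelope",
]

MU_BOUNDS = (1e-9, 0.5)
S_BOUNDS = (0.0, 0.95)
# chi-square(1) 95% cutoff / 2 for profile-likelihood intervals
PROFILE_CUTOFF = chi2.ppf(0.95, df=1) / 2.0


@dataclass
class EstimateResult:
    """Joint ML estimate of the loss rate and selection coefficient."""

    mu_hat: float
    s_hat: float
    nll: float
    converged: bool
    r_assumed: float
    p0_used: float
    t50_hat: float
    ci_mu: tuple[float, float] | None = None
    ci_s: tuple[float, float] | None = None
    boundary_flags: dict = field(default_factory=dict)
    engine: str = "continuous"
    n_obs: int = 0
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "engine": self.engine,
            "mu_hat": float(self.mu_hat),
            "s_hat": float(self.s_hat),
            "nll": float(self.nll),
            "converged": bool(self.converged),
            "r_assumed": float(self.r_assumed),
            "p0_used": float(self.p0_used),
            "t50_hat": float(self.t50_hat),
            "ci_mu": None if self.ci_mu is None else [float(v) for v in self.ci_mu],
            "ci_s": None if self.ci_s is None else [float(v) for v in self.ci_s],
            "boundary_flags": dict(self.boundary_flags),
            "n_obs": int(self.n_obs),
            "settings": dict(self.settings),
        }


# ---------------------------------------------------------------------------
# data plumbing


def _coerce_data(data) -> list[CountSeries]:
    """Accept a CountSeries, a list of them, or a tidy counts DataFrame."""
    if isinstance(data, CountSeries):
        return [data]
    if isinstance(data, pd.DataFrame):
        required = {"replicate", "time_h", "n_sampled", "x_engineered"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"counts table is missing columns: {sorted(missing)}")
        out = []
        for rep, grp in data.groupby("replicate", sort=False):
            grp = grp.sort_values("time_h")
            out.append(
                CountSeries(
                    replicate=str(rep),
                    t=grp["time_h"].to_numpy(float),
                    n=grp["n_sampled"].to_numpy(int),
                    x=grp["x_engineered"].to_numpy(int),
                )
            )
        return out
    data = list(data)
    if not data:
        raise ValueError("no count data provided")
    if not all(isinstance(d, CountSeries) for d in data):
        raise TypeError("expected CountSeries objects")
    return data


class _FlatCounts:
    """Pooled observations with cached binomial coefficients."""

    def __init__(self, series: list[CountSeries]):
        if not series or all(len(s) == 0 for s in series):
            raise ValueError("no count data provided")
        self.series = series
        self.t = np.concatenate([s.t for s in series])
        self.n = np.concatenate([s.n for s in series])
        self.x = np.concatenate([s.x for s in series])
        self.log_binom = gammaln(self.n + 1) - gammaln(self.x + 1) - gammaln(self.n - self.x + 1)

    def pooled_p0(self) -> float:
        """Initial frequency from the earliest sample of each replicate, pooled."""
        num = den = 0
        for s in self.series:
            j = int(np.argmin(s.t))
            num += s.x[j]
            den += s.n[j]
        return num / den


def _nll_flat(flat: _FlatCounts, mu: float, s: float, r: float, p0: float) -> float:
    p = _trajectory(mu, s, r, p0, flat.t)
    p = np.clip(p, 1e-300, 1.0 - 1e-16)
    terms = flat.log_binom + flat.x * np.log(p) + (flat.n - flat.x) * np.log1p(-p)
    return float(-np.sum(terms))


def _trajectory(mu: float, s: float, r: float, p0, t):
    # same closed form as model.frequency_trajectory, without paying for
    # dataclass validation in the optimizer's hot loop
    a = s * (1.0 - mu) + mu
    if a == 0.0:
        return np.broadcast_to(np.asarray(p0, float), np.shape(t)).copy()
    E = np.exp(-r * a * np.asarray(t, float))
    with np.errstate(invalid="ignore", divide="ignore"):
        p = p0 * a * E / (a - s * p0 * (1.0 - E))
    p = np.where(np.isnan(p), 1.0 if mu == 0.0 else 0.0, p)
    return np.clip(p, 0.0, 1.0)


def neg_log_likelihood(mu: float, s: float, r: float, p0: float, data) -> float:
    """Binomial negative log-likelihood of the counts under ``p(t)``.

    Replicates are independent and share ``(mu, s, r, p0)``, so their
    contributions add.  The binomial coefficients are computed through
    log-gamma, so large genotyped samples do not overflow.
    """
    if not 0 <= mu < 1:
        raise ValueError("mu must be in [0, 1)")
    if not 0 <= s < 1:
        raise ValueError("s must be in [0, 1)")
    if not 0 <= p0 <= 1:
        raise ValueError("p0 must be in [0, 1]")
    return _nll_flat(_FlatCounts(_coerce_data(data)), mu, s, r, p0)


# ---------------------------------------------------------------------------
# the estimator


class MutationSelectionMLE(BaseEstimator):
    """Joint ML estimator of transgene loss rate ``mu`` and selection ``s``.

    Parameters
    ----------
    r : float
        Assumed per-hour growth rate of the wild type (not estimated).
    p0_policy : {"pooled", "fixed", "free"}
        How the initial transgene frequency is handled: ``"pooled"``
        (default) fixes it at the pooled t0 sample frequency across
        replicates, ``"fixed"`` uses the value of ``p0``, ``"free"``
        estimates it as a third parameter.
    p0 : float
        Initial frequency used when ``p0_policy="fixed"``.
    n_starts : int
        Number of best coarse-grid points used to seed local optimization.
    compute_ci : bool
        If True, profile-likelihood 95% intervals are computed during fit.

    Attributes (after :meth:`fit`)
    ------------------------------
    mu_ , s_ : float
        Maximum-likelihood estimates.
    nll_ : float
        Negative log-likelihood at the optimum.
    t50_ : float
        Predicted half-life (hours) at the estimates, from a pure culture.
    result_ : EstimateResult
        Full structured result, including CIs and boundary flags.
    """

    def __init__(
        self,
        r: float = 0.1,
        p0_policy: str = "pooled",
        p0: float = 1.0,
        n_starts: int = 3,
        compute_ci: bool = False,
    ):
        self.r = r
        self.p0_policy = p0_policy
        self.p0 = p0
        self.n_starts = n_starts
        self.compute_ci = compute_ci

    # -- coordinate transforms: both parameters live on bounded intervals, so
    # optimization runs in unconstrained sigmoid-warped coordinates
    # (log10-scale for mu, logit for s).

    @staticmethod
    def _to_mu(y):
        lo, hi = np.log10(MU_BOUNDS[0]), np.log10(MU_BOUNDS[1])
        return 10.0 ** (lo + (hi - lo) * expit(y))

    @staticmethod
    def _from_mu(mu):
        lo, hi = np.log10(MU_BOUNDS[0]), np.log10(MU_BOUNDS[1])
        z = (np.log10(mu) - lo) / (hi - lo)
        return logit(np.clip(z, 1e-12, 1 - 1e-12))

    @staticmethod
    def _to_s(y):
        return S_BOUNDS[1] * expit(y)

    @staticmethod
    def _from_s(s):
        return logit(np.clip(s / S_BOUNDS[1], 1e-12, 1 - 1e-12))

    def _resolve_p0(self, flat: _FlatCounts) -> float | None:
        if self.p0_policy == "pooled":
            return flat.pooled_p0()
        if self.p0_policy == "fixed":
            return float(self.p0)
        if self.p0_policy == "free":
            return None
        raise ValueError(f"unknown p0_policy {self.p0_policy!r}")

    def fit(self, X, y=None):
        """Fit the estimator to count data (CountSeries list or tidy DataFrame)."""
        series = _coerce_data(X)
        flat = _FlatCounts(series)
        times_past_t0 = {float(t) for s in series for t in s.t[1:]}
        if len(times_past_t0) < 2:
            raise ValueError("need at least two distinct sampling times beyond t0")
        p0_fixed = self._resolve_p0(flat)
        free_p0 = p0_fixed is None
        p0_start = flat.pooled_p0() if free_p0 else p0_fixed

        def objective(y):
            mu, s = self._to_mu(y[0]), self._to_s(y[1])
            p0 = expit(y[2]) if free_p0 else p0_fixed
            return _nll_flat(flat, mu, s, self.r, p0)

        # coarse 5x5 multistart grid, log-spaced in both parameters
        mu_grid = np.logspace(-7, -1, 5)
        s_grid = np.logspace(np.log10(0.005), np.log10(0.5), 5)
        starts = []
        for m in mu_grid:
            for sv in s_grid:
                y = [self._from_mu(m), self._from_s(sv)]
                if free_p0:
                    y.append(float(logit(np.clip(p0_start, 1e-6, 1 - 1e-6))))
                starts.append((objective(y), y))
        starts.sort(key=lambda z: z[0])

        best = None
        converged = False
        for _, y0 in starts[: self.n_starts]:
            res = minimize(
                objective,
                y0,
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
            )
            if best is None or res.fun < best.fun:
                best = res
            converged = converged or bool(res.success)

        mu_hat = float(self._to_mu(best.x[0]))
        s_hat = float(self._to_s(best.x[1]))
        p0_used = float(expit(best.x[2])) if free_p0 else float(p0_fixed)

        flags = {
            "mu_at_lower": bool(mu_hat <= MU_BOUNDS[0] * 1.1),
            "mu_at_upper": bool(mu_hat >= MU_BOUNDS[1] * 0.999),
            "s_at_lower": bool(s_hat <= 1e-6),
            "s_at_upper": bool(s_hat >= S_BOUNDS[1] * 0.999),
        }
        if bool(np.all(flat.x == flat.n)):
            # no loss ever observed: mu pinned at its lower bound, s carries
            # no information (p(t) = 1 for every s when mu = 0, p0 = 1)
            flags["mu_at_lower"] = True
            flags["s_unidentifiable"] = True
            mu_hat = MU_BOUNDS[0]
            converged = True

        try:
            t50_hat = half_life(ModelParams(r=self.r, s=s_hat, mu=mu_hat))
        except ValueError:
            t50_hat = np.inf

        self.mu_ = mu_hat
        self.s_ = s_hat
        self.nll_ = float(_nll_flat(flat, mu_hat, s_hat, self.r, p0_used))
        self.p0_ = p0_used
        self.converged_ = converged
        self._flat = flat
        self.result_ = EstimateResult(
            mu_hat=mu_hat,
            s_hat=s_hat,
            nll=self.nll_,
            converged=converged,
            r_assumed=self.r,
            p0_used=p0_used,
            t50_hat=float(t50_hat),
            boundary_flags=flags,
            engine="continuous",
            n_obs=len(flat.t),
            settings={"p0_policy": self.p0_policy, "n_starts": self.n_starts},
        )
        if self.compute_ci:
            self.result_ = profile_confidence_intervals(series, self.r, self.result_)
        self.ci_mu_ = self.result_.ci_mu
        self.ci_s_ = self.result_.ci_s
        self.t50_ = self.result_.t50_hat
        return self

    def predict(self, t):
        """Expected transgene frequency at hours ``t`` under the fitted model."""
        if not hasattr(self, "mu_"):
            raise AttributeError("estimator is not fitted")
        return _trajectory(self.mu_, self.s_, self.r, self.p0_, np.asarray(t, float))


def fit_mle(
    data,
    r: float,
    p0_policy: str = "pooled",
    p0: float = 1.0,
    compute_ci: bool = False,
) -> EstimateResult:
    """Fit the continuous-time ML estimator; thin wrapper over :class:`MutationSelectionMLE`."""
    est = MutationSelectionMLE(r=r, p0_policy=p0_policy, p0=p0, compute_ci=compute_ci)
    est.fit(data)
    return est.result_


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals


def _profile_mu(flat: _FlatCounts, r: float, p0: float, mu: float, s_start: float) -> float:
    """NLL minimized over s at fixed mu."""
    def f(y):
        return _nll_flat(flat, mu, MutationSelectionMLE._to_s(y), r, p0)

    res = minimize_scalar(f, bracket=None, bounds=(-40.0, 40.0), method="bounded",
                          options={"xatol": 1e-7})
    return min(res.fun, f(MutationSelectionMLE._from_s(max(s_start, 1e-10))))


def _profile_s(flat: _FlatCounts, r: float, p0: float, s: float, mu_start: float) -> float:
    """NLL minimized over mu at fixed s."""
    def f(y):
        return _nll_flat(flat, MutationSelectionMLE._to_mu(y), s, r, p0)

    res = minimize_scalar(f, bounds=(-40.0, 40.0), method="bounded", options={"xatol": 1e-7})
    return min(res.fun, f(MutationSelectionMLE._from_mu(mu_start)))


def _profile_interval(profile, theta_hat, nll_min, lo, hi, step, to_theta, from_theta):
    """Bisection for the two crossings of profile(theta) = nll_min + cutoff.

    Works in a transformed coordinate (``from_theta``/``to_theta``); expands
    outward from the estimate in increments of ``step`` until the cutoff is
    exceeded or the bound is hit (endpoint clipped, flagged).
    """
    target = nll_min + PROFILE_CUTOFF
    z_hat = from_theta(theta_hat)
    out = []
    clipped = []
    for direction, z_bound in ((-1.0, lo), (1.0, hi)):
        z_in = z_hat
        crossed = None
        z = z_hat
        while True:
            z = z + direction * step
            if (direction < 0 and z <= z_bound) or (direction > 0 and z >= z_bound):
                z = z_bound
            val = profile(to_theta(z))
            if val >= target:
                crossed = z
                break
            z_in = z
            if z == z_bound:
                break
        if crossed is None:
            out.append(to_theta(z_bound))
            clipped.append(True)
        else:
            g = lambda zz: profile(to_theta(zz)) - target
            a, b = sorted((z_in, crossed))
            try:
                root = brentq(g, a, b, xtol=1e-6, rtol=1e-8)
            except ValueError:
                root = crossed
            out.append(to_theta(root))
            clipped.append(False)
    return (out[0], out[1]), clipped


def profile_confidence_intervals(data, r: float, fit: EstimateResult) -> EstimateResult:
    """Approximate 95% profile-likelihood intervals for ``mu`` and ``s``.

    A parameter value is inside its interval when the NLL, re-optimized over
    the other parameter, lies within ``chi2(1, 0.95)/2 = 1.92`` of the
    minimum.  Endpoints that run into the parameter bounds are clipped there
    and flagged (``ci_mu_clipped`` / ``ci_s_clipped``).
    """
    flat = _FlatCounts(_coerce_data(data))
    p0 = fit.p0_used
    nll_min = fit.nll

    ci_mu, clip_mu = _profile_interval(
        profile=lambda m: _profile_mu(flat, r, p0, m, fit.s_hat),
        theta_hat=max(fit.mu_hat, MU_BOUNDS[0]),
        nll_min=nll_min,
        lo=np.log10(MU_BOUNDS[0]),
        hi=np.log10(MU_BOUNDS[1]),
        step=0.2,
        to_theta=lambda z: 10.0 ** z,
        from_theta=np.log10,
    )
    ci_s, clip_s = _profile_interval(
        profile=lambda sv: _profile_s(flat, r, p0, sv, fit.mu_hat),
        theta_hat=float(np.clip(fit.s_hat, 9.5e-9, S_BOUNDS[1] * (1 - 1e-9))),
        nll_min=nll_min,
        lo=float(logit(1e-8 / S_BOUNDS[1])),
        hi=float(logit(1.0 - 1e-8)),
        step=0.5,
        to_theta=lambda z: S_BOUNDS[1] * expit(z),
        from_theta=lambda sv: float(logit(sv / S_BOUNDS[1])),
    )
    # a clipped lower endpoint at the numerical floor means "0" scientifically
    ci_s = (0.0 if clip_s[0] else ci_s[0], ci_s[1])

    fit.ci_mu = (float(ci_mu[0]), float(ci_mu[1]))
    fit.ci_s = (float(ci_s[0]), float(ci_s[1]))
    fit.boundary_flags["ci_mu_clipped"] = clip_mu
    fit.boundary_flags["ci_s_clipped"] = clip_s
    return fit


# ---------------------------------------------------------------------------
# surfaces and envelopes


def likelihood_surface(
    data,
    r: float,
    mu_grid=None,
    s_grid=None,
    p0_policy: str = "pooled",
    p0: float = 1.0,
) -> pd.DataFrame:
    """Exhaustive NLL evaluation on a (mu, s) grid, long-format.

    Defaults to 50 log-spaced mu values over the optimization range and 40
    linear s values; returns a DataFrame with columns ``mu``, ``s``, ``nll``.
    """
    series = _coerce_data(data)
    flat = _FlatCounts(series)
    if p0_policy == "pooled":
        p0_val = flat.pooled_p0()
    elif p0_policy == "fixed":
        p0_val = p0
    else:
        raise ValueError("likelihood_surface supports p0_policy 'pooled' or 'fixed'")
    if mu_grid is None:
        mu_grid = np.logspace(np.log10(MU_BOUNDS[0]), np.log10(MU_BOUNDS[1]), 50)
    if s_grid is None:
        s_grid = np.linspace(S_BOUNDS[0], S_BOUNDS[1], 40)
    rows = [
        (m, sv, _nll_flat(flat, float(m), float(sv), r, p0_val))
        for m in np.asarray(mu_grid)
        for sv in np.asarray(s_grid)
    ]
    return pd.DataFrame(rows, columns=["mu", "s", "nll"])


def fit_envelope(fit: EstimateResult, times, n, level: float = 0.95) -> pd.DataFrame:
    """Central binomial interval of the sampled frequency at each time point.

    Assuming the ML estimates are true, the genotyped frequency ``x/n`` at
    time ``t_j`` is ``Binomial(n_j, p_hat(t_j)) / n_j``; the envelope is its
    equal-tail ``level`` interval.  Columns: ``time_h``, ``n``, ``p_hat``,
    ``lower``, ``upper``.
    """
    times = np.asarray(times, dtype=float)
    n = np.broadcast_to(np.asarray(n, dtype=int), times.shape)
    p = _trajectory(fit.mu_hat, fit.s_hat, fit.r_assumed, fit.p0_used, times)
    alpha = (1.0 - level) / 2.0
    lower = binom.ppf(alpha, n, p) / n
    upper = binom.ppf(1.0 - alpha, n, p) / n
    return pd.DataFrame(
        {"time_h": times, "n": n, "p_hat": p, "lower": lower, "upper": upper}
    )
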