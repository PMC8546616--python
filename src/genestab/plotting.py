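"""Optional matplotlib figures: trajectory fits, surfaces, gain contours, recovery scatter.

All functions return the Figure and never show it; saving is the caller's
choice.  Numeric outputs of the package never depend on this module.
"""
from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

__all__ = [
    "plot_fit_envelope",
    "plot_likelihood_surface",
    "plot_gain_contours",
    "plot_recovery",
]


def plot_fit_envelope(series, envelope, ax=None):
    """Observed frequencies with the fitted curve and its binomial envelope."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(envelope["time_h"], envelope["lower"], envelope["upper"],
                    color="0.8", label="95% sampling envelope")
    ax.plot(envelope["time_h"], envelope["p_hat"], color="tab:blue", label="model fit")
    for s in series:
        ax.plot(s.t, s.frequency, "o", ms=4, alpha=0.8, label=s.replicate)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("transgene frequency")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    return ax.figure


def plot_likelihood_surface(surface, ax=None):
    """Filled contours of the NLL over (mu, s)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    piv = surface.pivot(index="s", columns="mu", values="nll")
    nll = piv.to_numpy()
    cs = ax.contourf(piv.columns.to_numpy(), piv.index.to_numpy(),
                     nll - np.nanmin(nll), levels=20)
    ax.set_xscale("log")
    ax.set_xlabel(r"$\mu$")
    ax.set_ylabel("s")
    ax.figure.colorbar(cs, ax=ax, label=r"$\Delta$ NLL")
    return ax.figure


def plot_gain_contours(grid, ax=None):
    """Contours of the t50 gain ratio over reduction factors (k_mu, k_s)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    piv = grid.pivot(index="k_s", columns="k_mu", values="ratio")
    cs = ax.contour(piv.columns.to_numpy(), piv.index.to_numpy(), piv.to_numpy(),
                    levels=10, colors="k", linewidths=0.8)
    ax.clabel(cs, fontsize=7)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"$k_\mu$ (mutation reduced $\times$)")
    ax.set_ylabel(r"$k_s$ (selection reduced $\times$)")
    return ax.figure


def plot_recovery(report, param: str = "mu", ax=None):
    """Estimates vs truth with the 1:1 line and the fitted OLS line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    rows = report.rows[~report.rows["failed"]]
    truth = rows[f"{param}_true"].to_numpy()
    est = rows[f"{param}_hat"].to_numpy()
    ax.plot(truth, est, "o", ms=4, alpha=0.7)
    lim = np.array([0.0, max(truth.max(), est.max()) * 1.05])
    ax.plot(lim, lim, color="tab:red", label="1:1")
    summ = report.summary[param]
    ax.plot(lim, summ["intercept"] + summ["slope"] * lim, color="tab:blue",
            label=f"fit (slope {summ['slope']:.2f})")
    ax.set_xlabel(f"true {param}")
    ax.set_ylabel(f"estimated {param}")
    ax.legend(fontsize=8)
    return ax.figure
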