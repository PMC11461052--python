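"""Closed-form results in the forward-driven limit.

When every reverse rate is sent to zero, the six-state energy-relay
network admits exact expressions for the error and the proofreading
cost.  Both collapse onto a single composite variable

    x = (omega_i / omega_l) * exp(eps_p) = (hR+ / lR+) * exp(-delta_p),

the ratio of the forward production rate (pathway 1) to the forward
proofreading rate (pathway 2) for the right substrate.  The error in
this limit is

    eta(x) = [(M-1)*G_R + G_W*(1 + K*(G_R-1))] / (K*M*G_R*G_W)

with ``G_S = 1 + lS+/hS+``, ``K = 1 + kR+/kW+ = 1 + e^delta`` and
``M = 1 + mR+/mW+ = 1 + e^gamma``.  Minimizing over x gives the minimal
relay error and its argmin x*; eliminating x between eta(x) and the
forward-limit cost C(x) yields the optimal cost-error trade-off curve.
All shipped closed forms were re-derived symbolically from the factor
formula and the Kramers rates and are cross-checked against the exact
steady-state solver in the test suite (see docs/methods.md).

Shorthand throughout: ``f(u) = 1/(1 + e^u)``; the equilibrium error is
``eta_eq = f(gamma)``.
"""
from __future__ import annotations

from enum import Enum

import numpy as np
from scipy.optimize import brentq

from .networks import RateSet

__all__ = [
    "RegimeLabel",
    "fermi",
    "equilibrium_error",
    "forward_limit_error",
    "forward_limit_factors",
    "error_vs_x",
    "min_error_erpr",
    "min_error_mm",
    "min_error_kpr",
    "classify_regime",
    "cost_vs_x",
    "cost_at_equilibrium_error",
    "cost_at_min_error",
    "cost_error_curve",
]


def fermi(u):
    """Logistic shorthand ``f(u) = 1/(1 + e^u)``."""
    return 1.0 / (1.0 + np.exp(u))


def equilibrium_error(gamma: float) -> float:
    """Error from Boltzmann weights of the bound states, ``f(gamma)``."""
    return fermi(gamma)


class RegimeLabel(str, Enum):
    """Operating regime of the relay scheme, set by (gamma, delta, delta_p)."""

    ERPR = "ERPR"
    ERPR_MM = "ERPR_MM"
    MM = "MM"


def classify_regime(gamma: float, delta: float, delta_p: float) -> RegimeLabel:
    """Pure relay for delta <= gamma; mixed up to delta = 2*gamma + delta_p;
    plain Michaelis--Menten beyond."""
    if delta <= gamma:
        return RegimeLabel.ERPR
    if delta <= 2.0 * gamma + delta_p:
        return RegimeLabel.ERPR_MM
    return RegimeLabel.MM


def forward_limit_factors(rates: RateSet) -> dict[str, float]:
    """Composite factors (G_R, G_W, K, M, x) of an ERPR rate set."""
    if rates.scheme != "ERPR":
        raise ValueError("forward-limit factors are defined for the ERPR scheme")
    return {
        "Gamma_R": 1.0 + rates["lR+"] / rates["hR+"],
        "Gamma_W": 1.0 + rates["lW+"] / rates["hW+"],
        "K": 1.0 + rates["kR+"] / rates["kW+"],
        "M": 1.0 + rates["mR+"] / rates["mW+"],
        "x": rates["hR+"] / rates["lR+"] * (rates["lR-"] / rates["lW-"]),
    }


def forward_limit_error(rates: RateSet) -> float:
    """Error of the relay scheme with all reverse rates sent to zero."""
    fx = forward_limit_factors(rates)
    GR, GW, K, M = fx["Gamma_R"], fx["Gamma_W"], fx["K"], fx["M"]
    return ((M - 1.0) * GR + GW * (1.0 + K * (GR - 1.0))) / (K * M * GR * GW)


def error_vs_x(x, gamma: float, delta: float, delta_p: float):
    """Forward-limit error as a function of the composite variable x.

    Obtained by substituting the Kramers rate ratios into the factor
    formula: ``G_R = 1 + e^{-delta_p}/x`` and ``G_W = 1 + e^{gamma}/x``.
    Vectorized over x.
    """
    x = np.asarray(x, dtype=float)
    K = 1.0 + np.exp(delta)
    M = 1.0 + np.exp(gamma)
    GR = 1.0 + np.exp(-delta_p) / x
    GW = 1.0 + np.exp(gamma) / x
    eta = ((M - 1.0) * GR + GW * (1.0 + K * (GR - 1.0))) / (K * M * GR * GW)
    return eta if eta.shape else float(eta)


def min_error_mm(gamma: float, delta: float) -> float:
    """Minimal Michaelis--Menten error, ``f(max(delta, gamma))``."""
    return fermi(max(delta, gamma))


def min_error_kpr(gamma: float, delta: float, delta_p: float) -> float:
    """Minimal kinetic-proofreading error, ``f(max(delta,gamma) + gamma + delta_p)``."""
    return fermi(max(delta, gamma) + gamma + delta_p)


def _x_star(gamma: float, delta: float, delta_p: float) -> float:
    num = np.exp(delta / 2.0) - np.exp(-delta_p / 2.0)
    den = np.exp(delta_p / 2.0) - np.exp(delta / 2.0 - gamma)
    with np.errstate(divide="ignore"):
        return num / den if den != 0 else float("inf")


def min_error_erpr(gamma: float, delta: float, delta_p: float) -> tuple[float, float]:
    """Minimal relay error and its argmin x*.

    Closed form (symbolically re-derived from the factor formula):

        eta_E = f(gamma) f(delta) *
                (e^{g+dp} + 2 e^{g+(d+dp)/2} - 1 - e^g - e^d) / (e^{g+dp} - 1)
        x*    = (e^{d/2} - e^{-dp/2}) / (e^{dp/2} - e^{d/2-g}).

    On and beyond the boundary ``delta >= 2*gamma + delta_p`` the argmin
    escapes to infinity and the scheme reduces to plain MM kinetics;
    then ``(f(delta), inf)`` is returned.
    """
    if delta >= 2.0 * gamma + delta_p:
        return fermi(delta), float("inf")
    g, d, dp = gamma, delta, delta_p
    num = np.exp(g + dp) + 2.0 * np.exp(g + (d + dp) / 2.0) - (1.0 + np.exp(g) + np.exp(d))
    den = np.exp(g + dp) - 1.0
    if den <= 0:  # gamma = delta_p = 0: relay cannot beat equilibrium
        return fermi(g), 0.0
    eta_E = fermi(g) * fermi(d) * num / den
    return float(eta_E), float(_x_star(g, d, dp))


def cost_vs_x(x, gamma: float, delta: float, delta_p: float):
    """Forward-limit proofreading cost C(x) (pathway-2 use per product).

        C(x) = f(delta) * [1 + e^d + x (e^{d-g} + e^{dp})]
               / [(1 + x e^{dp}) (1 + x e^{-g})]

    Derived from the forward-limit fluxes: the production flux equals the
    total binding flux, and the pathway-2 flux from each high-energy
    complex is the branching fraction ``lS+/(hS+ + lS+)`` of it.
    """
    x = np.asarray(x, dtype=float)
    g, d, dp = gamma, delta, delta_p
    C = fermi(d) * (1.0 + np.exp(d) + x * (np.exp(d - g) + np.exp(dp))) / (
        (1.0 + x * np.exp(dp)) * (1.0 + x * np.exp(-g))
    )
    return C if C.shape else float(C)


def cost_at_equilibrium_error(gamma: float, delta: float, delta_p: float) -> float:
    """Optimal forward-limit cost at eta = eta_eq.

    For delta < gamma the error re-attains its equilibrium value at a
    finite x on the low-cost branch, where (symbolic elimination)

        C(eta_eq) = (e^gamma - e^delta)(1 + e^{delta_p})
                    / [(1 + e^delta)(e^{gamma+delta_p} - 1)],

    vanishing continuously at delta = gamma.  For delta >= gamma the
    optimal configuration at eta_eq uses plain MM kinetics at zero cost.
    """
    g, d, dp = gamma, delta, delta_p
    if d >= g:
        return 0.0
    return (np.exp(g) - np.exp(d)) * (1.0 + np.exp(dp)) / (
        (1.0 + np.exp(d)) * (np.exp(g + dp) - 1.0)
    )


def cost_at_min_error(gamma: float, delta: float, delta_p: float) -> float:
    """Forward-limit cost at the minimal relay error, C(x*).

        C(eta_E) = f(delta) (e^{g+dp/2} - e^{d/2})(e^{d/2} + e^{dp/2})
                   / (e^{g+dp} - 1)

    Zero exactly on the MM boundary delta = 2*gamma + delta_p (and for
    the MM regime, where the proofreading pathway is unused).
    """
    g, d, dp = gamma, delta, delta_p
    if d >= 2.0 * g + dp:
        return 0.0
    return fermi(d) * (np.exp(g + dp / 2.0) - np.exp(d / 2.0)) * (
        np.exp(d / 2.0) + np.exp(dp / 2.0)
    ) / (np.exp(g + dp) - 1.0)


def cost_error_curve(
    eta_grid, gamma: float, delta: float, delta_p: float
) -> np.ndarray:
    """Optimal cost-error trade-off C(eta) by numeric elimination of x.

    For each requested error the equation ``eta(x) = eta`` is solved on
    the low-cost branch ``x >= x*`` (where the error increases
    monotonically from eta_E towards the MM value f(delta)) and the
    forward-limit cost at that x is returned.  Errors at or above
    f(delta) are reachable by plain MM kinetics at zero cost; errors
    below eta_E are infeasible and raise ``ValueError``.
    """
    eta_grid = np.atleast_1d(np.asarray(eta_grid, dtype=float))
    eta_E, x_star = min_error_erpr(gamma, delta, delta_p)
    eta_mm = fermi(delta)
    if np.any(eta_grid < eta_E * (1.0 - 1e-12)):
        raise ValueError(f"requested error below the minimal relay error {eta_E:.6g}")
    out = np.empty_like(eta_grid)
    for k, eta in enumerate(eta_grid):
        if eta >= eta_mm or not np.isfinite(x_star):
            out[k] = 0.0
            continue
        if eta <= eta_E:
            out[k] = cost_vs_x(x_star, gamma, delta, delta_p)
            continue
        lo = np.log(x_star)
        hi = lo + 1.0
        # expand until the bracket straddles the target error
        while error_vs_x(np.exp(hi), gamma, delta, delta_p) < eta:
            hi += 1.0
            if hi > lo + 80.0:  # pragma: no cover - cannot happen for eta < f(delta)
                raise RuntimeError("failed to bracket the error on the low-cost branch")
        lx = brentq(
            lambda u: error_vs_x(np.exp(u), gamma, delta, delta_p) - eta,
            lo,
            hi,
            xtol=1e-14,
            rtol=1e-14,
        )
        out[k] = cost_vs_x(np.exp(lx), gamma, delta, delta_p)
    return out
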