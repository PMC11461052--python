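"""Kinetic and thermodynamic observables of a discrimination network.

All observables are evaluated at the steady state of a rate set:

* error rate ``eta = J_W / (J_R + J_W)`` with production fluxes
  ``J_S = F * P(productive bound state for S)``;
* dimensionless speed ``v = (J_R + J_W) / F``;
* pathway costs ``C2`` (proofreading pathway, high-energy complex to
  ground state) and ``C3`` (upcycling pathway), each a net flux per
  product; the total cost ``C2 + C3`` vanishes at steady state and the
  reported cost is ``C2``;
* entropy production rate ``sigma`` (kB per unit time), catalysis edges
  excluded, and entropy production per product ``delta_sigma = sigma/J_p``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .networks import (
    DiscriminationParams,
    GeneratorMatrix,
    RateSet,
    PRODUCTIVE_STATES,
    build_rates,
    generator_matrix,
    steady_state,
    topology,
)

__all__ = [
    "Observables",
    "UndefinedObservableError",
    "production_fluxes",
    "error_rate",
    "pathway_costs",
    "speed",
    "entropy_production",
    "entropy_per_product",
    "evaluate",
]

# Fluxes below this magnitude are treated as zero (x ln x -> 0 limit).
_FLUX_FLOOR = 1e-300


class UndefinedObservableError(ZeroDivisionError):
    """An observable is undefined (e.g. zero production flux)."""


@dataclass(frozen=True)
class Observables:
    """Flat record of steady-state observables for one rate set."""

    scheme: str
    eta: float
    v: float
    C2: float
    C3: float
    sigma: float
    delta_sigma: float
    J_R: float
    J_W: float
    J_l_R: float = float("nan")
    J_l_W: float = float("nan")
    J_m_R: float = float("nan")
    J_m_W: float = float("nan")
    J_h_R: float = float("nan")
    J_h_W: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _state_index(scheme: str) -> dict[str, int]:
    states, _, _ = topology(scheme)
    return {s: k for k, s in enumerate(states)}


def production_fluxes(rates: RateSet, ss: np.ndarray) -> tuple[float, float]:
    """Steady-state production fluxes ``J_S = F * P(ES)`` for S in {R, W}."""
    idx = _state_index(rates.scheme)
    states, _, _ = topology(rates.scheme)
    if len(ss) != len(states):
        raise ValueError(
            f"distribution has {len(ss)} entries, scheme {rates.scheme} has {len(states)} states"
        )
    sR, sW = PRODUCTIVE_STATES[rates.scheme]
    return rates.F * ss[idx[sR]], rates.F * ss[idx[sW]]


def error_rate(J_R: float, J_W: float) -> float:
    """Fraction of the production flux forming the wrong product."""
    total = J_R + J_W
    if not total > 0:
        raise UndefinedObservableError("error rate undefined: zero production flux")
    return J_W / total


def speed(J_R: float, J_W: float, F: float) -> float:
    """Dimensionless production speed ``v = (J_R + J_W) / F``."""
    if not F > 0:
        raise UndefinedObservableError("speed undefined: F must be positive")
    return (J_R + J_W) / F


def _erpr_pathway_fluxes(rates: RateSet, ss: np.ndarray) -> dict[str, float]:
    idx = _state_index("ERPR")
    P = ss
    fx = {}
    for S in ("R", "W"):
        fx[f"J_l_{S}"] = rates[f"l{S}+"] * P[idx[f"E'{S}"]] - rates[f"l{S}-"] * P[idx["E"]]
        fx[f"J_m_{S}"] = rates[f"m{S}+"] * P[idx["E"]] - rates[f"m{S}-"] * P[idx[f"E{S}"]]
        fx[f"J_h_{S}"] = rates[f"h{S}+"] * P[idx[f"E'{S}"]] - rates[f"h{S}-"] * P[idx[f"E{S}"]]
    return fx


def pathway_costs(rates: RateSet, ss: np.ndarray) -> tuple[float, float]:
    """Net proofreading (C2) and upcycling (C3) pathway use per product.

    ``C2 = (J_l,R + J_l,W)/J_p`` counts how often the proofreading
    pathway discards a substrate from the high-energy complex per
    product formed; ``C3`` counts (with opposite sign) rebinding through
    the upcycling pathway.  At steady state the fluxes into the ground
    state balance, so ``C2 + C3 = 0``.
    """
    if rates.scheme != "ERPR":
        raise ValueError("pathway costs are defined for the ERPR scheme only")
    J_R, J_W = production_fluxes(rates, ss)
    J_p = J_R + J_W
    if not J_p > 0:
        raise UndefinedObservableError("pathway costs undefined: zero production flux")
    fx = _erpr_pathway_fluxes(rates, ss)
    C2 = (fx["J_l_R"] + fx["J_l_W"]) / J_p
    C3 = -(fx["J_m_R"] + fx["J_m_W"]) / J_p
    return C2, C3


def entropy_production(rates: RateSet, ss: np.ndarray) -> float:
    """Steady-state entropy production rate, catalysis edges excluded.

    ``sigma = sum over reversible edges of (k_ij P_i - k_ji P_j) *
    ln(k_ij P_i / (k_ji P_j))`` which is non-negative term by term.  An
    included edge with a strictly zero rate on one side but non-zero
    flux makes sigma formally infinite; this returns ``inf`` with a
    warning rather than raising.
    """
    idx = _state_index(rates.scheme)
    _, edges, _ = topology(rates.scheme)
    sigma = 0.0
    for fwd, rev, a, b in edges:
        i, j = idx[a], idx[b]
        plus = rates[fwd] * ss[i]
        minus = rates[rev] * ss[j]
        if plus < _FLUX_FLOOR and minus < _FLUX_FLOOR:
            continue
        if plus < _FLUX_FLOOR or minus < _FLUX_FLOOR:
            warnings.warn(
                f"edge {a}<->{b} is one-way with non-zero flux: entropy production diverges",
                RuntimeWarning,
            )
            return float("inf")
        sigma += (plus - minus) * np.log(plus / minus)
    return sigma


def entropy_per_product(sigma: float, J_p: float) -> float:
    """Entropy production per catalysis step, ``delta_sigma = sigma / J_p``."""
    if not J_p > 0:
        raise UndefinedObservableError("entropy per product undefined: zero production flux")
    return sigma / J_p


def evaluate(
    params_or_rates: DiscriminationParams | RateSet,
    scheme: str | None = None,
) -> Observables:
    """Full pipeline: rates -> generator -> steady state -> observables.

    Accepts either a :class:`DiscriminationParams` (with ``scheme``) or a
    ready-made :class:`RateSet`.  This is the single entry point the
    Pareto optimizer and the CLI call.
    """
    if isinstance(params_or_rates, RateSet):
        rates = params_or_rates
    else:
        if scheme is None:
            raise ValueError("scheme is required when passing DiscriminationParams")
        rates = build_rates(params_or_rates, scheme)
    G = generator_matrix(rates)
    ss = steady_state(G)
    J_R, J_W = production_fluxes(rates, ss)
    J_p = J_R + J_W
    eta = error_rate(J_R, J_W)
    v = speed(J_R, J_W, rates.F)
    sigma = entropy_production(rates, ss)
    dsig = entropy_per_product(sigma, J_p)
    extra: dict[str, float] = {}
    if rates.scheme == "ERPR":
        C2, C3 = pathway_costs(rates, ss)
        extra = _erpr_pathway_fluxes(rates, ss)
    elif rates.scheme == "KPR":
        # Net discard flux per product through the futile proofreading
        # transition ES* -> E + S, the conventional proofreading cost.
        idx = _state_index("KPR")
        J_K = sum(
            rates[f"K{S}+"] * ss[idx[f"E*{S}"]] - rates[f"K{S}-"] * ss[idx["E"]]
            for S in ("R", "W")
        )
        C2, C3 = J_K / J_p, float("nan")
    else:
        C2, C3 = 0.0, 0.0
    return Observables(
        scheme=rates.scheme,
        eta=eta,
        v=v,
        C2=C2,
        C3=C3,
        sigma=sigma,
        delta_sigma=dsig,
        J_R=J_R,
        J_W=J_W,
        **extra,
    )
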