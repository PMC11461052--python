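"""Reaction networks for enzymatic substrate discrimination.

Three schemes are supported, all with a right (R) and a wrong (W)
substrate competing for the same enzyme:

``MM``
    Plain Michaelis--Menten discrimination, ``E <-> ES -> E + P``.
``KPR``
    Classical kinetic proofreading: an activated complex ``ES*`` is
    reached from ``ES`` and can either form product or discard the
    substrate through a futile proofreading transition ``ES* <-> E + S``.
``ERPR``
    Energy-relay proofreading: the energy released by the previous
    catalysis step leaves the enzyme in a metastable high-energy state
    ``E'``; proofreading proceeds from the high-energy bound complex
    ``E'S`` down to the enzymatic ground state ``E`` without any external
    fuel molecule being hydrolysed.

Rates follow a Kramers parametrization over a free-energy landscape with
three discrimination parameters (all in units of kBT): ``gamma`` (binding
energy gap between right and wrong bound states), ``delta`` (initial
kinetic barrier gap, in the forward binding rates) and ``delta_p``
(proofreading barrier gap).  Substrate and product concentrations are
chemostatted and absorbed into the rates.  Catalysis is unidirectional
with rate ``F``, identical for both substrates.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

__all__ = [
    "SCHEMES",
    "DiscriminationParams",
    "RateSet",
    "GeneratorMatrix",
    "DegenerateNetworkError",
    "build_erpr_rates",
    "build_kpr_rates",
    "build_mm_rates",
    "build_rates",
    "generator_matrix",
    "steady_state",
    "topology",
]

SCHEMES = ("MM", "KPR", "ERPR")

# State ordering is fixed so that serialized distributions are comparable
# across runs.
ERPR_STATES = ("E'", "E'R", "E'W", "ER", "EW", "E")
KPR_STATES = ("E", "ER", "EW", "E*R", "E*W")
MM_STATES = ("E", "ER", "EW")

# Reversible edges: (forward rate, reverse rate, from-state, to-state).
ERPR_EDGES = (
    ("kR+", "kR-", "E'", "E'R"),
    ("kW+", "kW-", "E'", "E'W"),
    ("hR+", "hR-", "E'R", "ER"),
    ("hW+", "hW-", "E'W", "EW"),
    ("lR+", "lR-", "E'R", "E"),
    ("lW+", "lW-", "E'W", "E"),
    ("mR+", "mR-", "E", "ER"),
    ("mW+", "mW-", "E", "EW"),
)
KPR_EDGES = (
    ("kR+", "kR-", "E", "ER"),
    ("kW+", "kW-", "E", "EW"),
    ("hR+", "hR-", "ER", "E*R"),
    ("hW+", "hW-", "EW", "E*W"),
    ("KR+", "KR-", "E*R", "E"),
    ("KW+", "KW-", "E*W", "E"),
)
MM_EDGES = (
    ("kR+", "kR-", "E", "ER"),
    ("kW+", "kW-", "E", "EW"),
)

# Unidirectional catalysis edges (rate F), flagged so they can be
# excluded from the entropy production.
ERPR_CATALYSIS = (("ER", "E'"), ("EW", "E'"))
KPR_CATALYSIS = (("E*R", "E"), ("E*W", "E"))
MM_CATALYSIS = (("ER", "E"), ("EW", "E"))

_TOPOLOGY = {
    "ERPR": (ERPR_STATES, ERPR_EDGES, ERPR_CATALYSIS),
    "KPR": (KPR_STATES, KPR_EDGES, KPR_CATALYSIS),
    "MM": (MM_STATES, MM_EDGES, MM_CATALYSIS),
}

# States whose catalysis transition produces product, per scheme.
PRODUCTIVE_STATES = {
    "ERPR": ("ER", "EW"),
    "KPR": ("E*R", "E*W"),
    "MM": ("ER", "EW"),
}


def topology(scheme: str):
    """Return ``(states, reversible_edges, catalysis_edges)`` for a scheme."""
    try:
        return _TOPOLOGY[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


class DegenerateNetworkError(np.linalg.LinAlgError):
    """The generator has more than one (numerical) null dimension."""


@dataclass(frozen=True)
class DiscriminationParams:
    """Energies, barriers and kinetic prefactors defining one network.

    All energies are in units of kBT; frequencies and ``F`` are in units
    of inverse time (the base attempt frequency ``omega`` sets the time
    scale and is conventionally 1).

    Parameters
    ----------
    gamma : energetic discrimination (binding-energy gap).
    delta : initial kinetic discrimination (binding barrier gap), >= 0.
    delta_p : proofreading kinetic discrimination, >= 0.
    eps : binding energy scale of the first binding step.
    omega, omega_i, omega_l, omega_m : attempt frequencies of the
        binding (k), internal (h), proofreading (l) and upcycling (m)
        transitions.
    eps_i, eps_p : internal energies of the bound states relative to the
        enzymatic ground state.
    F : unidirectional catalysis rate, equal for both substrates.
    """

    gamma: float = 2.0
    delta: float = 1.0
    delta_p: float = 1.0
    eps: float = 5.0
    omega: float = 1.0
    omega_i: float = 1.0
    omega_l: float = 1.0
    omega_m: float = 1.0
    eps_i: float = 5.0
    eps_p: float = 2.0
    F: float = 1.0

    def __post_init__(self) -> None:
        for name in ("omega", "omega_i", "omega_l", "omega_m", "F"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.delta < 0 or self.delta_p < 0:
            raise ValueError("delta and delta_p must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class RateSet:
    """Named per-edge rate constants for one scheme, plus catalysis rate F.

    Rates must be non-negative; zero rates are permitted so that limits
    (e.g. the forward-driven limit, or a disabled proofreading pathway)
    can be represented, but the generic steady state requires an
    irreducible network.
    """

    scheme: str
    rates: Mapping[str, float]
    F: float

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        _, edges, _ = _TOPOLOGY[self.scheme]
        names = {n for e in edges for n in e[:2]}
        missing = names - set(self.rates)
        if missing:
            raise ValueError(f"missing rates for scheme {self.scheme}: {sorted(missing)}")
        for name in names:
            if self.rates[name] < 0:
                raise ValueError(f"rate {name} must be non-negative")
        if self.F < 0:
            raise ValueError("F must be non-negative")

    def __getitem__(self, name: str) -> float:
        return self.rates[name]

    def scaled_reverse(self, factor: float) -> "RateSet":
        """Return a copy with every reverse rate multiplied by ``factor``.

        Used to approach the forward-driven limit numerically.
        """
        new = dict(self.rates)
        _, edges, _ = _TOPOLOGY[self.scheme]
        for _, rev, _, _ in edges:
            new[rev] = new[rev] * factor
        return RateSet(self.scheme, new, self.F)


@dataclass(frozen=True)
class GeneratorMatrix:
    """Markov generator of a scheme, with catalysis edges tagged.

    ``matrix[j, i]`` is the rate of the ``i -> j`` transition; columns
    sum to zero (probability conservation).
    """

    matrix: np.ndarray
    states: tuple[str, ...]
    catalysis: tuple[tuple[int, int], ...]  # (from_index, to_index)
    scheme: str

    @property
    def n_states(self) -> int:
        return len(self.states)


def build_erpr_rates(params: DiscriminationParams) -> RateSet:
    """Kramers rates of the six-state energy-relay network.

    Binding (k) into the high-energy complex carries the initial kinetic
    discrimination ``delta`` in the forward direction and the energetic
    discrimination ``gamma`` in the wrong unbinding rate; the internal
    relaxation (h) is substrate-blind; proofreading (l) from ``E'S`` to
    the ground state carries ``delta_p``; upcycling (m) rebinds the
    substrate from the ground state.
    """
    p = params
    e = np.exp
    rates = {
        "kR+": p.omega * e(p.eps + p.delta),
        "kR-": p.omega * e(p.delta),
        "kW+": p.omega * e(p.eps),
        "kW-": p.omega * e(p.gamma),
        "hR+": p.omega_i * e(p.eps_i),
        "hR-": p.omega_i,
        "hW+": p.omega_i * e(p.eps_i),
        "hW-": p.omega_i,
        "lR+": p.omega_l * e(p.eps_i - p.eps_p - p.delta_p),
        "lR-": p.omega_l * e(-p.delta_p),
        "lW+": p.omega_l * e(p.eps_i - p.eps_p + p.gamma),
        "lW-": p.omega_l,
        "mR+": p.omega_m * e(p.eps_p),
        "mR-": p.omega_m,
        "mW+": p.omega_m * e(p.eps_p - p.gamma),
        "mW-": p.omega_m,
    }
    return RateSet("ERPR", rates, p.F)


def build_kpr_rates(params: DiscriminationParams) -> RateSet:
    """Five-state kinetic-proofreading network.

    Binding (k) and internal activation (h) are identical to the
    energy-relay parametrization; the proofreading transition
    ``ES* <-> E + S`` mirrors the relay's l-rates but acts from the
    activated bound state, and catalysis proceeds from ``ES*`` back to
    the single unbound state ``E``.  The ordering constraint
    ``eps_p <= eps_i`` is deliberately not applied here.
    """
    p = params
    e = np.exp
    rates = {
        "kR+": p.omega * e(p.eps + p.delta),
        "kR-": p.omega * e(p.delta),
        "kW+": p.omega * e(p.eps),
        "kW-": p.omega * e(p.gamma),
        "hR+": p.omega_i * e(p.eps_i),
        "hR-": p.omega_i,
        "hW+": p.omega_i * e(p.eps_i),
        "hW-": p.omega_i,
        "KR+": p.omega_l * e(p.eps_p - p.delta_p),
        "KR-": p.omega_l * e(-p.delta_p),
        "KW+": p.omega_l * e(p.eps_p + p.gamma),
        "KW-": p.omega_l,
    }
    return RateSet("KPR", rates, p.F)


def build_mm_rates(params: DiscriminationParams) -> RateSet:
    """Three-state Michaelis--Menten network ``E <-> ES -> E + P``."""
    p = params
    e = np.exp
    rates = {
        "kR+": p.omega * e(p.eps + p.delta),
        "kR-": p.omega * e(p.delta),
        "kW+": p.omega * e(p.eps),
        "kW-": p.omega * e(p.gamma),
    }
    return RateSet("MM", rates, p.F)


_BUILDERS = {"ERPR": build_erpr_rates, "KPR": build_kpr_rates, "MM": build_mm_rates}


def build_rates(params: DiscriminationParams, scheme: str) -> RateSet:
    """Dispatch to the scheme-specific rate builder."""
    try:
        builder = _BUILDERS[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    return builder(params)


def generator_matrix(rates: RateSet) -> GeneratorMatrix:
    """Assemble the Markov generator of a rate set.

    Off-diagonal entry ``(j, i)`` holds the total ``i -> j`` rate
    (reversible edge plus, where present, the catalysis rate); diagonal
    entries make every column sum to zero.
    """
    states, edges, catalysis = _TOPOLOGY[rates.scheme]
    idx = {s: k for k, s in enumerate(states)}
    n = len(states)
    G = np.zeros((n, n))
    for fwd, rev, a, b in edges:
        i, j = idx[a], idx[b]
        G[j, i] += rates[fwd]
        G[i, j] += rates[rev]
    cat_idx = []
    for a, b in catalysis:
        i, j = idx[a], idx[b]
        G[j, i] += rates.F
        cat_idx.append((i, j))
    np.fill_diagonal(G, 0.0)
    G -= np.diag(G.sum(axis=0))
    return GeneratorMatrix(G, tuple(states), tuple(cat_idx), rates.scheme)


def steady_state(G: GeneratorMatrix, rtol: float = 1e-10) -> np.ndarray:
    """Null vector of the generator (the steady state), normalized to 1.

    Solved by GTH state reduction on the jump-rate matrix: the
    elimination involves only sums, products and quotients of
    non-negative numbers, so every component of the distribution is
    accurate in a relative sense even when the rates span many decades
    (a plain equilibrated nullspace solve loses the small occupancies to
    cancellation).  A rank check on the equilibrated generator raises
    :class:`DegenerateNetworkError` for reducible networks, and the
    residual ``||G p||_inf < rtol * max_rate`` is verified afterwards.
    """
    A = np.asarray(G.matrix, dtype=float)
    n = A.shape[0]
    scale = np.abs(A).max(axis=1)
    scale[scale == 0] = 1.0
    sv = np.linalg.svd(A / scale[:, None], compute_uv=False)
    if sv[-2] <= 1e-12 * sv[0]:
        raise DegenerateNetworkError(
            "generator null space is more than one-dimensional"
        )
    # GTH elimination on W[i, j] = rate i -> j
    W = A.T.copy()
    np.fill_diagonal(W, 0.0)
    S = np.zeros(n)
    for k in range(n - 1, 0, -1):
        S[k] = W[k, :k].sum()
        if not S[k] > 0:
            raise DegenerateNetworkError(f"state {k} cannot reach the reduced chain")
        W[:k, :k] += np.outer(W[:k, k], W[k, :k] / S[k])
    p = np.zeros(n)
    p[0] = 1.0
    for k in range(1, n):
        p[k] = (p[:k] * W[:k, k]).sum() / S[k]
    p = p / p.sum()
    max_rate = np.abs(A).max()
    residual = np.abs(A @ p).max()
    if not residual < rtol * max_rate:
        raise DegenerateNetworkError(
            f"steady-state residual {residual:.3e} exceeds {rtol:.1e} * max rate"
        )
    return p
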