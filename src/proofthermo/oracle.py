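"""Stochastic-simulation oracle and random-instance generators.

The exact steady-state machinery in :mod:`proofthermo.networks` and
:mod:`proofthermo.observables` is validated against an independent
event-driven continuous-time Markov-chain simulation: occupancies come
from dwell times, the error and costs come from *event counts* (how
often catalysis fires for each substrate, how often the proofreading
pathway is traversed per product), so the flux-based definitions are
tested against genuinely different estimators.  Standard errors use
batch means over contiguous event batches.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .networks import (
    DiscriminationParams,
    RateSet,
    build_rates,
    generator_matrix,
    topology,
)
from .observables import Observables, entropy_production

__all__ = [
    "TrajectoryStats",
    "simulate",
    "empirical_observables",
    "random_rate_set",
    "random_params",
    "sample_rate_sets",
]


@dataclass(frozen=True)
class TrajectoryStats:
    """Dwell times and transition counts of one simulated trajectory."""

    scheme: str
    states: tuple[str, ...]
    total_time: float
    occupancy_time: np.ndarray  # (n,)
    counts: np.ndarray  # (n, n) int64, counts[i, j] = number of i->j jumps
    batch_time: np.ndarray  # (B,)
    batch_occupancy: np.ndarray  # (B, n)
    batch_counts: np.ndarray  # (B, n, n)
    seed: int
    n_events: int


@njit(cache=True)
def _gillespie_core(Q, n_events, seed, n_batches, start):  # pragma: no cover - numba
    n = Q.shape[0]
    exit_rate = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                exit_rate[i] += Q[i, j]
    np.random.seed(seed)
    occ = np.zeros((n_batches, n))
    counts = np.zeros((n_batches, n, n), dtype=np.int64)
    btime = np.zeros(n_batches)
    per_batch = n_events // n_batches
    state = start
    for ev in range(n_events):
        b = min(ev // per_batch, n_batches - 1)
        r = exit_rate[state]
        if r <= 0.0:
            return occ, counts, btime, -1  # absorbing state
        dt = -np.log(np.random.random()) / r
        occ[b, state] += dt
        btime[b] += dt
        u = np.random.random() * r
        acc = 0.0
        nxt = state
        for j in range(n):
            if j == state:
                continue
            acc += Q[state, j]
            if u < acc:
                nxt = j
                break
        counts[b, state, nxt] += 1
        state = nxt
    return occ, counts, btime, 0


def simulate(
    rates: RateSet, n_events: int, seed: int, n_batches: int = 20, start: int = 0
) -> TrajectoryStats:
    """Exact CTMC trajectory of ``n_events`` jumps (direct Gillespie sampling)."""
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if n_batches < 1 or n_batches > n_events:
        raise ValueError("need 1 <= n_batches <= n_events")
    G = generator_matrix(rates)
    Q = G.matrix.T.copy()  # Q[i, j] = rate i -> j
    np.fill_diagonal(Q, 0.0)
    occ, counts, btime, status = _gillespie_core(Q, n_events, seed, n_batches, start)
    if status != 0:
        raise RuntimeError("trajectory reached an absorbing state")
    return TrajectoryStats(
        scheme=rates.scheme,
        states=G.states,
        total_time=float(btime.sum()),
        occupancy_time=occ.sum(axis=0),
        counts=counts.sum(axis=0),
        batch_time=btime,
        batch_occupancy=occ,
        batch_counts=counts,
        seed=seed,
        n_events=n_events,
    )


def _catalysis_pairs(scheme: str) -> list[tuple[int, int, str]]:
    states, _, catalysis = topology(scheme)
    idx = {s: k for k, s in enumerate(states)}
    out = []
    for a, b in catalysis:
        substrate = "R" if "R" in a else "W"
        out.append((idx[a], idx[b], substrate))
    return out


def empirical_observables(
    stats: TrajectoryStats, rates: RateSet
) -> tuple[Observables, dict[str, float]]:
    """Event-count observables with batch-means standard errors.

    The error rate uses catalysis event counts per substrate, the speed
    uses catalysis events per unit time over F, and (for the relay
    scheme) C2/C3 use net pathway traversal counts per product.  The
    entropy production rate is evaluated from the empirical occupancies.
    Returns ``(observables, standard_errors)`` where the standard errors
    cover ``eta``, ``v`` and ``C2``.
    """
    if stats.scheme != rates.scheme:
        raise ValueError("trajectory and rate set belong to different schemes")
    states = stats.states
    idx = {s: k for k, s in enumerate(states)}
    cat = _catalysis_pairs(stats.scheme)

    def _per_batch(counts, time):
        n_cat = {"R": 0, "W": 0}
        for i, j, S in cat:
            n_cat[S] += counts[i, j]
        total = n_cat["R"] + n_cat["W"]
        eta = n_cat["W"] / total if total else np.nan
        v = (total / time) / rates.F if time > 0 else np.nan
        if stats.scheme == "ERPR":
            net_l = sum(
                counts[idx[f"E'{S}"], idx["E"]] - counts[idx["E"], idx[f"E'{S}"]]
                for S in ("R", "W")
            )
            net_m = sum(
                counts[idx["E"], idx[f"E{S}"]] - counts[idx[f"E{S}"], idx["E"]]
                for S in ("R", "W")
            )
            C2 = net_l / total if total else np.nan
            C3 = -net_m / total if total else np.nan
        else:
            C2 = C3 = np.nan
        return eta, v, C2, C3, n_cat["R"], n_cat["W"]

    eta, v, C2, C3, ncr, ncw = _per_batch(stats.counts, stats.total_time)
    B = stats.batch_counts.shape[0]
    batch_vals = np.array(
        [_per_batch(stats.batch_counts[b], stats.batch_time[b])[:4] for b in range(B)]
    )
    with np.errstate(invalid="ignore"):
        se = np.nanstd(batch_vals, axis=0, ddof=1) / np.sqrt(B)
    stderr = {"eta": se[0], "v": se[1], "C2": se[2], "C3": se[3]}

    p_emp = stats.occupancy_time / stats.total_time
    sigma = entropy_production(rates, p_emp)
    J_p = (ncr + ncw) / stats.total_time
    J_R = ncr / stats.total_time
    J_W = ncw / stats.total_time
    obs = Observables(
        scheme=stats.scheme,
        eta=eta,
        v=v,
        C2=C2,
        C3=C3,
        sigma=sigma,
        delta_sigma=sigma / J_p if J_p > 0 else np.nan,
        J_R=J_R,
        J_W=J_W,
    )
    return obs, stderr


def random_rate_set(
    seed_or_rng,
    scheme: str = "ERPR",
    log10_low: float = -2.0,
    log10_high: float = 2.0,
    forward_factor: float | None = None,
) -> RateSet:
    """Draw a rate set with every rate log-uniform in ``10^[low, high]``.

    ``forward_factor`` (if given) additionally multiplies every reverse
    rate, e.g. ``1e-12`` to approach the forward-driven limit.
    """
    rng = np.random.default_rng(seed_or_rng)
    _, edges, _ = topology(scheme)
    names = sorted({n for e in edges for n in e[:2]})
    rates = {
        name: 10.0 ** rng.uniform(log10_low, log10_high) for name in names
    }
    if forward_factor is not None:
        for _, rev, _, _ in edges:
            rates[rev] *= forward_factor
    F = 10.0 ** rng.uniform(log10_low, log10_high)
    return RateSet(scheme, rates, F)


def random_params(
    seed_or_rng,
    gamma_range=(0.0, 4.0),
    delta_range=(0.0, 8.0),
    delta_p_range=(0.0, 5.0),
    log10_freq_range=(-2.0, 2.0),
    energy_range=(0.0, 10.0),
) -> DiscriminationParams:
    """Draw structured parameters (Kramers-rate networks) at random."""
    rng = np.random.default_rng(seed_or_rng)
    return DiscriminationParams(
        gamma=rng.uniform(*gamma_range),
        delta=rng.uniform(*delta_range),
        delta_p=rng.uniform(*delta_p_range),
        eps=5.0,
        omega=1.0,
        omega_i=10.0 ** rng.uniform(*log10_freq_range),
        omega_l=10.0 ** rng.uniform(*log10_freq_range),
        omega_m=10.0 ** rng.uniform(*log10_freq_range),
        eps_i=rng.uniform(*energy_range),
        eps_p=rng.uniform(*energy_range),
        F=10.0 ** rng.uniform(*log10_freq_range),
    )


def sample_rate_sets(
    n: int,
    seed: int,
    scheme: str = "ERPR",
    require_positive_h_flux: bool = False,
    **kwargs,
):
    """Yield ``n`` random rate sets, optionally filtered on the net h-flux.

    The filter keeps draws whose steady state has ``J_h,R + J_h,W >= 0``
    (internal relaxation running forward on average), the condition
    under which the individual pathway costs are bounded by 1.  Each
    yielded item is ``(rate_set, steady_state)``.
    """
    from .networks import steady_state  # local to avoid cycle at import time

    rng = np.random.default_rng(seed)
    produced = 0
    while produced < n:
        rs = random_rate_set(rng, scheme=scheme, **kwargs)
        ss = steady_state(generator_matrix(rs))
        if require_positive_h_flux and scheme == "ERPR":
            states, _, _ = topology("ERPR")
            idx = {s: k for k, s in enumerate(states)}
            J_h = sum(
                rs[f"h{S}+"] * ss[idx[f"E'{S}"]] - rs[f"h{S}-"] * ss[idx[f"E{S}"]]
                for S in ("R", "W")
            )
            if J_h < 0:
                continue
        produced += 1
        yield rs, ss
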