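"""Shared fixtures.

The GA fronts used by the trade-off tests are expensive (merged 4-seed
runs plus hybrid refinement), so they are computed once per session and
shared across tests.
"""
from __future__ import annotations

import pytest

from proofthermo import analytics, pareto
from proofthermo.networks import DiscriminationParams


@pytest.fixture(scope="session")
def canonical_params() -> DiscriminationParams:
    """The canonical relay-regime parameter point (gamma=2, delta=1, delta_p=1)."""
    return DiscriminationParams()


@pytest.fixture(scope="session")
def erpr_front() -> pareto.ParetoFront:
    """Merged 4-seed refined front, pure relay regime (gamma=2, delta=1, delta_p=1)."""
    cfg = pareto.OptimizationConfig()
    return pareto.trade_off_front(cfg, seed=7)


@pytest.fixture(scope="session")
def mixed_front() -> pareto.ParetoFront:
    """Merged 4-seed refined front, mixed regime (gamma=2, delta=4, delta_p=2)."""
    cfg = pareto.OptimizationConfig(delta=4.0, delta_p=2.0)
    return pareto.trade_off_front(cfg, seed=11)


@pytest.fixture(scope="session")
def eta_bounds_erpr() -> tuple[float, float]:
    """(eta_E, eta_eq) for the canonical relay-regime point."""
    eta_E, _ = analytics.min_error_erpr(2.0, 1.0, 1.0)
    return eta_E, analytics.equilibrium_error(2.0)
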