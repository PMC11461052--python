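"""Steady-state observables: fluxes, error, costs, entropy production."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from proofthermo import networks as nw, observables as ob
from proofthermo.oracle import random_rate_set, sample_rate_sets


def params(**kw):
    return dataclasses.replace(nw.DiscriminationParams(), **kw)


def solve(rates):
    return nw.steady_state(nw.generator_matrix(rates))


class TestFluxesAndError:
    def test_zero_catalysis_means_zero_production(self):
        rs = nw.build_erpr_rates(params())
        rs = nw.RateSet("ERPR", rs.rates, 0.0)
        ss = solve(rs)
        assert ob.production_fluxes(rs, ss) == (0.0, 0.0)

    def test_uniform_distribution_fluxes(self):
        rs = nw.RateSet("ERPR", {k: 1.0 for k in nw.build_erpr_rates(params()).rates}, 1.0)
        ss = np.full(6, 1 / 6)
        J_R, J_W = ob.production_fluxes(rs, ss)
        assert J_R == pytest.approx(1 / 6)
        assert J_W == pytest.approx(1 / 6)

    def test_error_rate_basic_values(self):
        assert ob.error_rate(1.0, 0.0) == 0.0
        assert ob.error_rate(2.0, 2.0) == 0.5
        with pytest.raises(ob.UndefinedObservableError):
            ob.error_rate(0.0, 0.0)

    def test_mismatched_state_space_rejected(self):
        rs = nw.build_erpr_rates(params())
        with pytest.raises(ValueError):
            ob.production_fluxes(rs, np.full(3, 1 / 3))

    def test_equilibrium_error_is_boltzmann(self):
        """F -> 0: the error tends to f(gamma), the bound-state Boltzmann ratio."""
        rs = nw.build_erpr_rates(params(gamma=2.0, F=1e-12))
        ss = solve(rs)
        eta = ob.error_rate(*ob.production_fluxes(rs, ss))
        assert eta == pytest.approx(1 / (1 + np.exp(2.0)), rel=1e-6)


class TestCosts:
    def test_total_cost_vanishes_at_steady_state(self):
        for k, (rs, ss) in enumerate(sample_rate_sets(200, seed=42)):
            C2, C3 = ob.pathway_costs(rs, ss)
            assert abs(C2 + C3) < 1e-10, f"draw {k}: C2+C3 = {C2 + C3}"

    def test_cost_bound_structured_networks(self):
        """|C2|, |C3| <= 1 under forward net internal (h) flux, on networks
        drawn from the Kramers free-energy parametrization (the passive
        proofreading cycle prevents the runaway circulation that can break
        the bound for arbitrary unstructured rates)."""
        from proofthermo.oracle import random_params

        states, _, _ = nw.topology("ERPR")
        idx = {s: k for k, s in enumerate(states)}
        worst = 0.0
        n_accept = 0
        for k in range(1000):
            rs = nw.build_erpr_rates(random_params(60_000 + k))
            ss = solve(rs)
            J_h = sum(
                rs[f"h{S}+"] * ss[idx[f"E'{S}"]] - rs[f"h{S}-"] * ss[idx[f"E{S}"]]
                for S in ("R", "W")
            )
            if J_h < 0:
                continue
            n_accept += 1
            C2, C3 = ob.pathway_costs(rs, ss)
            worst = max(worst, abs(C2), abs(C3))
        assert n_accept >= 500
        assert worst <= 1.0 + 1e-12

    def test_one_sided_cost_bounds_unstructured(self):
        """For arbitrary positive rates, forward net h-flux still guarantees
        C2 <= 1 and C3 >= -1 (the flux-balance identities C2 = J_l/J_p and
        J_h = J_p - J_l); the two-sided bound needs the structured rates."""
        states, _, _ = nw.topology("ERPR")
        idx = {s: k for k, s in enumerate(states)}
        for rs, ss in sample_rate_sets(300, seed=43, require_positive_h_flux=True):
            C2, C3 = ob.pathway_costs(rs, ss)
            assert C2 <= 1.0 + 1e-12
            assert C3 >= -1.0 - 1e-12

    def test_disabled_proofreading_pathway_has_zero_cost(self):
        rs = nw.build_erpr_rates(params())
        rates = dict(rs.rates)
        for name in ("lR+", "lR-", "lW+", "lW-"):
            rates[name] = 0.0
        rs0 = nw.RateSet("ERPR", rates, rs.F)
        ss = solve(rs0)
        C2, C3 = ob.pathway_costs(rs0, ss)
        assert C2 == pytest.approx(0.0, abs=1e-14)

    def test_costs_only_for_relay_scheme(self):
        rs = nw.build_mm_rates(params())
        with pytest.raises(ValueError):
            ob.pathway_costs(rs, solve(rs))


class TestSpeed:
    def test_speed_is_bound_state_occupancy(self):
        """v = (J_R + J_W)/F = P_ER + P_EW <= 1 for the relay network."""
        rs = nw.build_erpr_rates(params())
        ss = solve(rs)
        v = ob.speed(*ob.production_fluxes(rs, ss), rs.F)
        i = {s: k for k, s in enumerate(nw.ERPR_STATES)}
        assert v == pytest.approx(ss[i["ER"]] + ss[i["EW"]], rel=1e-12)
        assert 0.0 < v <= 1.0

    def test_fast_catalysis_depletes_bound_states(self):
        vs = []
        for F in (1.0, 1e3, 1e6):
            rs = nw.build_erpr_rates(params(F=F))
            ss = solve(rs)
            vs.append(ob.speed(*ob.production_fluxes(rs, ss), F))
        assert vs[0] > vs[1] > vs[2]
        assert vs[2] < 1e-2


class TestEntropyProduction:
    def test_nonnegative_on_random_rate_sets(self):
        for rs, ss in sample_rate_sets(100, seed=44):
            assert ob.entropy_production(rs, ss) >= 0.0

    def test_vanishes_at_equilibrium(self):
        """The structured (Kramers) network satisfies detailed balance when
        catalysis is switched off, so sigma -> 0 as F -> 0."""
        rs = nw.build_erpr_rates(params(F=1e-10))
        ss = solve(rs)
        assert ob.entropy_production(rs, ss) == pytest.approx(0.0, abs=1e-7)

    def test_one_way_edge_diverges_with_warning(self):
        rs = nw.build_erpr_rates(params())
        rates = dict(rs.rates)
        rates["hR-"] = 0.0
        rs1 = nw.RateSet("ERPR", rates, rs.F)
        ss = solve(rs1)
        with pytest.warns(RuntimeWarning):
            assert ob.entropy_production(rs1, ss) == np.inf

    def test_cycle_decomposition_identity(self):
        """sigma equals the sum over graph cycles of cycle flux times cycle
        affinity: decompose the steady-state edge currents into a cycle
        basis of the (full) network graph and recombine."""
        import networkx as nx

        rs = random_rate_set(7, scheme="ERPR", log10_low=-1, log10_high=1)
        ss = solve(rs)
        states, edges, catalysis = nw.topology("ERPR")
        idx = {s: k for k, s in enumerate(states)}
        # oriented edge list: reversible edges then catalysis edges
        oriented = [(idx[a], idx[b]) for _, _, a, b in edges]
        oriented += [(idx[a], idx[b]) for a, b in catalysis]
        currents = []
        affinities = []  # probability-inclusive affinity; None on catalysis
        for fwd, rev, a, b in edges:
            i, j = idx[a], idx[b]
            plus, minus = rs[fwd] * ss[i], rs[rev] * ss[j]
            currents.append(plus - minus)
            affinities.append(np.log(plus / minus))
        for a, b in catalysis:
            currents.append(rs.F * ss[idx[a]])
            affinities.append(None)
        Gx = nx.Graph()
        Gx.add_edges_from(oriented)
        lookup = {}
        for e, (i, j) in enumerate(oriented):
            lookup[(i, j)] = (e, +1.0)
            lookup[(j, i)] = (e, -1.0)
        n_edges = len(oriented)
        rows = []
        for cyc in nx.cycle_basis(Gx):  # ordered node lists
            chi = np.zeros(n_edges)
            for u, v in zip(cyc, cyc[1:] + cyc[:1]):
                e, s = lookup[(u, v)]
                chi[e] = s
            rows.append(chi)
        Chi = np.array(rows).T  # (n_edges, n_cycles)
        phi, *_ = np.linalg.lstsq(Chi, np.array(currents), rcond=None)
        assert np.abs(Chi @ phi - currents).max() < 1e-12  # currents are cyclic
        sigma_cycles = 0.0
        for c, chi in enumerate(Chi.T):
            aff = sum(
                s * affinities[e]
                for e, s in enumerate(chi)
                if s != 0 and affinities[e] is not None
            )
            sigma_cycles += phi[c] * aff
        sigma = ob.entropy_production(rs, ss)
        assert sigma_cycles == pytest.approx(sigma, rel=1e-8)

    def test_entropy_per_product(self):
        assert ob.entropy_per_product(0.0, 1.0) == 0.0
        assert ob.entropy_per_product(2.0, 4.0) == 0.5
        with pytest.raises(ob.UndefinedObservableError):
            ob.entropy_per_product(1.0, 0.0)


class TestEvaluatePipeline:
    @pytest.mark.parametrize("scheme", ["ERPR", "KPR", "MM"])
    def test_smoke_all_schemes(self, scheme):
        o = ob.evaluate(nw.DiscriminationParams(), scheme)
        assert 0.0 <= o.eta <= 1.0
        assert 0.0 <= o.v <= 1.0
        assert o.sigma >= 0.0
        assert o.delta_sigma >= 0.0

    def test_requires_scheme_with_params(self):
        with pytest.raises(ValueError):
            ob.evaluate(nw.DiscriminationParams())

    def test_accepts_rate_set_directly(self):
        rs = nw.build_erpr_rates(nw.DiscriminationParams())
        o1 = ob.evaluate(rs)
        o2 = ob.evaluate(nw.DiscriminationParams(), "ERPR")
        assert o1.eta == pytest.approx(o2.eta, rel=1e-12)
        assert o1.C2 + o1.C3 == pytest.approx(0.0, abs=1e-10)


class TestBatchEngineAgreesWithModularPath:
    def test_objectives_match_evaluate(self):
        """The vectorized GA engine and the modular rates->generator->
        steady-state->observables path are independent implementations;
        they must agree on random parameter draws."""
        from proofthermo import pareto as pt

        rng = np.random.default_rng(11)
        for scheme in ("ERPR", "KPR"):
            cfg = pt.OptimizationConfig(
                scheme=scheme,
                log10_rate_bounds=(-2, 2),
                energy_bounds=(0.0, 8.0),
                constrain_eps_order=False,
            )
            lb, ub = cfg.bounds()
            X = rng.uniform(lb, ub, (100, len(lb)))
            obj, par = pt.batch_objectives(X, cfg)
            for k in range(0, 100, 7):
                p = nw.DiscriminationParams(
                    gamma=cfg.gamma, delta=cfg.delta, delta_p=cfg.delta_p,
                    eps=cfg.eps, omega=cfg.omega,
                    omega_i=par[k, 0], omega_l=par[k, 1], omega_m=par[k, 2],
                    eps_i=par[k, 3], eps_p=par[k, 4], F=par[k, 5],
                )
                o = ob.evaluate(p, scheme)
                assert obj[k, 0] == pytest.approx(o.eta, rel=1e-8, abs=1e-12)
                assert obj[k, 1] == pytest.approx(o.v, rel=1e-8)
                assert obj[k, 2] == pytest.approx(o.C2, rel=1e-6, abs=1e-10)
                assert obj[k, 3] == pytest.approx(o.delta_sigma, rel=1e-6)
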