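"""Cycle enumeration, flux decomposition, sensitivities, populations."""

import itertools

import numpy as np
import pytest

from twinsite.model import Conditions, FreeEnergyParams, ModelClass
from twinsite.observables import steady_state_distribution, turnover_from_fluxes
from twinsite import fluxes as fx

from conftest import random_params


def brute_force_single_hydrolysis_cycles(mc: ModelClass) -> set[frozenset]:
    """All simple cycles with exactly one hydrolysis edge, by DFS (oracle)."""
    adj: dict[int, set[int]] = {s.index: set() for s in mc.states}
    hyd_pairs = set()
    for t in mc.transitions:
        adj[t.source.index].add(t.target.index)
        adj[t.target.index].add(t.source.index)
        if t.is_hydrolysis:
            hyd_pairs.add(frozenset((t.source.index, t.target.index)))

    cycles: set[frozenset] = set()

    def extend(path: list[int]) -> None:
        last = path[-1]
        for nxt in adj[last]:
            if nxt == path[0] and len(path) >= 3:
                edges = [
                    frozenset((a, b))
                    for a, b in zip(path, path[1:] + path[:1])
                ]
                if sum(e in hyd_pairs for e in edges) == 1:
                    cycles.add(frozenset(edges))
            elif nxt not in path and nxt > path[0]:
                extend(path + [nxt])

    for start in adj:
        extend([start])
    return cycles


class TestCycleEnumeration:
    def test_matches_brute_force_oracle(self, mc):
        cycles = fx.enumerate_hydrolysis_cycles(mc)
        expected = brute_force_single_hydrolysis_cycles(mc)
        got = {
            frozenset(
                frozenset((a, b))
                for a, b in zip(c.states, c.states[1:] + c.states[:1])
            )
            for c in cycles
        }
        assert got == expected
        assert len(cycles) == len(expected) == 44

    def test_every_cycle_has_exactly_one_hydrolysis_edge(self, mc):
        for cyc in fx.enumerate_hydrolysis_cycles(mc):
            n_hyd = sum(
                mc.transitions[e].is_hydrolysis for e, _s in cyc.edges
            )
            assert n_hyd == 1
            # first step is the hydrolysis edge, traversed forward
            assert mc.transitions[cyc.edges[0][0]].is_hydrolysis
            assert cyc.edges[0][1] == +1

    def test_named_five_state_cycles_present(self, mc):
        cycles = fx.enumerate_hydrolysis_cycles(mc)
        names = {c.name for c in cycles if c.name}
        assert names == {"1T", "1D", "2T", "2D"}
        # hydrolysis in NBSI with ATP in NBSII (paper's 1-2-3-5-12 pattern)
        keys = {c.key for c in cycles}
        assert "cTT-cDT-oDT-oaT-oTT" in keys

    def test_deterministic_order(self, mc):
        a = fx.enumerate_hydrolysis_cycles(mc)
        b = fx.enumerate_hydrolysis_cycles(mc)
        assert [c.key for c in a] == [c.key for c in b]

    def test_brute_force_oracle_on_random_subgraphs(self, mc):
        """Enumeration restricted to random edge subsets matches DFS."""
        import networkx as nx

        rng = np.random.default_rng(0)
        full_edges = [(t.source.index, t.target.index) for t in mc.transitions]
        for _ in range(5):
            keep = rng.random(len(full_edges)) < 0.7
            G = nx.Graph(e for e, k in zip(full_edges, keep) if k)
            hyd = {
                frozenset((t.source.index, t.target.index))
                for t, k in zip(mc.transitions, keep)
                if k and t.is_hydrolysis
            }
            found = 0
            for walk in nx.simple_cycles(G):
                edges = [frozenset(p) for p in zip(walk, walk[1:] + walk[:1])]
                if sum(e in hyd for e in edges) == 1:
                    found += 1
            # DFS oracle on the same subgraph
            adj = {n: set(G[n]) for n in G}
            seen = set()

            def extend(path):
                nonlocal seen
                for nxt in adj[path[-1]]:
                    if nxt == path[0] and len(path) >= 3:
                        edges = frozenset(
                            frozenset(p) for p in zip(path, path[1:] + path[:1])
                        )
                        if sum(e in hyd for e in edges) == 1:
                            seen.add(edges)
                    elif nxt not in path and nxt > path[0]:
                        extend(path + [nxt])

            for start in adj:
                extend([start])
            assert found == len(seen)


class TestNetFluxes:
    def test_divergence_free_at_steady_state(self, mc, params):
        rm = mc.build_rate_matrix(params, fx.saturating_conditions())
        pi = steady_state_distribution(rm.Q)
        flux = fx.net_fluxes(mc, rm, pi)
        div = np.zeros(13)
        for e, t in enumerate(mc.transitions):
            div[t.source.index] -= flux[e]
            div[t.target.index] += flux[e]
        assert np.abs(div).max() < 1e-8 * max(np.abs(flux).max(), 1.0)

    def test_equilibrium_fluxes_vanish(self, mc, params):
        from twinsite.model import equilibrium_conditions

        rm = mc.build_rate_matrix(params, equilibrium_conditions())
        pi = steady_state_distribution(rm.Q)
        flux = fx.net_fluxes(mc, rm, pi)
        assert np.abs(flux).max() < 1e-10 * np.abs(rm.kf * pi[mc._src]).max()


class TestDecomposition:
    def test_two_cycle_toy_matches_hand_computed_split(self):
        """A 4-state network with two cycles sharing the hydrolysis edge.

        Flux f1 runs through cTT-cDT-oDT-oaT-oTT (1T), f2 through the
        6-cycle replacing oaT by oTa->oaa; engineered fluxes split at the
        branch in ratio of the open-state exits.
        """
        mc = ModelClass()
        params = random_params(mc, seed=3)
        rm = mc.build_rate_matrix(params, fx.saturating_conditions())
        pi = steady_state_distribution(rm.Q)
        cycles = fx.enumerate_hydrolysis_cycles(mc)
        rep = fx.decompose_cycle_fluxes(mc, rm, pi, cycles)
        flux = rep.edge_net_flux
        # conservation per hydrolysis edge is the hand-checkable contract
        for e, t in enumerate(mc.transitions):
            if not t.is_hydrolysis:
                continue
            assigned = sum(
                th for cyc, th in zip(rep.cycles, rep.theta)
                if cyc.edges[0][0] == e
            )
            assert assigned == pytest.approx(flux[e], abs=1e-8 * max(abs(rep.turnover), 1e-30))

    def test_single_cycle_carries_everything(self):
        """Suppressing all but the 1T route assigns ~100% to that cycle."""
        mc = ModelClass()
        params = random_params(mc, seed=3)
        # block site II hydrolysis and ADP exchange entirely
        params.barriers["hyd_II"] = 43.0
        params.barriers["bind_ADP_II"] = 43.0
        params.diffs["bind_ADP_II"] = 8.0
        rm = mc.build_rate_matrix(params, fx.saturating_conditions())
        pi = steady_state_distribution(rm.Q)
        rep = fx.decompose_cycle_fluxes(mc, rm, pi)
        main = np.argmax(np.abs(rep.theta))
        assert rep.vartheta[main] == pytest.approx(1.0, abs=1e-3)

    def test_conservation_and_totals_on_random_models(self, mc):
        for seed in range(6):
            params = random_params(mc, seed=seed)
            rm = mc.build_rate_matrix(params, fx.saturating_conditions())
            pi = steady_state_distribution(rm.Q)
            rep = fx.decompose_cycle_fluxes(mc, rm, pi)
            scale = max(abs(rep.turnover), 1e-30)
            assert rep.residual_hydrolysis <= 1e-8 * scale
            assert rep.theta.sum() == pytest.approx(rep.turnover, rel=1e-8)


class TestClassification:
    def test_type_key_from_dominant_cycles(self, mc, params):
        rm = mc.build_rate_matrix(params, fx.saturating_conditions())
        pi = steady_state_distribution(rm.Q)
        rep = fx.decompose_cycle_fluxes(mc, rm, pi)
        key = fx.classify_reaction_type(rep, tau=0.20)
        assert key == tuple(sorted(c.key for c in rep.dominant(0.20)))

    def test_tau_zero_includes_all_positive_cycles(self, mc, params):
        rm = mc.build_rate_matrix(params, fx.saturating_conditions())
        pi = steady_state_distribution(rm.Q)
        rep = fx.decompose_cycle_fluxes(mc, rm, pi)
        key = fx.classify_reaction_type(rep, tau=0.0)
        assert len(key) == int((rep.vartheta > 0).sum())

    def test_all_below_threshold_gives_empty_type(self, mc, params):
        rm = mc.build_rate_matrix(params, fx.saturating_conditions())
        pi = steady_state_distribution(rm.Q)
        rep = fx.decompose_cycle_fluxes(mc, rm, pi)
        assert fx.classify_reaction_type(rep, tau=1.1) == ()

    def test_fixture_type_stable_over_threshold_scan(self):
        """The packaged fixture's WT type is stable for tau in [0.05, 0.25]."""
        from twinsite.synthetic import asymmetric_fixture

        truth = asymmetric_fixture()
        mc = truth.mc
        params, _ = truth.layout.split(truth.x)
        rm = mc.build_rate_matrix(params, fx.saturating_conditions())
        pi = steady_state_distribution(rm.Q)
        rep = fx.decompose_cycle_fluxes(mc, rm, pi)
        keys = {fx.classify_reaction_type(rep, tau=t) for t in np.linspace(0.05, 0.25, 9)}
        assert len(keys) == 1


class TestSensitivities:
    def test_adjoint_matches_finite_differences(self, mc):
        for seed in (3, 7):
            params = random_params(mc, seed=seed)
            sa = fx.sensitivities(mc, params, mode="adjoint")
            sf = fx.sensitivities(mc, params, mode="fd")
            for key in sa.coefficient_sensitivity:
                a, b = sa.coefficient_sensitivity[key], sf.coefficient_sensitivity[key]
                assert a == pytest.approx(b, rel=1e-4, abs=1e-4 * abs(sa.kcat))
            np.testing.assert_allclose(
                sa.state_sensitivity, sf.state_sensitivity,
                rtol=1e-4, atol=1e-4 * abs(sa.kcat),
            )

    def test_uniform_rate_scaling_homogeneity(self, mc, params):
        rep = fx.sensitivities(mc, params, mode="adjoint")
        total = sum(rep.coefficient_sensitivity.values())
        assert total == pytest.approx(rep.kcat, rel=1e-6)

    def test_linear_chain_identifies_slow_step(self, mc):
        """With one slow step in the single-route cycle, that label wins."""
        params = random_params(mc, seed=3)
        for lab in params.barriers:
            params.barriers[lab] = 16.0
        params.barriers["hyd_II"] = 43.0       # block route II
        params.barriers["bind_ADP_II"] = 43.0
        params.diffs["bind_ADP_II"] = 8.0
        params.barriers["conf_TT"] = 32.0      # the slow step
        rep = fx.sensitivities(mc, params, mode="adjoint")
        assert rep.rate_limiting_coefficient[0] == "conf_TT"

    def test_rate_limiting_state_is_argmax(self, mc, params):
        rep = fx.sensitivities(mc, params)
        assert rep.rate_limiting_state == int(np.argmax(np.abs(rep.state_sensitivity)))


class TestPopulationSummary:
    def test_single_sample_gives_one_hot_matrices(self, mc, params):
        summary = fx.population_summary(mc, [params])
        assert summary.cond_most_given_rate_limiting.sum() == pytest.approx(1.0)
        col = summary.rate_limiting[0]
        assert summary.cond_most_given_rate_limiting[summary.most_populated[0], col] == 1.0

    def test_matrices_are_column_conditioned(self, mc):
        sets = [random_params(mc, seed=s) for s in range(4)]
        summary = fx.population_summary(mc, sets)
        mat = summary.cond_most_given_rate_limiting
        sums = mat.sum(axis=0)
        for c in range(13):
            assert sums[c] == pytest.approx(1.0) or sums[c] == 0.0

    def test_dominance_flag_thresholds_at_ninety_percent(self):
        from twinsite.synthetic import asymmetric_fixture

        truth = asymmetric_fixture()
        params, _ = truth.layout.split(truth.x)
        summary = fx.population_summary(truth.mc, [params])
        assert bool(summary.dominance_flag[0])  # fixture has a >=90% state


def test_dot_export_mentions_all_states(mc, params):
    rm = mc.build_rate_matrix(params, fx.saturating_conditions())
    pi = steady_state_distribution(rm.Q)
    flux = fx.net_fluxes(mc, rm, pi)
    dot = fx.export_flux_graph_dot(mc, pi, flux)
    assert dot.startswith("digraph")
    for s in mc.states:
        assert f'label="{s.key}"' in dot
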