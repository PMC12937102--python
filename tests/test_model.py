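"""State space, transition topology and rate-matrix thermodynamics."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twinsite.constants import R_GAS, T_REF, attempt_frequency
from twinsite.model import (
    DIFF_KEYS,
    Conditions,
    FreeEnergyParams,
    MarkovState,
    ModelClass,
    ModelError,
    MutationSpec,
    count_free_parameters,
    cycle_ratio_product,
    enumerate_states,
    enumerate_transitions,
    equilibrium_conditions,
    state_free_energy,
)

from conftest import random_params


class TestStateSpace:
    def test_thirteen_states_nine_open_four_closed(self):
        states = enumerate_states()
        assert len(states) == 13
        assert sum(s.conformation == "open" for s in states) == 9
        closed = [s for s in states if s.conformation == "closed"]
        assert len(closed) == 4
        assert all(s.occupancy_I != "apo" and s.occupancy_II != "apo" for s in closed)

    def test_indices_are_canonical_and_unique(self):
        states = enumerate_states()
        assert [s.index for s in states] == list(range(13))
        assert states[0].key == "oaa"

    def test_closed_apo_state_rejected(self):
        with pytest.raises(ModelError):
            MarkovState("closed", "apo", "ATP", 0)

    def test_occupation_numbers(self):
        states = enumerate_states()
        by_key = {s.key: s for s in states}
        assert (by_key["cTT"].n_atp, by_key["cTT"].n_adp) == (2, 0)
        assert (by_key["oTD"].n_atp, by_key["oTD"].n_adp) == (1, 1)
        assert (by_key["oaa"].n_atp, by_key["oaa"].n_adp) == (0, 0)


class TestTopology:
    def test_twenty_forward_edges_ten_labels(self, mc):
        assert len(mc.transitions) == 20
        assert len(mc.labels) == 10
        kinds = [t.kind for t in mc.transitions]
        assert sum(k.startswith("bind") for k in kinds) == 12
        assert sum(k == "conf_change" for k in kinds) == 4
        assert sum(k.startswith("hydrolysis") for k in kinds) == 4

    def test_allosteric_labels_are_per_edge(self, mc_allosteric):
        assert len(mc_allosteric.labels) == 20

    def test_structural_constraints(self, mc):
        for t in mc.transitions:
            if t.is_exchange:
                assert t.source.conformation == "open" == t.target.conformation
            if t.is_hydrolysis:
                assert t.source.conformation == "closed" == t.target.conformation
            if t.kind == "conf_change":
                assert t.source.occupancy_I == t.target.occupancy_I
                assert t.source.occupancy_II == t.target.occupancy_II

    def test_graph_connected_with_cycle_rank_eight(self, mc):
        G = nx.Graph((t.source.index, t.target.index) for t in mc.transitions)
        assert nx.is_connected(G)
        assert mc.n_transitions - mc.n_states + 1 == 8

    def test_rejects_unindexed_states(self):
        bad = [MarkovState("open", "apo", "apo")]
        with pytest.raises(ModelError):
            enumerate_transitions(bad)


class TestParameterCounts:
    @pytest.mark.parametrize(
        "allostery,mutation_model,expected",
        [
            (False, "fixed_factor", 17),
            (True, "fixed_factor", 32),
            (False, "free_factor_and_affinity", 29),
            (True, "free_factor_and_affinity", 44),
        ],
    )
    def test_layout_counts(self, allostery, mutation_model, expected):
        assert count_free_parameters(allostery, mutation_model) == expected

    def test_detailed_balance_eliminates_three_coefficients(self, mc):
        # 10 forward + 10 backward unique coefficients, 17 free parameters
        n_coefficients = 2 * len(mc.labels)
        assert n_coefficients - mc.count_free_parameters() == 3


class TestStateFreeEnergy:
    def test_reference_state_is_zero(self, mc, params):
        assert state_free_energy(params, mc.states[0]) == 0.0

    def test_single_ligand_additivity(self, mc, params):
        by_key = {s.key: s for s in mc.states}
        assert state_free_energy(params, by_key["oTa"]) == pytest.approx(
            params.diffs["bind_ATP_I"]
        )
        assert state_free_energy(params, by_key["oaD"]) == pytest.approx(
            params.diffs["bind_ADP_II"]
        )

    def test_site_swap_symmetry(self, mc, params):
        swapped = FreeEnergyParams(
            barriers=dict(params.barriers),
            diffs={
                "bind_ATP_I": params.diffs["bind_ATP_II"],
                "bind_ATP_II": params.diffs["bind_ATP_I"],
                "bind_ADP_I": params.diffs["bind_ADP_II"],
                "bind_ADP_II": params.diffs["bind_ADP_I"],
                "open_to_closed": params.diffs["open_to_closed"],
                "ATP_to_ADP_closed_I": params.diffs["ATP_to_ADP_closed_II"],
                "ATP_to_ADP_closed_II": params.diffs["ATP_to_ADP_closed_I"],
            },
        )
        by_key = {s.key: s for s in mc.states}
        for a, b in [("oTD", "oDT"), ("cTD", "cDT"), ("oTa", "oaT")]:
            assert state_free_energy(params, by_key[a]) == pytest.approx(
                state_free_energy(swapped, by_key[b])
            )

    def test_layout_validation(self):
        with pytest.raises(ModelError):
            FreeEnergyParams(barriers={"a": 0.0})
        with pytest.raises(ModelError):
            FreeEnergyParams(
                barriers={"a": 0.0},
                diffs={k: 0.0 for k in DIFF_KEYS},
                state_energies=np.zeros(13),
            )


class TestRateMatrix:
    def test_zero_barrier_unimolecular_rate_is_attempt_frequency(self, mc):
        params = FreeEnergyParams(
            barriers={lab: 0.0 for lab in mc.labels},
            diffs={k: 0.0 for k in DIFF_KEYS},
        )
        rm = mc.build_rate_matrix(params, Conditions(1.0, 1.0, 1.0))
        conf_edges = [i for i, t in enumerate(mc.transitions) if t.kind == "conf_change"]
        omega0 = attempt_frequency(T_REF)
        assert rm.kf[conf_edges] == pytest.approx(omega0)
        assert omega0 == pytest.approx(6.21e12, rel=1e-3)

    def test_columns_sum_to_zero(self, mc, params):
        rm = mc.build_rate_matrix(params, Conditions(1e-3, 1e-5, 1e-5))
        colsums = np.abs(rm.Q.sum(axis=0))
        assert colsums.max() <= 1e-10 * np.abs(rm.Q).max()

    def test_zeros_only_where_no_transition(self, mc, params):
        rm = mc.build_rate_matrix(params, Conditions(1.0, 1.0, 1.0))
        connected = set()
        for t in mc.transitions:
            connected.add((t.target.index, t.source.index))
            connected.add((t.source.index, t.target.index))
        for i in range(13):
            for j in range(13):
                if i == j:
                    continue
                if (i, j) in connected:
                    assert rm.Q[i, j] > 0
                else:
                    assert rm.Q[i, j] == 0

    def test_single_hydrolysis_cycle_product_recovers_dg0(self, mc, params):
        rm = mc.build_rate_matrix(params, Conditions(1.0, 1.0, 1.0))
        # bind ATP I -> close -> hydrolyse I -> open -> release ADP+Pi at I
        cycle = [4, 9, 11, 7, 1]  # oTT cTT cDT oDT oaT
        prod = cycle_ratio_product(mc, rm, cycle)
        dg0 = -R_GAS * T_REF * math.log(prod) / 1e3
        assert dg0 == pytest.approx(-29.288, rel=1e-6)
        assert prod == pytest.approx(1.353e5, rel=1e-3)

    def test_no_chemistry_cycle_product_is_one(self, mc, params):
        rm = mc.build_rate_matrix(params, Conditions(1.0, 1.0, 1.0))
        # bind ATP at I, then II, unbind at I, then II: no net chemistry
        cycle = [0, 3, 4, 1]
        assert cycle_ratio_product(mc, rm, cycle) == pytest.approx(1.0, rel=1e-8)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_detailed_balance_closure_any_parameters(self, seed):
        """Cycle products close thermodynamically for arbitrary parameters."""
        mc = ModelClass()
        params = random_params(mc, seed=seed, fast=False)
        rm = mc.build_rate_matrix(params, Conditions(1.0, 1.0, 1.0))
        prod = cycle_ratio_product(mc, rm, [4, 9, 10, 5, 3])  # hydrolysis at II
        expected = math.exp(29.288e3 / (R_GAS * T_REF))
        assert prod == pytest.approx(expected, rel=1e-8)

    def test_temperature_rescaling_follows_eyring(self, mc, params):
        """Rates at two temperatures agree via fixed-energy barrier scaling."""
        t2 = 310.0
        rm_ref = mc.build_rate_matrix(params, Conditions(1.0, 1.0, 1.0))
        rm_hot = mc.build_rate_matrix(
            params, Conditions(1.0, 1.0, 1.0, temperature=t2)
        )
        conf = [i for i, t in enumerate(mc.transitions) if t.kind == "conf_change"]
        for e in conf:
            barrier_ref = math.log(attempt_frequency(T_REF) / rm_ref.kf[e])
            barrier_hot = math.log(attempt_frequency(t2) / rm_hot.kf[e])
            assert barrier_hot * t2 == pytest.approx(barrier_ref * T_REF, rel=1e-10)

    def test_invalid_conditions_rejected(self):
        with pytest.raises(ModelError):
            Conditions(conc_ATP=-1.0)
        with pytest.raises(ModelError):
            Conditions(temperature=0.0)


class TestMutation:
    def test_mutation_scales_only_its_sites_hydrolysis(self, mc, params):
        cond = Conditions(1e-3, 1e-5, 1e-5)
        wt = mc.build_rate_matrix(params, cond)
        mut = mc.build_rate_matrix(
            params, cond, MutationSpec(site="NBSII", hydrolysis_reduction_factor=100.0)
        )
        for e, t in enumerate(mc.transitions):
            if t.kind == "hydrolysis_II":
                assert mut.kf[e] == pytest.approx(wt.kf[e] / 100.0)
                assert mut.kb[e] == pytest.approx(wt.kb[e] / 100.0)
            else:
                assert mut.kf[e] == wt.kf[e]
                assert mut.kb[e] == wt.kb[e]

    def test_wild_type_matrix_bit_identical_outside_mutated_entries(self, mc, params):
        cond = Conditions(1e-3, 1e-5, 1e-5)
        wt = mc.build_rate_matrix(params, cond)
        mut = mc.build_rate_matrix(params, cond, mc.mutation_for_species("E238Q"))
        touched = set()
        for e, t in enumerate(mc.transitions):
            if t.kind == "hydrolysis_I":
                touched.add((t.target.index, t.source.index))
                touched.add((t.source.index, t.target.index))
                touched.add((t.source.index, t.source.index))
                touched.add((t.target.index, t.target.index))
        for i in range(13):
            for j in range(13):
                if (i, j) not in touched:
                    assert mut.Q[i, j] == wt.Q[i, j]

    def test_affinity_shift_slows_unbinding_when_negative(self, mc, params):
        cond = Conditions(1e-3, 1e-5, 1e-5)
        wt = mc.build_rate_matrix(params, cond)
        shifted = mc.build_rate_matrix(
            params,
            cond,
            MutationSpec(
                site="NBSI",
                hydrolysis_reduction_factor=100.0,
                affinity_shift={("ATP", "NBSI"): -2.0},
            ),
        )
        for e, t in enumerate(mc.transitions):
            if t.kind == "bind_ATP_I":
                # unbinding (backward) leaves the ATP-bound state
                assert shifted.kb[e] == pytest.approx(wt.kb[e] * math.exp(-2.0))
                assert shifted.kf[e] == wt.kf[e]

    def test_unknown_species_rejected(self, mc):
        with pytest.raises(ModelError):
            mc.mutation_for_species("E999Q")


def test_equilibrium_conditions_satisfy_mass_action(params):
    cond = equilibrium_conditions()
    k_eq = cond.conc_ADP * cond.conc_Pi / cond.conc_ATP
    assert k_eq == pytest.approx(math.exp(29.288e3 / (R_GAS * T_REF)), rel=1e-12)
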