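"""Transfer function, compiled ODE system, simulation and flux summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cholode.logic_ode import (
    ConditionInput,
    ParameterBounds,
    ParameterVector,
    compile_model,
    flux_summaries,
    hill_transfer,
    relative_uptake_change,
    simulate,
)
from cholode.pkn import NetworkEdge, NetworkNode, PriorKnowledgeNetwork, cholesterol_pkn
from cholode.synthdata import toy_conditions, toy_network

from conftest import euler_oracle


class TestHillTransfer:
    @pytest.mark.parametrize("k,n", [(0.1, 1), (0.5, 2), (0.9, 7.5)])
    def test_normalization_endpoints(self, k, n):
        assert hill_transfer(0.0, k, n) == 0.0
        assert hill_transfer(1.0, k, n) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # 0.25 * (1 + 0.25) / (0.25 + 0.25)
        assert hill_transfer(0.5, 0.5, 2) == pytest.approx(0.625)

    def test_half_effect_at_k(self):
        # at x = k the response is (1 + k^n) / 2 >= 1/2, the curve's midpoint
        assert hill_transfer(0.3, 0.3, 4) == pytest.approx((1 + 0.3**4) / 2)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        x1=st.floats(0.001, 0.998),
        dx=st.floats(0.001, 0.5),
        k=st.floats(0.01, 1.0),
        n=st.floats(1.0, 10.0),
    )
    def test_strictly_increasing(self, x1, dx, k, n):
        x2 = min(x1 + dx, 1.0)
        assert hill_transfer(x2, k, n) > hill_transfer(x1, k, n)

    @pytest.mark.parametrize("bad", [(-0.1, 0.5, 2), (1.1, 0.5, 2), (0.5, 0.0, 2), (0.5, 0.5, 0.5)])
    def test_domain_violations_rejected(self, bad):
        with pytest.raises(ValueError):
            hill_transfer(*bad)


class TestParameterVector:
    def test_fixture_template_structure(self):
        net = cholesterol_pkn()
        pv = ParameterVector.from_network(net)
        # per hill (edge, source) a k and n, one tau per dynamic node,
        # the metabolic constants
        assert {"k1", "k4", "kM4", "kI_atorvastatin", "tau_CholER"} <= set(pv.names)
        assert len(set(pv.names)) == len(pv.names)
        # knockdown transfer shapes and the fixed SREBP edges are frozen
        fixed = {n for n, f in zip(pv.names, pv.fixed) if f}
        assert "k_siSREBF1_SREBP1" in fixed and "n_siLDLR_LDLR" in fixed
        assert "k_SREBP_SREBP1" in fixed and "k_SREBP_SREBP2" in fixed
        assert "k_SREBP2_HMGCR" not in fixed

    def test_bounds_shared_and_respected(self):
        pv = ParameterVector.from_network(toy_network(), ParameterBounds())
        assert pv.within_bounds()
        for name, kind, lo, hi in zip(pv.names, pv.kinds, pv.lower, pv.upper):
            if kind == "hill_n":
                assert (lo, hi) == (1.0, 10.0)
            if kind == "tau":
                assert (lo, hi) == (0.01, 10.0)

    def test_with_free_values_keeps_fixed_entries(self):
        net = cholesterol_pkn()
        pv = ParameterVector.from_network(net)
        out = pv.with_free_values(np.full(len(pv.free_names), 0.123))
        fixed_vals = out.values[out.fixed]
        assert np.array_equal(fixed_vals, pv.values[pv.fixed])
        assert np.all(out.values[~out.fixed] == 0.123)

    def test_csv_round_trip(self, tmp_path):
        pv = ParameterVector.from_network(toy_network())
        pv.to_csv(tmp_path / "p.csv")
        back = ParameterVector.from_csv(tmp_path / "p.csv")
        assert back.names == pv.names
        assert np.allclose(back.values, pv.values)
        assert np.array_equal(back.fixed, pv.fixed)


def _two_node_net():
    nodes = [
        NetworkNode("S", category="stimulus", initial_level=0.0),
        NetworkNode("P", category="protein", measured=True),
    ]
    return PriorKnowledgeNetwork(nodes, [NetworkEdge("S>P", (("S", 1),), "P")])


class TestRhs:
    def test_fixed_point_of_single_activating_edge(self):
        net = _two_node_net()
        pv = ParameterVector.from_network(net).updated({"tau_P": 1.0})
        model = compile_model(net, pv)
        clamps = model.clamp_vector(ConditionInput("on", {"S": 1.0}))
        dx = model.rhs(0.0, np.array([1.0]), pv.values, clamps)
        assert dx[0] == pytest.approx(0.0, abs=1e-12)

    def test_acetyl_coa_pure_source_term(self):
        net = cholesterol_pkn()
        pv = ParameterVector.from_network(net).updated(
            {"k1": 0.8, "k2": 0.0, "k3": 0.0, "k7": 0.0, "tau_AcetylCoA": 1.0}
        )
        model = compile_model(net, pv)
        x = model.x0.copy()
        dx = model.rhs(0.0, x, pv.values, model.default_clamps)
        i = model.dynamic.index("AcetylCoA")
        assert dx[i] == pytest.approx(0.5 * 0.8)

    def test_hmgcoa_flux_reduces_to_plain_michaelis_menten_without_statin(self):
        net = cholesterol_pkn()
        pv = ParameterVector.from_network(net)
        model = compile_model(net, pv)
        x = model.x0.copy()
        for node, level in [("HMGCoA", 0.3), ("HMGCR", 0.6), ("AtorvaIn", 0.0),
                            ("HMGCS1act", 0.0), ("Mevalonate", 0.0)]:
            x[model.dynamic.index(node)] = level
        dx = model.rhs(0.0, x, pv.values, model.default_clamps)
        k4, km4 = pv["k4"], pv["kM4"]
        expected = pv["tau_Mevalonate"] * (k4 * 0.6 * 0.3 / (km4 + 0.3))
        assert dx[model.dynamic.index("Mevalonate")] == pytest.approx(expected)

    def test_missing_parameter_is_named(self):
        net = toy_network()
        pv = ParameterVector.from_network(net)
        short = ParameterVector(
            pv.names[:-1], pv.values[:-1], pv.lower[:-1], pv.upper[:-1], pv.fixed[:-1]
        )
        with pytest.raises(KeyError, match="tau_"):
            compile_model(net, short)

    def test_kernel_matches_reference_implementation(self, toy_truth):
        net = toy_network()
        model = compile_model(net, toy_truth.params)
        rng = np.random.default_rng(3)
        clamps = model.clamp_vector(toy_conditions()["stim_drug"])
        for _ in range(20):
            x = rng.uniform(0.0, 1.5, model.n_dyn)
            fast = model.rhs(0.0, x, toy_truth.params.values, clamps)
            ref = model.rhs_reference(0.0, x, toy_truth.params.values, clamps)
            assert np.allclose(fast, ref, atol=1e-12)


class TestSimulate:
    def test_determinism_bit_identical(self, toy_net, toy_truth):
        cond = toy_conditions()["stim"]
        a = simulate(toy_net, toy_truth.params, cond)
        b = simulate(toy_net, toy_truth.params, cond)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.times, b.times)

    def test_regulatory_states_bounded(self, toy_net, toy_truth):
        model = compile_model(toy_net, toy_truth.params)
        for cond in toy_conditions().values():
            res = model.simulate(toy_truth.params, cond)
            for node in ("TF", "E1", "E2"):
                traj = res.trajectory(node)
                assert np.all(traj >= -1e-6) and np.all(traj <= 1 + 1e-6)

    def test_metabolites_nonnegative(self, toy_net, toy_truth):
        model = compile_model(toy_net, toy_truth.params)
        for cond in toy_conditions().values():
            res = model.simulate(toy_truth.params, cond)
            for node in ("M1", "M2", "M3"):
                assert np.all(res.trajectory(node) >= -1e-9)

    def test_terminal_state_matches_euler_oracle(self, toy_net, toy_truth):
        model = compile_model(toy_net, toy_truth.params)
        for cond in (toy_conditions()["untreated"], toy_conditions()["stim_drug"]):
            res = model.simulate(toy_truth.params, cond, rtol=1e-9, atol=1e-11)
            oracle = euler_oracle(
                model, toy_truth.params.values, model.clamp_vector(cond), cond.end_time
            )
            assert np.max(np.abs(res.states[-1] - oracle)) < 1e-4

    def test_statin_raises_hmgcoa(self):
        net = cholesterol_pkn()
        pv = ParameterVector.from_network(net)
        untreated = simulate(net, pv).terminal
        statin = simulate(net, pv, ConditionInput("statin", {"AtorvaEx": 1.0})).terminal
        assert statin["HMGCoA"] > untreated["HMGCoA"]

    def test_infinite_inhibition_constant_equals_no_statin(self, toy_net, toy_truth):
        drugged = toy_conditions()["drug"]
        immune = toy_truth.params.updated({"kI_mm": 1e9})
        with_drug = simulate(toy_net, immune, drugged)
        no_drug = simulate(toy_net, immune, ConditionInput("off", {}))
        assert np.allclose(with_drug.states[-1], no_drug.states[-1], atol=1e-5)

    def test_end_time_must_be_positive(self, toy_net, toy_truth):
        with pytest.raises(ValueError):
            simulate(toy_net, toy_truth.params, end_time=-1.0)

    def test_converged_flag_reflects_residual(self, toy_net, toy_truth):
        res = simulate(toy_net, toy_truth.params, toy_conditions()["untreated"])
        assert res.converged == (res.max_residual < 1e-6)


class TestFluxSummaries:
    def _params(self, net, k5, k6):
        return ParameterVector.from_network(net).updated({"k5": k5, "k6": k6})

    def test_equal_fluxes_give_half(self):
        net = cholesterol_pkn()
        pv = self._params(net, k5=0.2, k6=0.2)
        state = {"CholMedia": 1.0, "LDLR": 1.0, "NPC1": 1.0, "Mevalonate": 1.0}
        fx = flux_summaries(net, pv, {"c": state})
        assert fx.loc["c", "fraction_uptake"] == pytest.approx(0.5)

    def test_fraction_arithmetic(self):
        net = cholesterol_pkn()
        pv = self._params(net, k5=0.1, k6=0.3)
        state = {"CholMedia": 1.0, "LDLR": 1.0, "NPC1": 1.0, "Mevalonate": 1.0}
        fx = flux_summaries(net, pv, {"c": state})
        assert fx.loc["c", "uptake"] == pytest.approx(0.3)
        assert fx.loc["c", "synthesis"] == pytest.approx(0.1)
        assert fx.loc["c", "fraction_uptake"] == pytest.approx(0.75)

    def test_relative_uptake_change(self):
        net = cholesterol_pkn()
        pv = self._params(net, k5=0.1, k6=1.0)
        states = {
            "control": {"CholMedia": 1.0, "LDLR": 0.5, "NPC1": 1.0, "Mevalonate": 0.1},
            "treated": {"CholMedia": 1.0, "LDLR": 0.8, "NPC1": 1.0, "Mevalonate": 0.1},
        }
        fx = flux_summaries(net, pv, states)
        assert relative_uptake_change(fx, "treated", "control") == pytest.approx(0.6)

    def test_clamped_medium_level_taken_from_condition(self):
        # sterol-depleted medium (clamped CholMedia) must reduce the
        # computed uptake flux even though clamped nodes are absent from
        # the dynamic terminal state
        net = cholesterol_pkn()
        pv = self._params(net, k5=0.1, k6=0.5)
        state = {"LDLR": 1.0, "NPC1": 1.0, "Mevalonate": 1.0}
        conds = {"lpds": ConditionInput("lpds", {"CholMedia": 0.05})}
        fx = flux_summaries(net, pv, {"lpds": state, "full": state},
                            conditions=conds)
        assert fx.loc["lpds", "uptake"] == pytest.approx(0.5 * 0.05)
        assert fx.loc["full", "uptake"] == pytest.approx(0.5 * 0.5)

    def test_zero_total_flux_flagged_not_raised(self):
        net = cholesterol_pkn()
        pv = self._params(net, k5=0.0, k6=0.0)
        fx = flux_summaries(net, pv, {"c": {"Mevalonate": 0.0, "CholMedia": 0.0,
                                            "LDLR": 0.0, "NPC1": 0.0}})
        assert bool(fx.loc["c", "undefined_fraction"])
        assert np.isnan(fx.loc["c", "fraction_uptake"])
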