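"""QP/LP/generalized balancing of infeasible scenarios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fluxbalancer as fb
from fluxbalancer.exceptions import BalancingError
from fluxbalancer.networks import random_scenario


class TestComputeWeights:
    def test_magnitude_scheme(self):
        scen = fb.FluxScenario(fixed={"R4": 2.0, "R10": 4.0})
        w = fb.compute_weights(scen, "W2")
        assert w == {"R4": 0.5, "R10": 0.25}

    def test_equal_scheme(self):
        scen = fb.FluxScenario(fixed={"R4": 2.0, "R10": 4.0})
        assert set(fb.compute_weights(scen, "W3").values()) == {1.0}

    def test_variance_scheme(self):
        scen = fb.FluxScenario(fixed={"R4": 2.0}, variances={"R4": 0.25})
        assert fb.compute_weights(scen, "W1") == {"R4": 4.0}
        with pytest.raises(ValueError, match="W1"):
            fb.compute_weights(fb.FluxScenario(fixed={"R4": 2.0}), "W1")

    def test_zero_rate_rules(self):
        scen = fb.FluxScenario(fixed={"Ra": 0.0, "Rb": 4.0})
        w = fb.compute_weights(scen, "W2")
        assert w == {"Ra": 1e6, "Rb": 0.25}
        w = fb.compute_weights(scen, fb.WeightSpec("W2", pin_zero_rates=True))
        assert math.isinf(w["Ra"])

    def test_zero_flux_weight_floor(self):
        with pytest.raises(ValueError):
            fb.WeightSpec("W2", zero_flux_weight=10.0)


class TestQpBalance:
    def test_magnitude_weights_match_printed_value(self, pair, pair_scenario):
        res = fb.qp_balance(pair, pair_scenario, "W2")
        assert res.status == "optimal"
        assert res.corrected_values["R4"] == pytest.approx(8 / 3, abs=1e-6)
        assert res.corrected_values["R10"] == pytest.approx(8 / 3, abs=1e-6)

    def test_equal_weights(self, pair, pair_scenario):
        res = fb.qp_balance(pair, pair_scenario, "W3")
        assert res.corrected_values["R4"] == pytest.approx(3.0, abs=1e-6)
        assert res.corrected_values["R10"] == pytest.approx(3.0, abs=1e-6)
        assert res.objective_value == pytest.approx(2.0, abs=1e-6)

    def test_bound_clips_the_unconstrained_optimum(self, pair, pair_scenario):
        clipped = pair.copy()
        clipped.ub[0] = 2.5  # ub(R4): QP optimum 3 becomes infeasible
        res = fb.qp_balance(clipped, pair_scenario, "W3")
        assert res.corrected_values["R4"] == pytest.approx(2.5, abs=1e-6)
        assert res.corrected_values["R10"] == pytest.approx(2.5, abs=1e-6)
        assert res.deltas["R4"] == pytest.approx(-0.5, abs=1e-6)
        assert res.deltas["R10"] == pytest.approx(1.5, abs=1e-6)

    def test_feasible_scenario_needs_no_correction(self, pair):
        res = fb.qp_balance(pair, fb.FluxScenario(fixed={"R4": 3.0, "R10": 3.0}), "W3")
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)
        assert all(abs(d) < 1e-6 for d in res.deltas.values())

    def test_infeasible_base_detected(self, pair, pair_scenario):
        broken = pair.copy()
        broken.lb[0], broken.ub[0] = 5.0, 6.0  # R4 in [5,6]
        broken.ub[1] = 1.0  # but R10 <= 1: base system infeasible
        res = fb.qp_balance(broken, pair_scenario, "W3")
        assert res.status == "infeasible_base"
        assert "generalized_balance" in res.message

    def test_empty_scenario(self, pair):
        res = fb.qp_balance(pair, fb.FluxScenario(fixed={}), "W3")
        assert res.status == "optimal" and res.objective_value == 0.0


class TestLpBalance:
    def test_equal_weights_objective_and_optimal_face(self, pair, pair_scenario):
        res = fb.lp_balance(pair, pair_scenario, "W3", check_uniqueness=True)
        assert res.objective_value == pytest.approx(2.0, abs=1e-9)
        v4, v10 = res.corrected_values["R4"], res.corrected_values["R10"]
        assert v4 == pytest.approx(v10, abs=1e-8)
        assert 2.0 - 1e-8 <= v4 <= 4.0 + 1e-8
        assert res.unique is False  # whole segment [2,4] is optimal

    def test_magnitude_weights_unique_solution(self, pair, pair_scenario):
        res = fb.lp_balance(pair, pair_scenario, "W2", check_uniqueness=True)
        assert res.corrected_values["R4"] == pytest.approx(2.0, abs=1e-8)
        assert res.corrected_values["R10"] == pytest.approx(2.0, abs=1e-8)
        assert res.unique is True

    def test_feasible_scenario_zero_slacks(self, pair):
        res = fb.lp_balance(pair, fb.FluxScenario(fixed={"R4": 3.0, "R10": 3.0}), "W3")
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)
        for dp, dm in res.deltas.values():
            assert dp == pytest.approx(0.0, abs=1e-9)
            assert dm == pytest.approx(0.0, abs=1e-9)

    def test_slack_pairs_never_both_active(self):
        for seed in range(10):
            syn = random_scenario(seed, sigma=0.3, k=8, n=10, m=5)
            res = fb.lp_balance(syn.model, syn.scenario, "W2")
            assert res.status == "optimal"
            for dp, dm in res.deltas.values():
                assert min(dp, dm) == pytest.approx(0.0, abs=1e-9)

    def test_lp_objective_never_exceeds_qp_absolute_cost(self):
        """The LP minimizes sum w|delta|; the QP corrections are feasible for
        it, so the LP optimum is a lower bound."""
        for seed in range(10):
            syn = random_scenario(seed, sigma=0.3, k=8, n=10, m=5)
            w = fb.compute_weights(syn.scenario, "W2")
            qp = fb.qp_balance(syn.model, syn.scenario, "W2")
            lp = fb.lp_balance(syn.model, syn.scenario, "W2")
            qp_abs = sum(w[r] * abs(d) for r, d in qp.deltas.items())
            assert lp.objective_value <= qp_abs + 1e-6 * (1 + qp_abs)


class TestGeneralizedBalance:
    def test_steady_state_slacks_match_pseudoinverse_residual(self, chain):
        scen = fb.FluxScenario(fixed={"R1": 5.0, "R3": 7.0})
        res = fb.generalized_balance(chain, scen, targets={"steady_state"}, engine="qp")
        slacks = res.constraint_slacks["steady_state"]
        assert slacks["A"] == pytest.approx(-1.0, abs=1e-6)
        assert slacks["B"] == pytest.approx(-1.0, abs=1e-6)
        # and they equal N r at the pseudoinverse solution (r2 = 6)
        part = fb.partition(chain, scen)
        r = np.zeros(3)
        r[part.U] = fb.pseudoinverse_solution(part)
        r[part.F] = part.rF
        np.testing.assert_allclose(
            [slacks["A"], slacks["B"]], chain.N @ r, atol=1e-6
        )

    def test_bound_slacks_cannot_fix_balance_inconsistency(self, pair, pair_scenario):
        with pytest.raises(BalancingError, match="slack target"):
            fb.generalized_balance(pair, pair_scenario, targets={"bounds"})

    def test_consistent_scenario_all_slacks_zero(self, chain):
        scen = fb.FluxScenario(fixed={"R1": 5.0, "R3": 5.0})
        for targets in [{"steady_state"}, {"fixed_rates", "bounds"}]:
            res = fb.generalized_balance(chain, scen, targets=targets, engine="qp")
            assert res.objective_value == pytest.approx(0.0, abs=1e-8)

    def test_bound_slack_resolves_bound_inconsistency(self, chain):
        tight = fb.chain3(ub_r1=3.0)
        scen = fb.FluxScenario(fixed={"R3": 5.0})  # needs r1 = 5 > ub
        res = fb.generalized_balance(tight, scen, targets={"bounds"}, engine="qp")
        assert res.constraint_slacks["ub"]["R1"] == pytest.approx(2.0, abs=1e-6)

    def test_lp_engine_on_steady_state(self, chain):
        scen = fb.FluxScenario(fixed={"R1": 5.0, "R3": 7.0})
        res = fb.generalized_balance(chain, scen, targets={"steady_state"}, engine="lp")
        assert res.status == "optimal"
        # total absolute steady-state slack needed is 2
        total = sum(abs(v) for v in res.constraint_slacks["steady_state"].values())
        assert total == pytest.approx(2.0, abs=1e-8)

    def test_general_constraint_slack(self, chain):
        con = chain.copy()
        con.A = np.array([[1.0, 0.0, 0.0]])  # r1 <= 3
        con.b = np.array([3.0])
        scen = fb.FluxScenario(fixed={"R3": 5.0})
        res = fb.generalized_balance(con, scen, targets={"general"}, engine="qp")
        assert res.constraint_slacks["general"][0] == pytest.approx(2.0, abs=1e-6)

    def test_monotone_in_target_classes(self, pair, pair_scenario):
        """Enlarging the correctable set never increases the optimum."""
        small = fb.generalized_balance(
            pair, pair_scenario, targets={"fixed_rates"}, engine="qp")
        large = fb.generalized_balance(
            pair, pair_scenario, targets={"fixed_rates", "steady_state", "bounds"},
            engine="qp")
        assert large.objective_value <= small.objective_value + 1e-8


class TestApplyCorrections:
    def test_qp_correction_application(self, pair, pair_scenario):
        res = fb.qp_balance(pair, pair_scenario, "W3")
        new = fb.apply_corrections(pair_scenario, res)
        assert new.fixed["R4"] == pytest.approx(3.0, abs=1e-6)
        assert pair_scenario.fixed["R4"] == 2.0  # original untouched

    def test_lp_sign_convention(self):
        res = fb.CorrectionResult(
            method="lp",
            deltas={"R10": (2.0, 0.0)},
            corrected_values={"R10": 6.0},
            status="optimal",
        )
        scen = fb.FluxScenario(fixed={"R10": 4.0})
        assert fb.apply_corrections(scen, res).fixed["R10"] == 6.0
        assert res.corrections() == {"R10": pytest.approx(2.0)}

    def test_zero_correction_is_identity(self, pair):
        scen = fb.FluxScenario(fixed={"R4": 3.0, "R10": 3.0})
        res = fb.qp_balance(pair, scen, "W3")
        assert fb.apply_corrections(scen, res).fixed == pytest.approx(scen.fixed, abs=1e-9)


class TestProperties:
    def test_post_correction_feasibility(self):
        for seed in range(15):
            syn = random_scenario(seed, sigma=0.4)
            for method in (fb.qp_balance, fb.lp_balance):
                res = method(syn.model, syn.scenario, "W3")
                assert res.status == "optimal"
                corrected = fb.apply_corrections(syn.scenario, res)
                assert fb.check_feasible(syn.model, corrected, feasibility_tol=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3), seed=st.integers(0, 5))
    def test_weight_scaling_leaves_argmin_unchanged(self, scale, seed):
        syn = random_scenario(seed, sigma=0.3, k=8, n=10, m=5)
        w = fb.compute_weights(syn.scenario, "W2")
        w_scaled = {r: scale * v for r, v in w.items()}
        a = fb.qp_balance(syn.model, syn.scenario, w)
        b = fb.qp_balance(syn.model, syn.scenario, w_scaled)
        for rid in w:
            assert a.deltas[rid] == pytest.approx(b.deltas[rid], abs=1e-6)
        assert b.objective_value == pytest.approx(
            scale * a.objective_value, rel=1e-6, abs=1e-9)

    def test_pinned_zero_rates_are_never_corrected(self, example):
        scen = fb.FluxScenario(fixed={"R1": 1.0, "R2": 2.0, "R3": 1.5, "R4": 2.0,
                                      "R6": 0.0})
        spec = fb.WeightSpec("W2", pin_zero_rates=True)
        for method in (fb.qp_balance, fb.lp_balance):
            res = method(example, scen, spec)
            assert res.status == "optimal"
            assert res.corrected_values["R6"] == 0.0
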