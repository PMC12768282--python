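import itertools

import numpy as np
import pytest
import sympy as sp

from cardiobool.bne import (
    ConvergenceError,
    closed_form_cm_steady_state,
    cm_symbolic_steady_state,
    iterate_to_fixed_point,
    ra_sweep_and_threshold,
    transform_to_real,
)
from cardiobool.logic import evaluate, sync_step
from cardiobool.synth import RandomNetworkSpec, random_boolean_network

from conftest import make_net


@pytest.fixture(scope="module")
def cm_system(cm_model):
    return transform_to_real(cm_model.network)


class TestTransform:
    def test_and_not_becomes_product(self, cm_system):
        x_irx4, x_nr2f2 = sp.symbols("x_IRX4 x_NR2F2")
        expected = sp.expand(x_irx4 * (1 - x_nr2f2))
        assert sp.simplify(cm_system.updates["MYL2"] - expected) == 0

    def test_or_becomes_probabilistic_sum(self, cm_system):
        x_irx4 = sp.Symbol("x_IRX4")
        gamma = sp.Symbol("gamma")
        expected = sp.expand(x_irx4 + gamma - gamma * x_irx4)
        assert sp.simplify(cm_system.updates["HAND2"] - expected) == 0

    def test_constant_rule(self):
        net = make_net({"A": "1", "B": "A"})
        system = transform_to_real(net, param_nodes={})
        assert system.updates["A"] == 1

    def test_corner_equivalence_verified_on_construction(self):
        # transform_to_real checks every polynomial on all binary corners;
        # spot-check one network explicitly as well
        net = random_boolean_network(RandomNetworkSpec(n=4, k=2, seed=2))
        system = transform_to_real(net, param_nodes={})
        for node in net.nodes:
            poly = system.updates[node]
            names = sorted(net.functions[node].variables())
            for corner in itertools.product((0, 1), repeat=len(names)):
                env = dict(zip(names, corner))
                real = poly.subs({system.symbols[n]: v for n, v in env.items()})
                assert int(real) == evaluate(net.functions[node], env)

    def test_params_taken_from_inputs(self, cm_system):
        assert {n: str(s) for n, s in cm_system.params.items()} == {
            "RA": "rho",
            "GATA4_6": "gamma",
            "NOTCH": "nu",
        }


class TestIteration:
    def test_boolean_atrial_corner(self, cm_system):
        state, _ = iterate_to_fixed_point(cm_system, {"rho": 1, "gamma": 1, "nu": 1})
        assert state["MYL7"] == pytest.approx(1.0, abs=1e-8)
        assert state["MYL2"] == pytest.approx(0.0, abs=1e-8)
        assert state["NR2F2"] == pytest.approx(1.0, abs=1e-8)

    def test_boolean_ventricular_corner(self, cm_system):
        state, _ = iterate_to_fixed_point(cm_system, {"rho": 0, "gamma": 1, "nu": 1})
        assert state["MYL2"] == pytest.approx(1.0, abs=1e-8)
        assert state["MYL7"] == pytest.approx(0.0, abs=1e-8)

    def test_half_ra(self, cm_system):
        # frozen from the algebraic solution at rho = 1/2, gamma = nu = 1
        state, meta = iterate_to_fixed_point(
            cm_system, {"rho": 0.5, "gamma": 1, "nu": 1}, tol=1e-9
        )
        assert meta["residual"] < 1e-9
        for node, expected in {
            "NR2F2": 0.5, "HAND2": 1.0, "IRX4": 0.5,
            "MYL2": 0.25, "HEY2": 0.5, "MYL7": 0.25,
        }.items():
            assert state[node] == pytest.approx(expected, abs=1e-8), node

    def test_input_validation(self, cm_system):
        with pytest.raises(ValueError):
            iterate_to_fixed_point(cm_system, {"rho": 1.5, "gamma": 1, "nu": 1})
        with pytest.raises(KeyError):
            iterate_to_fixed_point(cm_system, {"rho": 1, "gamma": 1})

    def test_closure_in_unit_cube(self, cm_system):
        rng = np.random.default_rng(0)
        for _ in range(20):
            rho, gamma, nu = rng.uniform(0.05, 1.0, size=3)
            state, _ = iterate_to_fixed_point(
                cm_system, {"rho": rho, "gamma": gamma, "nu": nu}
            )
            assert all(-1e-12 <= v <= 1 + 1e-12 for v in state.values())

    def test_convergence_near_degenerate_corner(self, cm_system):
        # contraction factor (1-gamma)(1-rho) < 1 whenever rho + gamma > 0
        state, _ = iterate_to_fixed_point(
            cm_system, {"rho": 0.05, "gamma": 0.05, "nu": 1}
        )
        expected = closed_form_cm_steady_state(0.05, 0.05, 1)
        assert state["HAND2"] == pytest.approx(expected["HAND2"], abs=1e-7)


class TestClosedForm:
    def test_ventricular_corner(self):
        state = closed_form_cm_steady_state(0, 1)
        assert (state["HAND2"], state["IRX4"], state["MYL2"]) == (1, 1, 1)

    def test_half_values(self):
        state = closed_form_cm_steady_state(0.5, 1)
        assert state["HAND2"] == pytest.approx(1.0)
        assert state["IRX4"] == pytest.approx(0.5)
        assert state["MYL2"] == pytest.approx(0.25)

    def test_degenerate_corner_raises(self):
        with pytest.raises(ZeroDivisionError):
            closed_form_cm_steady_state(0, 0)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            closed_form_cm_steady_state(2, 1)

    def test_oracle_equivalence_grid(self, cm_system):
        # iteration and algebra agree on a (rho, gamma) grid, nu = 1
        tol = 1e-9
        for rho in np.linspace(0, 1, 21):
            for gamma in np.linspace(0, 1, 21):
                if rho + gamma == 0:
                    continue
                closed = closed_form_cm_steady_state(float(rho), float(gamma), 1.0)
                iterated, _ = iterate_to_fixed_point(
                    cm_system, {"rho": float(rho), "gamma": float(gamma), "nu": 1.0},
                    tol=tol,
                )
                for node in ("NR2F2", "HAND2", "IRX4", "MYL2", "HEY2", "MYL7"):
                    assert iterated[node] == pytest.approx(
                        closed[node], abs=10 * tol
                    ), (node, rho, gamma)


class TestSymbolic:
    def test_steady_state_matches_printed_algebra(self, cm_system):
        rho, gamma, nu = sp.symbols("rho gamma nu")
        solution = cm_symbolic_steady_state(cm_system)
        hand2 = gamma / (rho + gamma - rho * gamma)
        expected = {
            "NR2F2": rho,
            "HEY2": nu * gamma * (1 - rho),
            "MYL7": rho * (1 - nu * gamma * (1 - rho)),
            "HAND2": hand2,
            "IRX4": hand2 * (1 - rho),
            "MYL2": hand2 * (1 - rho) ** 2,
        }
        for node, expr in expected.items():
            assert sp.simplify(solution[node] - expr) == 0, node

    def test_update_functions_match_printed_recurrences(self, cm_system):
        # after substituting the stabilised NR2F2 value (rho), the updates
        # become the printed recurrences in the inputs alone
        rho, gamma, nu = sp.symbols("rho gamma nu")
        x = cm_system.symbols
        subs = {x["NR2F2"]: rho}
        assert sp.simplify(cm_system.updates["NR2F2"] - rho) == 0
        assert sp.simplify(cm_system.updates["HEY2"].subs(subs) - nu * gamma * (1 - rho)) == 0
        assert sp.simplify(
            cm_system.updates["IRX4"].subs(subs) - x["HAND2"] * (1 - rho)
        ) == 0
        assert sp.simplify(
            cm_system.updates["MYL2"].subs(subs) - x["IRX4"] * (1 - rho)
        ) == 0
        assert sp.simplify(
            cm_system.updates["HAND2"] - (x["IRX4"] + gamma - gamma * x["IRX4"])
        ) == 0


@pytest.fixture(scope="module")
def sweep(cm_model):
    system = transform_to_real(cm_model.network)
    return ra_sweep_and_threshold(system, grid_size=41)


class TestRaSweep:
    def test_crossover_at_half(self, sweep):
        assert sweep.threshold == pytest.approx(0.5, abs=1e-8)

    def test_endpoint_is_ventricular_corner(self, sweep):
        assert sweep.activities["MYL2"].iloc[0] == pytest.approx(1.0)
        assert sweep.activities["MYL7"].iloc[0] == pytest.approx(0.0)

    def test_myl2_non_increasing(self, sweep):
        myl2 = sweep.activities["MYL2"].to_numpy()
        assert (np.diff(myl2) <= 1e-12).all()

    def test_quadratic_marker_profiles(self, sweep):
        # at gamma = nu = 1 the closed forms give MYL2 = (1-rho)^2, MYL7 = rho^2
        np.testing.assert_allclose(
            sweep.activities["MYL2"], (1 - sweep.rho) ** 2, atol=1e-8
        )
        np.testing.assert_allclose(
            sweep.activities["MYL7"], sweep.rho**2, atol=1e-8
        )

    def test_no_crossover_reported(self):
        # markers pinned apart: the gap never changes sign -> no threshold
        net = make_net(
            {"RA": "RA", "GATA4_6": "GATA4_6", "NOTCH": "NOTCH", "MYL2": "1", "MYL7": "0"}
        )
        result = ra_sweep_and_threshold(transform_to_real(net), grid_size=11)
        assert result.threshold is None

    def test_grid_size_validation(self, cm_system):
        with pytest.raises(ValueError):
            ra_sweep_and_threshold(cm_system, grid_size=5)


class TestCornerTrajectories:
    @pytest.mark.parametrize("seed", [1, 7])
    def test_bne_equals_boolean_on_binary_states(self, seed):
        # synchronous BNE trajectories from binary corners reproduce the
        # Boolean synchronous trajectories exactly
        net = random_boolean_network(RandomNetworkSpec(n=5, k=2, seed=seed))
        system = transform_to_real(net, param_nodes={})
        exprs = system.substituted({})
        for bits in range(1 << net.n):
            b_state = net.state(bits)
            c_state = {n: float(b_state[n]) for n in net.nodes}
            for _ in range(8):
                b_state = sync_step(net, b_state)
                c_state = {
                    n: float(exprs[n].subs(
                        {system.symbols[m]: c_state[m] for m in net.nodes}
                    ))
                    for n in net.nodes
                }
                assert c_state == {n: float(b_state[n]) for n in net.nodes}
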