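"""Continuous relaxation of Boolean networks and the RA dose–response sweep.

The relaxation maps each logic rule to a multilinear polynomial over
``[0, 1]`` activities: ``x AND y -> x*y``, ``x OR y -> x + y - x*y``,
``NOT x -> 1 - x``. At binary corners the polynomials coincide with their
Boolean sources, and the synchronous iteration of the resulting system is
the deterministic continuous counterpart of the Boolean dynamics.

For the cardiomyocyte-subtype model the three signaling inputs become the
parameters ``rho`` (RA), ``gamma`` (GATA4/6) and ``nu`` (NOTCH); the module
also carries the algebraic steady-state solution of that system and the
atrial/ventricular crossover threshold in ``rho``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import sympy as sp
from scipy.optimize import brentq

from .logic import And, BooleanNetwork, Const, LogicExpr, Not, Or, Var, canonical_name

__all__ = [
    "PARAM_NODES",
    "RealUpdateSystem",
    "ContinuousState",
    "ConvergenceError",
    "transform_to_real",
    "iterate_to_fixed_point",
    "closed_form_cm_steady_state",
    "cm_symbolic_steady_state",
    "RASweepResult",
    "ra_sweep_and_threshold",
]

#: Default mapping of signaling input nodes to continuous parameters.
PARAM_NODES: dict[str, str] = {"RA": "rho", "GATA4_6": "gamma", "NOTCH": "nu"}

ContinuousState = dict[str, float]


class ConvergenceError(RuntimeError):
    def __init__(self, residual: float, iterations: int):
        super().__init__(
            f"no fixed point within {iterations} iterations (residual {residual:.3e})"
        )
        self.residual = residual
        self.iterations = iterations


def _to_poly(expr: LogicExpr, sym: Mapping[str, sp.Symbol]) -> sp.Expr:
    if isinstance(expr, Const):
        return sp.Integer(expr.value)
    if isinstance(expr, Var):
        return sym[expr.name]
    if isinstance(expr, Not):
        return 1 - _to_poly(expr.operand, sym)
    if isinstance(expr, And):
        out = _to_poly(expr.args[0], sym)
        for a in expr.args[1:]:
            out = out * _to_poly(a, sym)
        return out
    if isinstance(expr, Or):
        out = _to_poly(expr.args[0], sym)
        for a in expr.args[1:]:
            nxt = _to_poly(a, sym)
            out = out + nxt - out * nxt
        return out
    raise TypeError(f"not a LogicExpr: {expr!r}")


@dataclass
class RealUpdateSystem:
    """Polynomial update functions over [0,1]-valued node activities.

    ``params`` maps input node names to their parameter symbols; these nodes
    are held at the supplied parameter value instead of being iterated.
    """

    nodes: tuple[str, ...]
    updates: dict[str, sp.Expr]  # dynamic node -> polynomial in symbols
    params: dict[str, sp.Symbol]  # input node -> parameter symbol
    symbols: dict[str, sp.Symbol]  # node -> its state symbol

    @property
    def dynamic_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if n not in self.params)

    def substituted(self, inputs: Mapping[str, float]) -> dict[str, sp.Expr]:
        """Update polynomials with parameter values substituted in."""
        subs = {self.params[n]: sp.Float(v) for n, v in self._input_map(inputs).items()}
        return {n: e.subs(subs) for n, e in self.updates.items()}

    def _input_map(self, inputs: Mapping[str, float]) -> dict[str, float]:
        by_param = {str(s): n for n, s in self.params.items()}
        out: dict[str, float] = {}
        for key, value in inputs.items():
            node = by_param.get(key, canonical_name(key))
            if node not in self.params:
                raise KeyError(f"unknown input {key!r}")
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"input {key}={value} outside [0, 1]")
            out[node] = float(value)
        missing = set(self.params) - set(out)
        if missing:
            raise KeyError(f"missing input value(s) for {sorted(missing)}")
        return out


def transform_to_real(
    net: BooleanNetwork,
    param_nodes: Mapping[str, str] | None = None,
    verify_corners: bool = True,
) -> RealUpdateSystem:
    """Relax a Boolean network to its polynomial update system.

    ``param_nodes`` maps input node names to parameter symbol names; those
    nodes (which must be self-sustaining inputs) become free parameters.
    With ``verify_corners`` each polynomial is checked to equal its Boolean
    source on all binary corners of its regulators.
    """
    if param_nodes is None:
        param_nodes = {k: v for k, v in PARAM_NODES.items() if k in net.index}
    params = {canonical_name(n): sp.Symbol(s) for n, s in param_nodes.items()}
    symbols = {n: params.get(n, sp.Symbol(f"x_{n}")) for n in net.nodes}
    updates = {}
    for node in net.nodes:
        if node in params:
            continue
        expr = net.effective_function(node)
        poly = sp.expand(_to_poly(expr, symbols))
        if verify_corners:
            _check_corners(expr, poly, symbols)
        updates[node] = poly
    return RealUpdateSystem(net.nodes, updates, params, symbols)


def _check_corners(expr: LogicExpr, poly: sp.Expr, symbols: Mapping[str, sp.Symbol]) -> None:
    from itertools import product

    from .logic import _eval  # standard Boolean evaluation

    names = sorted(expr.variables())
    for corner in product((0, 1), repeat=len(names)):
        env = dict(zip(names, corner))
        boolean = _eval(expr, env.__getitem__)
        real = poly.subs({symbols[n]: v for n, v in env.items()})
        if int(real) != boolean:
            raise AssertionError(
                f"polynomial disagrees with Boolean source at corner {env}"
            )


def iterate_to_fixed_point(
    system: RealUpdateSystem,
    inputs: Mapping[str, float],
    tol: float = 1e-9,
    max_iter: int = 10_000,
    init: Mapping[str, float] | float = 0.5,
) -> tuple[ContinuousState, dict]:
    """Synchronously iterate the relaxed system until the max-norm step < tol.

    Returns ``(state, meta)`` where ``meta`` records iterations and the
    final residual. Raises :class:`ConvergenceError` when the budget is
    exhausted (the degenerate all-zero input corner cycles forever).
    """
    dyn = system.dynamic_nodes
    exprs = system.substituted(inputs)
    args = [system.symbols[n] for n in dyn]
    fns = [sp.lambdify(args, exprs[n], modules="numpy") for n in dyn]

    if isinstance(init, Mapping):
        x = np.array([float(init[n]) for n in dyn])
    else:
        x = np.full(len(dyn), float(init))
    residual = np.inf
    for it in range(1, max_iter + 1):
        new = np.array([f(*x) for f in fns], dtype=float)
        residual = float(np.max(np.abs(new - x))) if len(dyn) else 0.0
        x = new
        if residual < tol:
            state = dict(zip(dyn, (float(v) for v in x)))
            for node, value in system._input_map(inputs).items():
                state[node] = value
            return state, {"iterations": it, "residual": residual}
    raise ConvergenceError(residual, max_iter)


def closed_form_cm_steady_state(
    rho: float, gamma: float, nu: float = 1.0
) -> ContinuousState:
    """Algebraic steady state of the relaxed cardiomyocyte-subtype system.

    Valid whenever ``rho + gamma - rho*gamma > 0``; at the degenerate corner
    ``rho = gamma = 0`` the coupled HAND2/IRX4 block is a neutral two-cycle
    and no unique steady state exists.
    """
    for name, v in (("rho", rho), ("gamma", gamma), ("nu", nu)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    denom = rho + gamma - rho * gamma
    if denom <= 0.0:
        raise ZeroDivisionError(
            "degenerate input corner rho = gamma = 0: coupled block does not stabilise"
        )
    hand2 = gamma / denom
    irx4 = hand2 * (1.0 - rho)
    return {
        "RA": rho,
        "GATA4_6": gamma,
        "NOTCH": nu,
        "NR2F2": rho,
        "HAND2": hand2,
        "IRX4": irx4,
        "MYL2": irx4 * (1.0 - rho),
        "HEY2": nu * gamma * (1.0 - rho),
        "MYL7": rho * (1.0 - nu * gamma * (1.0 - rho)),
    }


def cm_symbolic_steady_state(system: RealUpdateSystem) -> dict[str, sp.Expr]:
    """Solve the relaxed subtype system symbolically at steady state.

    Stabilises the input-driven chain (NR2F2, then HEY2/MYL7) by
    substitution and solves the coupled HAND2/IRX4/MYL2 block linearly.
    Returns one expression per dynamic node in the input parameters.
    """
    sym = system.symbols
    eqs = [sp.Eq(sym[n], system.updates[n]) for n in system.dynamic_nodes]
    solutions = sp.solve(eqs, [sym[n] for n in system.dynamic_nodes], dict=True)
    if len(solutions) != 1:
        raise ValueError(f"expected a unique symbolic steady state, got {len(solutions)}")
    sol = solutions[0]
    return {n: sp.simplify(sol[sym[n]]) for n in system.dynamic_nodes}


@dataclass
class RASweepResult:
    """Steady-state activities on a rho grid plus the marker crossover."""

    rho: np.ndarray
    activities: "object"  # pandas.DataFrame, one column per node
    threshold: float | None  # rho* with MYL2 = MYL7, None if no crossover
    gamma: float
    nu: float

    def to_frame(self):
        frame = self.activities.copy()
        frame.insert(0, "rho", self.rho)
        return frame


def ra_sweep_and_threshold(
    system: RealUpdateSystem,
    gamma: float = 1.0,
    nu: float = 1.0,
    grid_size: int = 101,
    tol: float = 1e-9,
) -> RASweepResult:
    """Sweep RA over [0, 1] and locate the atrial/ventricular crossover.

    Steady states come from the closed-form solution's oracle-verified
    iteration; the crossover ``rho*`` solves ``MYL2(rho) = MYL7(rho)`` by
    bisection between the bracketing grid points. Returns ``threshold=None``
    when the difference does not change sign on the grid.
    """
    import pandas as pd

    if grid_size < 11:
        raise ValueError("grid_size must be at least 11")
    rhos = np.linspace(0.0, 1.0, grid_size)
    records = []
    for rho in rhos:
        state, _ = iterate_to_fixed_point(
            system, {"rho": float(rho), "gamma": gamma, "nu": nu}, tol=tol
        )
        records.append(state)
    activities = pd.DataFrame.from_records(records)

    def gap(rho: float) -> float:
        state, _ = iterate_to_fixed_point(
            system, {"rho": float(rho), "gamma": gamma, "nu": nu}, tol=tol
        )
        return state["MYL2"] - state["MYL7"]

    diff = activities["MYL2"].to_numpy() - activities["MYL7"].to_numpy()
    threshold = None
    for i in range(len(rhos) - 1):
        lo, hi = diff[i], diff[i + 1]
        if lo == 0.0:
            threshold = float(rhos[i])
            break
        if lo * hi < 0:
            threshold = float(brentq(gap, rhos[i], rhos[i + 1], xtol=1e-10))
            break
    else:
        if diff[-1] == 0.0:
            threshold = float(rhos[-1])
    return RASweepResult(rhos, activities, threshold, gamma, nu)
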