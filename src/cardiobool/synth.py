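"""Synthetic inputs: random initial populations, random Boolean networks,
and an exact absorption-probability solver used as an oracle for the
Monte-Carlo population simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .attractors import (
    Attractor,
    StateSpaceTooLargeError,
    find_attractors,
    state_to_free_index,
    successor_table,
)
from .logic import And, BooleanNetwork, Const, LogicExpr, NetworkState, Not, Or, Var

__all__ = [
    "RandomNetworkSpec",
    "random_initial_state",
    "random_boolean_network",
    "exact_absorption_probabilities",
]

ABSORPTION_GUARD = 12


@dataclass(frozen=True)
class RandomNetworkSpec:
    """Parameters for a random-truth-table network (oracle harness)."""

    n: int
    k: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one node")
        if not 1 <= self.k <= self.n:
            raise ValueError("in-degree bound must be in [1, n]")


def random_initial_state(net: BooleanNetwork, rng: np.random.Generator) -> NetworkState:
    """Clamps at their values, every free node independently Bernoulli(1/2)."""
    bits = 0
    draws = rng.integers(0, 2, size=net.n_free)
    for name, b in zip(net.free_nodes, draws):
        if b:
            bits |= 1 << net.index[name]
    mask, value = net.clamp_bits()
    return NetworkState(net, (bits & ~mask) | value)


def _truth_table_expr(regulators: tuple[str, ...], table: np.ndarray) -> LogicExpr:
    """Sum-of-products expression for a truth table over ``regulators``."""
    if not table.any():
        return Const(0)
    if table.all():
        return Const(1)
    minterms = []
    for row, out in enumerate(table):
        if not out:
            continue
        lits: list[LogicExpr] = []
        for j, reg in enumerate(regulators):
            lit: LogicExpr = Var(reg)
            if not (row >> j) & 1:
                lit = Not(lit)
            lits.append(lit)
        minterms.append(lits[0] if len(lits) == 1 else And(tuple(lits)))
    return minterms[0] if len(minterms) == 1 else Or(tuple(minterms))


def random_boolean_network(
    spec: RandomNetworkSpec, rng: np.random.Generator | None = None
) -> BooleanNetwork:
    """A random network: each node gets a random truth table over at most
    ``k`` distinct random regulators. Reproducible from ``spec.seed``."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    nodes = [f"N{i}" for i in range(spec.n)]
    functions = {}
    for node in nodes:
        d = int(rng.integers(1, spec.k + 1))
        regs = tuple(nodes[i] for i in sorted(rng.choice(spec.n, size=d, replace=False)))
        table = rng.integers(0, 2, size=1 << d).astype(np.uint8)
        functions[node] = _truth_table_expr(regs, table)
    return BooleanNetwork(nodes, functions)


def exact_absorption_probabilities(
    net: BooleanNetwork,
    start: NetworkState,
    guard: int = ABSORPTION_GUARD,
) -> dict[Attractor, float]:
    """Exact absorption probabilities of the uniform single-node-update chain.

    The chain picks one of the ``n`` nodes uniformly (probability ``1/n``,
    clamped and stable nodes yield self-loops) and applies its update.
    Attractors of size > 1 are lumped into single absorbing classes; the
    returned probabilities sum to 1.
    """
    f = net.n_free
    if f > guard:
        raise StateSpaceTooLargeError(f, guard, "exact absorption solve")
    attractors = find_attractors(net, guard=guard)
    start_idx = state_to_free_index(net, start)
    for att in attractors:
        if any(state_to_free_index(net, s) == start_idx for s in att.states):
            return {a: (1.0 if a is att else 0.0) for a in attractors}

    table = successor_table(net)
    n_states = table.shape[0]
    n_total = net.n
    # class id per absorbing state, -1 for transient
    clazz = np.full(n_states, -1, dtype=np.int64)
    for c, att in enumerate(attractors):
        for s in att.states:
            clazz[state_to_free_index(net, s)] = c
    transient = np.flatnonzero(clazz < 0)
    t_pos = np.full(n_states, -1, dtype=np.int64)
    t_pos[transient] = np.arange(transient.size)

    # Build Q (transient -> transient) and R (transient -> class) with each
    # free-node update carrying mass 1/n; residual mass stays on the diagonal.
    rows_q, cols_q, vals_q = [], [], []
    r = np.zeros((transient.size, len(attractors)))
    diag = np.full(transient.size, (n_total - f) / n_total)
    p = 1.0 / n_total
    for j in range(f):
        dst = table[transient, j]
        to_trans = clazz[dst] < 0
        same = dst == transient
        diag[same] += p
        move = to_trans & ~same
        rows_q.append(np.flatnonzero(move))
        cols_q.append(t_pos[dst[move]])
        vals_q.append(np.full(int(move.sum()), p))
        absorbed = ~to_trans
        np.add.at(r, (np.flatnonzero(absorbed), clazz[dst[absorbed]]), p)
    rows = np.concatenate(rows_q + [np.arange(transient.size)])
    cols = np.concatenate(cols_q + [np.arange(transient.size)])
    vals = np.concatenate(vals_q + [diag])
    q = sp.csr_matrix((vals, (rows, cols)), shape=(transient.size, transient.size))
    system = sp.eye(transient.size, format="csr") - q
    b = spla.spsolve(system.tocsc(), r)
    b = np.atleast_2d(b)
    if b.shape[0] != transient.size:  # spsolve squeezes single-column rhs
        b = b.T
    probs = np.clip(b[t_pos[start_idx]], 0.0, 1.0)  # shave solver round-off
    return {att: float(probs[c]) for c, att in enumerate(attractors)}
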