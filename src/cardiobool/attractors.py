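"""Exhaustive state-space analysis of asynchronous Boolean networks.

States over the free nodes (clamps fixed) are enumerated as packed
integers in which bit ``j`` holds free node ``j``. Fixed points come from a
vectorised scan; complex attractors from strongly-connected-component
condensation of the asynchronous transition relation (scipy.sparse.csgraph).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .logic import And, BooleanNetwork, Const, LogicExpr, NetworkState, Not, Or, Var

__all__ = [
    "StateSpaceTooLargeError",
    "Attractor",
    "StateTransitionGraph",
    "enumerate_fixed_points",
    "find_attractors",
    "reachable_attractors",
    "build_stg",
    "free_index_to_state",
    "state_to_free_index",
    "successor_table",
    "fixed_point_mask",
]

FIXED_POINT_GUARD = 24
ATTRACTOR_GUARD = 22
STG_GUARD = 16
_CHUNK = 1 << 20


class StateSpaceTooLargeError(ValueError):
    def __init__(self, n_free: int, guard: int, what: str):
        super().__init__(
            f"{what} requires <= {guard} free nodes, network has {n_free}; "
            f"clamp input nodes to shrink the state space"
        )


def _eval_vector(expr: LogicExpr, columns: dict[str, np.ndarray]) -> np.ndarray:
    """Evaluate an expression over parallel uint8 columns."""
    if isinstance(expr, Const):
        some = next(iter(columns.values()))
        return np.full(some.shape, expr.value, dtype=np.uint8)
    if isinstance(expr, Var):
        return columns[expr.name]
    if isinstance(expr, Not):
        return (1 - _eval_vector(expr.operand, columns)).astype(np.uint8)
    if isinstance(expr, And):
        out = _eval_vector(expr.args[0], columns)
        for a in expr.args[1:]:
            out = out & _eval_vector(a, columns)
        return out
    if isinstance(expr, Or):
        out = _eval_vector(expr.args[0], columns)
        for a in expr.args[1:]:
            out = out | _eval_vector(a, columns)
        return out
    raise TypeError(f"not a LogicExpr: {expr!r}")


def _free_columns(net: BooleanNetwork, idx: np.ndarray) -> dict[str, np.ndarray]:
    """Node-name -> uint8 column for an array of free-state indices."""
    cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(net.free_nodes):
        cols[name] = ((idx >> j) & 1).astype(np.uint8)
    for name, v in net.clamps.items():
        cols[name] = np.full(idx.shape, v, dtype=np.uint8)
    return cols


def free_index_to_state(net: BooleanNetwork, idx: int) -> NetworkState:
    """Unpack a free-state index into a full :class:`NetworkState`."""
    bits = 0
    for j, name in enumerate(net.free_nodes):
        if (idx >> j) & 1:
            bits |= 1 << net.index[name]
    for name, v in net.clamps.items():
        if v:
            bits |= 1 << net.index[name]
    return NetworkState(net, bits)


def state_to_free_index(net: BooleanNetwork, state: NetworkState) -> int:
    idx = 0
    for j, name in enumerate(net.free_nodes):
        if state[name]:
            idx |= 1 << j
    return idx


def successor_table(net: BooleanNetwork) -> np.ndarray:
    """Asynchronous successor table over free-state indices.

    Entry ``[s, j]`` is the index reached from ``s`` by updating free node
    ``j`` (equal to ``s`` when that node is stable). Shape ``(2**f, f)``.
    """
    f = net.n_free
    if f == 0:
        return np.zeros((1, 0), dtype=np.int64)
    idx = np.arange(1 << f, dtype=np.int64)
    cols = _free_columns(net, idx)
    table = np.empty((1 << f, f), dtype=np.int64)
    for j, name in enumerate(net.free_nodes):
        val = _eval_vector(net.functions[name], cols).astype(np.int64)
        table[:, j] = (idx & ~(1 << j)) | (val << j)
    return table


def fixed_point_mask(net: BooleanNetwork, table: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask over free-state indices marking fixed points."""
    if table is None:
        table = successor_table(net)
    idx = np.arange(table.shape[0], dtype=np.int64)
    if table.shape[1] == 0:
        return np.ones(1, dtype=bool)
    return (table == idx[:, None]).all(axis=1)


def enumerate_fixed_points(
    net: BooleanNetwork, guard: int = FIXED_POINT_GUARD
) -> list[NetworkState]:
    """All states with ``f(x) = x`` under the clamps, ascending by index."""
    f = net.n_free
    if f > guard:
        raise StateSpaceTooLargeError(f, guard, "fixed-point enumeration")
    if f == 0:
        return [free_index_to_state(net, 0)]
    found: list[int] = []
    for start in range(0, 1 << f, _CHUNK):
        idx = np.arange(start, min(start + _CHUNK, 1 << f), dtype=np.int64)
        cols = _free_columns(net, idx)
        stable = np.ones(idx.shape, dtype=bool)
        for j, name in enumerate(net.free_nodes):
            val = _eval_vector(net.functions[name], cols)
            stable &= val == cols[name]
            if not stable.any():
                break
        found.extend(int(i) for i in idx[stable])
    return [free_index_to_state(net, i) for i in found]


@dataclass(frozen=True)
class Attractor:
    """A terminal SCC of the asynchronous state transition graph."""

    states: tuple[NetworkState, ...]  # sorted by packed bits
    is_steady: bool

    @property
    def size(self) -> int:
        return len(self.states)

    def __contains__(self, state: NetworkState) -> bool:
        return state in self.states

    def __hash__(self) -> int:
        return hash(tuple(s.bits for s in self.states))

    def __repr__(self) -> str:  # pragma: no cover
        kind = "steady" if self.is_steady else f"cyclic[{self.size}]"
        return f"Attractor({kind}, {self.states[0]!r})"


def find_attractors(net: BooleanNetwork, guard: int = ATTRACTOR_GUARD) -> list[Attractor]:
    """All attractors (terminal SCCs) of the asynchronous dynamics.

    Fixed points appear as singleton steady attractors; cyclic attractors
    are detected exactly via SCC condensation. Ordered lexicographically by
    the packed bits of their first state.
    """
    f = net.n_free
    if f > guard:
        raise StateSpaceTooLargeError(f, guard, "attractor search")
    table = successor_table(net)
    n_states = table.shape[0]
    if f == 0:
        return [Attractor((free_index_to_state(net, 0),), True)]
    src = np.repeat(np.arange(n_states, dtype=np.int64), f)
    dst = table.ravel()
    moving = src != dst  # self-loops are irrelevant to SCC structure
    adj = sp.csr_matrix(
        (np.ones(int(moving.sum()), dtype=np.int8), (src[moving], dst[moving])),
        shape=(n_states, n_states),
    )
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    terminal = np.ones(n_comp, dtype=bool)
    cross = labels[src[moving]] != labels[dst[moving]]
    terminal[labels[src[moving]][cross]] = False
    attractors = []
    for comp in np.flatnonzero(terminal):
        members = np.flatnonzero(labels == comp)
        states = tuple(free_index_to_state(net, int(i)) for i in members)
        attractors.append(Attractor(states, is_steady=len(states) == 1))
    return sorted(attractors, key=lambda a: a.states[0].bits)


def reachable_attractors(
    net: BooleanNetwork, start: NetworkState, guard: int = ATTRACTOR_GUARD
) -> list[Attractor]:
    """Attractors intersecting the forward-reachable set of ``start``."""
    f = net.n_free
    if f > guard:
        raise StateSpaceTooLargeError(f, guard, "reachability analysis")
    table = successor_table(net)
    visited = np.zeros(table.shape[0], dtype=bool)
    frontier = np.array([state_to_free_index(net, start)], dtype=np.int64)
    visited[frontier] = True
    while frontier.size:
        nxt = np.unique(table[frontier].ravel())
        frontier = nxt[~visited[nxt]]
        visited[frontier] = True
    out = []
    for att in find_attractors(net, guard=guard):
        if any(visited[state_to_free_index(net, s)] for s in att.states):
            out.append(att)
    return out


@dataclass
class StateTransitionGraph:
    """The full asynchronous STG over free-state indices (self-loops kept)."""

    network: BooleanNetwork
    graph: "object"  # networkx.DiGraph with int free-index nodes

    def state(self, idx: int) -> NetworkState:
        return free_index_to_state(self.network, idx)

    def label(self, idx: int) -> str:
        s = self.state(idx)
        return ",".join(f"{n}={s[n]}" for n in self.network.free_nodes)


def build_stg(net: BooleanNetwork, guard: int = STG_GUARD) -> StateTransitionGraph:
    """Materialise the full STG (2^f vertices, out-degree = free count)."""
    import networkx as nx

    f = net.n_free
    if f > guard:
        raise StateSpaceTooLargeError(f, guard, "STG construction")
    table = successor_table(net)
    g = nx.DiGraph()
    g.add_nodes_from(range(table.shape[0]))
    if f > 0:
        src = np.repeat(np.arange(table.shape[0], dtype=np.int64), f)
        g.add_edges_from(zip(src.tolist(), table.ravel().tolist()))
    else:
        g.add_edge(0, 0)
    return StateTransitionGraph(net, g)
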