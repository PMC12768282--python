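"""Markov-chain simulation of heterogeneous cell populations.

Each simulated cell starts from a uniform-random assignment of the free
nodes (inputs clamped per condition) and repeatedly applies the update of
one uniformly chosen node — probability ``1/n`` over *all* nodes, so stable
and clamped choices are retained as null steps — until it sits in a fixed
point of the clamped network. Terminal states are classified with the
model's cell-type signatures.

Seeding scheme (v1): the master seed feeds a ``numpy`` ``SeedSequence``;
child sequences are spawned per condition in the model's declared condition
order, and all draws within a condition come from that child generator in a
fixed vectorised order. Identical master seeds give identical counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attractors import (
    fixed_point_mask,
    free_index_to_state,
    state_to_free_index,
    successor_table,
)
from .logic import BooleanNetwork, NetworkState, evaluate
from .models import ModelDefinition, classify_attractor

__all__ = [
    "SimulationConfig",
    "CellRun",
    "AbsorptionCounts",
    "LineageFidelity",
    "NonConvergenceError",
    "simulate_cell",
    "simulate_population",
    "lineage_fraction",
]

SEED_SCHEME = "v1"
_VECTOR_GUARD = 20  # free nodes above this fall back to the per-cell loop


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a population run."""

    runs: int = 100_000
    seed: int = 0
    max_steps: int | None = None  # default 10_000 * n nodes

    def __post_init__(self) -> None:
        if self.runs <= 0:
            raise ValueError("runs must be positive")

    def step_budget(self, n_nodes: int) -> int:
        return self.max_steps if self.max_steps is not None else 10_000 * n_nodes


@dataclass
class CellRun:
    """Outcome of a single cell's walk to absorption."""

    state: NetworkState
    steps: int
    converged: bool


def simulate_cell(
    net: BooleanNetwork,
    start: NetworkState,
    rng: np.random.Generator,
    max_steps: int | None = None,
) -> CellRun:
    """Walk one cell to a fixed point with uniform single-node updates.

    Termination is detected by an incrementally maintained set of unstable
    nodes, not by "no change this step", so null steps cannot end a run
    early. A cell still unstable after ``max_steps`` draws is flagged
    non-converged.
    """
    budget = max_steps if max_steps is not None else 10_000 * net.n
    nodes = net.nodes
    free = set(net.free_nodes)
    # free node -> free nodes whose update function reads it
    dependents: dict[str, list[str]] = {n: [] for n in nodes}
    for n in net.free_nodes:
        for v in net.functions[n].variables():
            dependents[v].append(n)

    bits = start.bits

    def stable(node: str) -> bool:
        return evaluate(net.functions[node], _Lookup(net, bits)) == (bits >> net.index[node]) & 1

    unstable = {n for n in free if not stable(n)}
    steps = 0
    while unstable and steps < budget:
        node = nodes[int(rng.integers(net.n))]
        steps += 1
        if node not in unstable:
            continue  # null step: clamped, stable or already at its target
        i = net.index[node]
        bits ^= 1 << i
        unstable.discard(node)
        for dep in dependents[node]:
            if dep in free:
                if stable(dep):
                    unstable.discard(dep)
                else:
                    unstable.add(dep)
    return CellRun(NetworkState(net, bits), steps, converged=not unstable)


class _Lookup:
    __slots__ = ("net", "bits")

    def __init__(self, net: BooleanNetwork, bits: int):
        self.net = net
        self.bits = bits

    def __getitem__(self, name: str) -> int:
        return (self.bits >> self.net.index[name]) & 1


class NonConvergenceError(RuntimeError):
    """Raised when strict mode encounters non-absorbed cells."""


@dataclass
class AbsorptionCounts:
    """Per-condition counts of absorbed cells by cell-type label."""

    counts: dict[str, dict[str, int]]  # condition name -> label -> count
    non_converged: dict[str, int]
    runs: int
    seed: int
    seed_scheme: str = SEED_SCHEME

    def total(self, condition: str) -> int:
        return sum(self.counts[condition].values()) + self.non_converged[condition]

    def to_frame(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        if labels is None:
            labels = sorted({l for c in self.counts.values() for l in c})
        rows = []
        for cond, by_label in self.counts.items():
            row = {"condition": cond}
            row.update({l: by_label.get(l, 0) for l in labels})
            row["non_converged"] = self.non_converged[cond]
            rows.append(row)
        return pd.DataFrame(rows).set_index("condition")


def _classify_indices(
    net: BooleanNetwork, model: ModelDefinition, idx: np.ndarray
) -> np.ndarray:
    """Signature label index per free-state index (-1 = unclassified)."""
    cols = {}
    for j, name in enumerate(net.free_nodes):
        cols[name] = ((idx >> j) & 1).astype(np.uint8)
    for name, v in net.clamps.items():
        cols[name] = np.full(idx.shape, v, dtype=np.uint8)
    label = np.full(idx.shape, -1, dtype=np.int64)
    hits = np.zeros(idx.shape, dtype=np.int64)
    for s, sig in enumerate(model.signatures):
        mask = np.ones(idx.shape, dtype=bool)
        for node, value in sig.require.items():
            mask &= cols[node] == value
        hits += mask
        label[mask] = s
    if (hits > 1).any():
        raise ValueError("cell-type signatures are not mutually exclusive here")
    return label


def _simulate_condition_vectorised(
    net: BooleanNetwork,
    model: ModelDefinition,
    runs: int,
    rng: np.random.Generator,
    budget: int,
) -> tuple[dict[str, int], int]:
    f = net.n_free
    table = successor_table(net)
    fp = fixed_point_mask(net, table)
    node_to_free = np.full(net.n, -1, dtype=np.int64)
    for j, name in enumerate(net.free_nodes):
        node_to_free[net.index[name]] = j

    idx = rng.integers(0, 1 << f, size=runs, dtype=np.int64) if f else np.zeros(runs, np.int64)
    active = np.flatnonzero(~fp[idx])
    steps = 0
    while active.size and steps < budget:
        steps += 1
        choice = rng.integers(0, net.n, size=active.size)
        sel = node_to_free[choice]
        upd = sel >= 0
        rows = active[upd]
        idx[rows] = table[idx[rows], sel[upd]]
        active = active[~fp[idx[active]]]

    converged = np.ones(runs, dtype=bool)
    converged[active] = False
    labels = _classify_indices(net, model, idx[converged])
    names = [sig.label for sig in model.signatures] + ["unclassified"]
    counts: dict[str, int] = {}
    for s, name in enumerate(names):
        key = s if name != "unclassified" else -1
        c = int((labels == key).sum())
        if c:
            counts[name] = counts.get(name, 0) + c
    return counts, int(active.size)


def simulate_population(
    model: ModelDefinition,
    config: SimulationConfig,
    conditions: Sequence[str] | None = None,
    strict: bool = False,
) -> AbsorptionCounts:
    """Run ``config.runs`` cells per condition and count terminal cell types.

    ``conditions`` selects a subset of the model's named conditions (default
    all, in declared order). With ``strict=True`` any non-converged cell —
    the signature of a cyclic attractor or an exhausted step budget — raises
    :class:`NonConvergenceError` instead of only being counted.
    """
    chosen = [
        c for c in model.conditions if conditions is None or c.name in conditions
    ]
    if conditions is not None and len(chosen) != len(conditions):
        known = {c.name for c in model.conditions}
        raise KeyError(f"unknown condition(s): {sorted(set(conditions) - known)}")
    children = np.random.SeedSequence(config.seed).spawn(len(model.conditions))
    by_index = {c.name: i for i, c in enumerate(model.conditions)}

    counts: dict[str, dict[str, int]] = {}
    non_conv: dict[str, int] = {}
    for cond in chosen:
        net = model.clamped_network(cond.levels)
        rng = np.random.default_rng(children[by_index[cond.name]])
        budget = config.step_budget(net.n)
        if net.n_free <= _VECTOR_GUARD:
            c, nc = _simulate_condition_vectorised(net, model, config.runs, rng, budget)
        else:  # pragma: no cover - packaged models never reach this
            c, nc = {}, 0
            for _ in range(config.runs):
                from .synth import random_initial_state

                run = simulate_cell(net, random_initial_state(net, rng), rng, budget)
                if not run.converged:
                    nc += 1
                    continue
                label = classify_attractor(run.state, model.signatures)
                c[label] = c.get(label, 0) + 1
        counts[cond.name] = c
        non_conv[cond.name] = nc
        if strict and nc:
            raise NonConvergenceError(
                f"{nc} of {config.runs} cells did not absorb under {cond.name}"
            )
    return AbsorptionCounts(counts, non_conv, config.runs, config.seed)


@dataclass(frozen=True)
class LineageFidelity:
    """Fraction of cells absorbing into their condition's expected lineage."""

    fraction: float
    standard_error: float
    matched: int
    total: int


def lineage_fraction(
    counts: AbsorptionCounts,
    expected_map: Mapping[str, str],
) -> LineageFidelity:
    """Pooled expected-lineage fraction with a binomial standard error.

    ``expected_map`` maps condition name to the expected cell-type label;
    it must cover every simulated condition. Non-converged cells count
    against the fraction.
    """
    missing = set(counts.counts) - set(expected_map)
    if missing:
        raise KeyError(f"expected_map misses condition(s): {sorted(missing)}")
    matched = sum(
        counts.counts[cond].get(expected_map[cond], 0) for cond in counts.counts
    )
    total = sum(counts.total(cond) for cond in counts.counts)
    p = matched / total
    se = float(np.sqrt(p * (1 - p) / total))
    return LineageFidelity(p, se, matched, total)
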