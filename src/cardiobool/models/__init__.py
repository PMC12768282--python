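"""Packaged cardiac network definitions and their steady-state validation.

Three models ship as ``.bnet`` files plus a JSON sidecar (inputs, cell-type
signatures, expected steady-state tables, provenance):

``cm_subtype``
    9-node atrial-vs-ventricular commitment network (inputs NOTCH, RA,
    GATA4/6); two steady states, aCM and vCM.
``heart_field``
    11-node first-vs-second heart field network (inputs ex_WNT, ex_BMP2);
    steady states FHF, SHF and the GATA4/6-silent null state.
``unified``
    21-node combination of the two, linked through the shared GATA4/6 node
    and an NKX2-5 -> IRX4 edge; five steady states across the four
    (WNT, RA) signaling conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

from ..attractors import Attractor, find_attractors
from ..io import parse_bnet
from ..logic import BooleanNetwork, NetworkState, canonical_name

__all__ = [
    "MODEL_NAMES",
    "CellTypeSignature",
    "Condition",
    "SteadyStateTable",
    "ModelDefinition",
    "load_model",
    "classify_attractor",
    "ClassificationAmbiguityError",
    "TableVerificationReport",
    "verify_steady_state_tables",
]

MODEL_NAMES = ("cm_subtype", "heart_field", "unified")


@dataclass(frozen=True)
class CellTypeSignature:
    """A cell-type label with its marker constraints (partial assignment)."""

    label: str
    require: Mapping[str, int]

    def matches(self, state: NetworkState, ignore: frozenset[str] = frozenset()) -> bool:
        return all(
            state[node] == value
            for node, value in self.require.items()
            if canonical_name(node) not in ignore
        )


@dataclass(frozen=True)
class Condition:
    """A named clamp condition, e.g. ``WNT=0,RA=1``."""

    name: str
    levels: Mapping[str, int]  # axis label -> 0/1
    expected_lineage: str


@dataclass(frozen=True)
class ExpectedState:
    label: str
    condition: Mapping[str, int]  # axis label -> level
    state: Mapping[str, int]  # node -> bit (partial for the unified table)


@dataclass(frozen=True)
class SteadyStateTable:
    """The published steady states, one row per (condition, state)."""

    rows: tuple[ExpectedState, ...]

    def conditions(self) -> list[Mapping[str, int]]:
        seen: list[Mapping[str, int]] = []
        for row in self.rows:
            if row.condition not in seen:
                seen.append(row.condition)
        return seen


@dataclass
class ModelDefinition:
    """A packaged network plus its inputs, signatures and expected tables."""

    name: str
    network: BooleanNetwork
    inputs: tuple[str, ...]
    fixed_inputs: Mapping[str, int]
    condition_axes: Mapping[str, str]  # axis label ("WNT") -> node ("EX_WNT")
    conditions: tuple[Condition, ...]
    signatures: tuple[CellTypeSignature, ...]
    steady_state_table: SteadyStateTable
    provenance: Mapping[str, object] = field(default_factory=dict)

    def clamps_for(self, levels: Mapping[str, int]) -> dict[str, int]:
        """Clamp map for a condition: fixed inputs plus the axis levels."""
        clamps = {canonical_name(k): v for k, v in self.fixed_inputs.items()}
        for axis, value in levels.items():
            node = self.condition_axes.get(axis)
            if node is None:
                raise KeyError(f"model {self.name!r} has no condition axis {axis!r}")
            clamps[canonical_name(node)] = int(value)
        return clamps

    def clamped_network(self, levels: Mapping[str, int]) -> BooleanNetwork:
        return self.network.with_clamps(self.clamps_for(levels))

    def signature(self, label: str) -> CellTypeSignature:
        for sig in self.signatures:
            if sig.label == label:
                return sig
        raise KeyError(label)


def _load_data(name: str) -> tuple[str, dict]:
    pkg = resources.files(__package__) / "data"
    bnet = (pkg / f"{name}.bnet").read_text()
    meta = json.loads((pkg / f"{name}.json").read_text())
    return bnet, meta


def load_model(name: str) -> ModelDefinition:
    """Load one of the packaged models by name."""
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    bnet, meta = _load_data(name)
    network = parse_bnet(bnet)
    table = SteadyStateTable(
        tuple(
            ExpectedState(
                label=row["label"],
                condition=dict(row["condition"]),
                state={canonical_name(k): v for k, v in row["state"].items()},
            )
            for row in meta["steady_state_table"]
        )
    )
    return ModelDefinition(
        name=name,
        network=network,
        inputs=tuple(canonical_name(i) for i in meta["inputs"]),
        fixed_inputs={canonical_name(k): v for k, v in meta["fixed_inputs"].items()},
        condition_axes=dict(meta["condition_axes"]),
        conditions=tuple(
            Condition(c["name"], dict(c["levels"]), c["expected_lineage"])
            for c in meta["conditions"]
        ),
        signatures=tuple(
            CellTypeSignature(s["label"], {canonical_name(k): v for k, v in s["require"].items()})
            for s in meta["signatures"]
        ),
        steady_state_table=table,
        provenance=meta.get("provenance", {}),
    )


class ClassificationAmbiguityError(ValueError):
    """Two signatures matched one steady state (signature set not exclusive)."""


def classify_attractor(
    state: NetworkState,
    signatures: tuple[CellTypeSignature, ...],
    ignore: frozenset[str] = frozenset(),
) -> str:
    """Label a steady state by the unique matching signature.

    Nodes in ``ignore`` (e.g. those fixed by an active perturbation) are
    excluded from signature matching. Returns ``"unclassified"`` when no
    signature matches.
    """
    ignore = frozenset(canonical_name(n) for n in ignore)
    matched = [s.label for s in signatures if s.matches(state, ignore)]
    if len(matched) > 1:
        raise ClassificationAmbiguityError(
            f"state matches multiple signatures: {matched}"
        )
    return matched[0] if matched else "unclassified"


@dataclass
class TableRowResult:
    condition: Mapping[str, int]
    label: str
    found: bool


@dataclass
class TableVerificationReport:
    """Per-condition comparison of model attractors with the expected table."""

    model: str
    rows: list[TableRowResult]
    unexpected: list[tuple[Mapping[str, int], Attractor]]
    non_steady: list[tuple[Mapping[str, int], Attractor]]

    @property
    def passed(self) -> bool:
        return (
            all(r.found for r in self.rows)
            and not self.unexpected
            and not self.non_steady
        )

    def summary(self) -> str:
        n_ok = sum(r.found for r in self.rows)
        lines = [f"{self.model}: {n_ok}/{len(self.rows)} expected states found"]
        for r in self.rows:
            cond = ",".join(f"{k}={v}" for k, v in r.condition.items())
            lines.append(f"  [{'ok' if r.found else 'MISSING'}] {r.label} under {cond}")
        for cond, att in self.unexpected:
            c = ",".join(f"{k}={v}" for k, v in cond.items())
            lines.append(f"  [UNEXPECTED] attractor under {c}: {att!r}")
        for cond, att in self.non_steady:
            c = ",".join(f"{k}={v}" for k, v in cond.items())
            lines.append(f"  [CYCLIC] non-steady attractor under {c}: {att!r}")
        lines.append("PASS" if self.passed else "FAIL")
        return "\n".join(lines)


def verify_steady_state_tables(
    model: ModelDefinition, table: SteadyStateTable | None = None
) -> TableVerificationReport:
    """Check the packaged network against an expected steady-state table.

    For each clamp condition appearing in the table: every expected row must
    be realised by a steady attractor agreeing on all listed nodes, every
    attractor must match some expected row, and no cyclic attractor may
    exist.
    """
    if table is None:
        table = model.steady_state_table
    rows: list[TableRowResult] = []
    unexpected: list[tuple[Mapping[str, int], Attractor]] = []
    non_steady: list[tuple[Mapping[str, int], Attractor]] = []
    for cond in table.conditions():
        net = model.clamped_network(cond)
        attractors = find_attractors(net)
        expected_here = [r for r in table.rows if r.condition == cond]
        matched_atts: set[int] = set()
        for row in expected_here:
            hit = False
            for i, att in enumerate(attractors):
                if att.is_steady and att.states[0].satisfies(row.state):
                    hit = True
                    matched_atts.add(i)
            rows.append(TableRowResult(cond, row.label, hit))
        for i, att in enumerate(attractors):
            if not att.is_steady:
                non_steady.append((cond, att))
            elif i not in matched_atts:
                unexpected.append((cond, att))
    return TableVerificationReport(model.name, rows, unexpected, non_steady)
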