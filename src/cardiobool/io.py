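"""File formats and run provenance.

The canonical model format is the BoolNet ``.bnet`` dialect: a
``targets, factors`` header followed by one ``NODE, RULE`` line per node,
with ``&``/``|``/``!`` operators and 0/1 constants. State transition graphs
export to DOT and GraphML; every CLI run emits a :class:`RunManifest`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from .attractors import StateTransitionGraph
from .logic import (
    BooleanNetwork,
    Const,
    ParseError,
    UnknownNodeError,
    canonical_name,
    format_expression,
    parse_expression,
)

__all__ = [
    "BnetFormatError",
    "read_bnet",
    "parse_bnet",
    "write_bnet",
    "export_stg_dot",
    "export_stg_graphml",
    "RunManifest",
]


class BnetFormatError(ValueError):
    """Malformed .bnet file; message carries the offending line number."""


def parse_bnet(text: str) -> BooleanNetwork:
    """Parse ``.bnet`` text into a network (declaration order = file order)."""
    rules: list[tuple[str, str, int]] = []
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not header_seen:
            if line.lower().replace(" ", "") != "targets,factors":
                raise BnetFormatError(
                    f"line {lineno}: expected 'targets, factors' header, got {line!r}"
                )
            header_seen = True
            continue
        if "," not in line:
            raise BnetFormatError(f"line {lineno}: expected 'target, factors'")
        target, factors = line.split(",", 1)
        rules.append((canonical_name(target), factors.strip(), lineno))
    if not header_seen:
        raise BnetFormatError("missing 'targets, factors' header")

    nodes = []
    seen = set()
    for name, _, lineno in rules:
        if name in seen:
            raise BnetFormatError(f"line {lineno}: duplicate target {name!r}")
        seen.add(name)
        nodes.append(name)

    functions = {}
    for name, factors, lineno in rules:
        try:
            functions[name] = parse_expression(factors, nodes)
        except UnknownNodeError as e:
            raise BnetFormatError(f"line {lineno}: undeclared factor {e.name!r}") from e
        except ParseError as e:
            raise BnetFormatError(f"line {lineno}: {e}") from e
    return BooleanNetwork(nodes, functions)


def read_bnet(path: str | Path) -> BooleanNetwork:
    """Read a network from a ``.bnet`` file."""
    return parse_bnet(Path(path).read_text())


def write_bnet(net: BooleanNetwork) -> str:
    """Serialise a network; re-reading gives a truth-table-equivalent model.

    Clamped nodes are written as their clamp constant with the original rule
    preserved in a trailing comment.
    """
    lines = ["targets, factors"]
    for node in net.nodes:
        if node in net.clamps:
            original = format_expression(net.functions[node])
            lines.append(f"{node}, {net.clamps[node]}  # clamped (rule: {original})")
        else:
            lines.append(f"{node}, {format_expression(net.functions[node])}")
    return "\n".join(lines) + "\n"


def network_checksum(net: BooleanNetwork) -> str:
    """SHA-256 of the canonical serialisation (used in run manifests)."""
    return hashlib.sha256(write_bnet(net).encode()).hexdigest()


# ---------------------------------------------------------------------------
# STG export
# ---------------------------------------------------------------------------


def export_stg_dot(stg: StateTransitionGraph, hide_self_loops: bool = True) -> str:
    """Render an STG as a DOT digraph with ``node=value`` vertex labels."""
    out = ["digraph STG {", '  node [shape=box, fontname="monospace"];']
    for idx in stg.graph.nodes:
        out.append(f'  s{idx} [label="{stg.label(idx)}"];')
    for u, v in stg.graph.edges:
        if hide_self_loops and u == v:
            continue
        out.append(f"  s{u} -> s{v};")
    out.append("}")
    return "\n".join(out) + "\n"


def export_stg_graphml(stg: StateTransitionGraph, hide_self_loops: bool = True) -> str:
    """Render an STG as GraphML (same topology as the DOT export)."""
    import networkx as nx

    g = nx.DiGraph()
    for idx in stg.graph.nodes:
        g.add_node(f"s{idx}", label=stg.label(idx))
    for u, v in stg.graph.edges:
        if hide_self_loops and u == v:
            continue
        g.add_edge(f"s{u}", f"s{v}")
    return "\n".join(nx.generate_graphml(g)) + "\n"


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Provenance record emitted by every CLI run."""

    command: str
    model: str | None = None
    model_checksum: str | None = None
    seed: int | None = None
    parameters: dict = field(default_factory=dict)
    package_version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.package_version:
            from . import __version__

            self.package_version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())
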