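"""Boolean expressions, networks, states and update semantics.

Everything downstream (attractor search, population simulation, the
continuous extension) is built on the small algebra defined here: an
expression tree over ``AND``/``OR``/``NOT``/literals/constants, a
:class:`BooleanNetwork` mapping each node to one update function, and a
:class:`NetworkState` holding one bit per node.

Node names are normalised to a canonical form (uppercase; ``/``, ``-`` and
``.`` become ``_``) and a small alias table maps printed synonyms such as
``COUP-TFII`` onto their canonical gene symbol (``NR2F2``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Mapping, Sequence

__all__ = [
    "ALIASES",
    "canonical_name",
    "LogicExpr",
    "Const",
    "Var",
    "Not",
    "And",
    "Or",
    "ParseError",
    "UnknownNodeError",
    "parse_expression",
    "format_expression",
    "evaluate",
    "BooleanNetwork",
    "NetworkState",
    "Perturbation",
    "PerturbationConflictError",
    "sync_step",
    "async_successors",
    "apply_perturbation",
]

#: Printed synonyms -> canonical node id (applied after `canonical_name`).
ALIASES: dict[str, str] = {
    "COUP_TFII": "NR2F2",
    "COUPTFII": "NR2F2",
    "COUPTF_II": "NR2F2",
    "GATAS": "GATA4_6",
    "GATA4": "GATA4_6",
    "GATA6": "GATA4_6",
    "GATA": "GATA4_6",
    "NKX2.5": "NKX2_5",
    "FOXC1": "FOXC1_2",
    "FOXC2": "FOXC1_2",
    "EXWNT": "EX_WNT",
    "EXBMP2": "EX_BMP2",
    "EXFGF8": "EX_FGF8",
}


def canonical_name(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Normalise a node identifier and resolve printed synonyms.

    ``GATA4/6`` and ``GATA4_6`` map to the same id, as do ``NKX2-5`` and
    ``NKX2_5``; ``COUP-TFII`` resolves to ``NR2F2``.
    """
    canon = re.sub(r"[/\-.]", "_", name.strip()).upper()
    table = ALIASES if aliases is None else aliases
    return table.get(canon, canon)


# ---------------------------------------------------------------------------
# Expression trees
# ---------------------------------------------------------------------------


class LogicExpr:
    """Base class for Boolean expression trees."""

    __slots__ = ()

    def variables(self) -> frozenset[str]:
        """All node names referenced by this expression."""
        out: set[str] = set()
        _collect_vars(self, out)
        return frozenset(out)

    def __and__(self, other: "LogicExpr") -> "LogicExpr":
        return And((self, other))

    def __or__(self, other: "LogicExpr") -> "LogicExpr":
        return Or((self, other))

    def __invert__(self) -> "LogicExpr":
        return Not(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({format_expression(self)!r})"


@dataclass(frozen=True, repr=False)
class Const(LogicExpr):
    value: int

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError(f"constant must be 0 or 1, got {self.value!r}")


@dataclass(frozen=True, repr=False)
class Var(LogicExpr):
    name: str


@dataclass(frozen=True, repr=False)
class Not(LogicExpr):
    operand: LogicExpr


@dataclass(frozen=True, repr=False)
class And(LogicExpr):
    args: tuple[LogicExpr, ...]


@dataclass(frozen=True, repr=False)
class Or(LogicExpr):
    args: tuple[LogicExpr, ...]


def _collect_vars(expr: LogicExpr, out: set[str]) -> None:
    if isinstance(expr, Var):
        out.add(expr.name)
    elif isinstance(expr, Not):
        _collect_vars(expr.operand, out)
    elif isinstance(expr, (And, Or)):
        for a in expr.args:
            _collect_vars(a, out)


def evaluate(expr: LogicExpr, state: "NetworkState | Mapping[str, int]") -> int:
    """Evaluate an expression under a state (standard Boolean semantics)."""
    return _eval(expr, state.__getitem__)


def _eval(expr: LogicExpr, lookup: Callable[[str], int]) -> int:
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Var):
        return int(lookup(expr.name))
    if isinstance(expr, Not):
        return 1 - _eval(expr.operand, lookup)
    if isinstance(expr, And):
        for a in expr.args:
            if not _eval(a, lookup):
                return 0
        return 1
    if isinstance(expr, Or):
        for a in expr.args:
            if _eval(a, lookup):
                return 1
        return 0
    raise TypeError(f"not a LogicExpr: {expr!r}")


# ---------------------------------------------------------------------------
# Parser (BoolNet dialect: &, |, ! with parentheses; NOT > AND > OR)
# ---------------------------------------------------------------------------


class ParseError(ValueError):
    """Malformed rule text; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UnknownNodeError(KeyError):
    """An identifier did not resolve to a declared node."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:
        return f"unknown node identifier: {self.name!r}"


_TOKEN_RE = re.compile(r"\s*(?:(?P<op>[&|!()])|(?P<const>[01])(?![\w./-])|(?P<ident>[A-Za-z_][\w./-]*))")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ParseError(f"unexpected character {text[pos:].lstrip()[0]!r}", pos)
        if m.lastgroup == "op":
            tokens.append(("op", m.group("op"), m.start("op")))
        elif m.lastgroup == "const":
            tokens.append(("const", m.group("const"), m.start("const")))
        else:
            tokens.append(("ident", m.group("ident"), m.start("ident")))
        pos = m.end()
    return tokens


def parse_expression(
    text: str,
    declared_nodes: Iterable[str] | None = None,
    aliases: Mapping[str, str] | None = None,
) -> LogicExpr:
    """Parse a rule string into a :class:`LogicExpr`.

    Operators are ``&`` (AND), ``|`` (OR), ``!`` (NOT) with the usual
    precedence NOT > AND > OR; identifiers are normalised and aliased.
    When ``declared_nodes`` is given, every literal must resolve to one of
    them (after normalisation) or :class:`UnknownNodeError` is raised.
    """
    declared = None
    if declared_nodes is not None:
        declared = {canonical_name(n, aliases) for n in declared_nodes}

    tokens = _tokenize(text)
    if not tokens:
        raise ParseError("empty expression", 0)
    out, idx = _parse_or(tokens, 0, declared, aliases)
    if idx != len(tokens):
        raise ParseError(f"unexpected token {tokens[idx][1]!r}", tokens[idx][2])
    return out


def _parse_or(tokens, idx, declared, aliases):
    left, idx = _parse_and(tokens, idx, declared, aliases)
    args = [left]
    while idx < len(tokens) and tokens[idx][:2] == ("op", "|"):
        nxt, idx = _parse_and(tokens, idx + 1, declared, aliases)
        args.append(nxt)
    return (args[0] if len(args) == 1 else Or(tuple(args))), idx


def _parse_and(tokens, idx, declared, aliases):
    left, idx = _parse_unary(tokens, idx, declared, aliases)
    args = [left]
    while idx < len(tokens) and tokens[idx][:2] == ("op", "&"):
        nxt, idx = _parse_unary(tokens, idx + 1, declared, aliases)
        args.append(nxt)
    return (args[0] if len(args) == 1 else And(tuple(args))), idx


def _parse_unary(tokens, idx, declared, aliases):
    if idx >= len(tokens):
        last = tokens[-1][2] + len(tokens[-1][1]) if tokens else 0
        raise ParseError("unexpected end of expression", last)
    kind, value, pos = tokens[idx]
    if (kind, value) == ("op", "!"):
        operand, idx = _parse_unary(tokens, idx + 1, declared, aliases)
        return Not(operand), idx
    if (kind, value) == ("op", "("):
        inner, idx = _parse_or(tokens, idx + 1, declared, aliases)
        if idx >= len(tokens) or tokens[idx][:2] != ("op", ")"):
            raise ParseError("unclosed parenthesis", pos)
        return inner, idx + 1
    if kind == "const":
        return Const(int(value)), idx + 1
    if kind == "ident":
        name = canonical_name(value, aliases)
        if declared is not None and name not in declared:
            raise UnknownNodeError(value)
        return Var(name), idx + 1
    raise ParseError(f"unexpected token {value!r}", pos)


def format_expression(expr: LogicExpr) -> str:
    """Serialise an expression in the parser's dialect (round-trips)."""
    return _fmt(expr, 0)


def _fmt(expr: LogicExpr, prec: int) -> str:
    # precedence levels: OR=1, AND=2, NOT=3, atoms=4
    if isinstance(expr, Const):
        return str(expr.value)
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Not):
        s = "!" + _fmt(expr.operand, 3)
        return f"({s})" if prec > 3 else s
    if isinstance(expr, And):
        s = " & ".join(_fmt(a, 2) for a in expr.args)
        return f"({s})" if prec > 2 else s
    if isinstance(expr, Or):
        s = " | ".join(_fmt(a, 1) for a in expr.args)
        return f"({s})" if prec > 1 else s
    raise TypeError(f"not a LogicExpr: {expr!r}")


# ---------------------------------------------------------------------------
# Networks and states
# ---------------------------------------------------------------------------


class BooleanNetwork:
    """A Boolean network: ordered nodes, one update function per node, clamps.

    Node order defines bit positions in packed integer states (bit ``i``
    holds node ``i``). Clamped nodes' update functions are overridden by the
    clamp constant and are excluded from the free-node enumeration.
    """

    def __init__(
        self,
        nodes: Sequence[str],
        functions: Mapping[str, LogicExpr],
        clamps: Mapping[str, int] | None = None,
        perturbed: Iterable[str] = (),
    ):
        self.nodes: tuple[str, ...] = tuple(canonical_name(n) for n in nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names after normalisation")
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.nodes)}
        funcs = {canonical_name(k): v for k, v in functions.items()}
        missing = set(self.nodes) - set(funcs)
        extra = set(funcs) - set(self.nodes)
        if missing or extra:
            raise ValueError(
                f"update map must cover the node set exactly "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )
        for n, f in funcs.items():
            undeclared = f.variables() - set(self.nodes)
            if undeclared:
                raise UnknownNodeError(sorted(undeclared)[0])
        self.functions: dict[str, LogicExpr] = {n: funcs[n] for n in self.nodes}
        self.clamps: dict[str, int] = {}
        for k, v in (clamps or {}).items():
            name = canonical_name(k)
            if name not in self.index:
                raise UnknownNodeError(k)
            if v not in (0, 1):
                raise ValueError(f"clamp value must be 0/1, got {v!r}")
            self.clamps[name] = int(v)
        self.perturbed: frozenset[str] = frozenset(canonical_name(p) for p in perturbed)

    # -- basic structure ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def free_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if n not in self.clamps)

    @property
    def n_free(self) -> int:
        return self.n - len(self.clamps)

    def effective_function(self, node: str) -> LogicExpr:
        """Update function with clamps applied (clamped -> constant)."""
        name = canonical_name(node)
        if name in self.clamps:
            return Const(self.clamps[name])
        return self.functions[name]

    def with_clamps(self, clamps: Mapping[str, int]) -> "BooleanNetwork":
        """Return a copy with additional clamps merged in."""
        merged = dict(self.clamps)
        for k, v in clamps.items():
            merged[canonical_name(k)] = int(v)
        return BooleanNetwork(self.nodes, self.functions, merged, self.perturbed)

    # -- states -------------------------------------------------------------

    def state(self, assignment: Mapping[str, int] | int) -> "NetworkState":
        """Build a state from a name->bit mapping or a packed integer.

        Clamped nodes are forced to their clamp value.
        """
        if isinstance(assignment, int):
            bits = assignment
        else:
            bits = 0
            for name, value in assignment.items():
                i = self.index[canonical_name(name)]
                if value:
                    bits |= 1 << i
        for name, value in self.clamps.items():
            i = self.index[name]
            bits = (bits & ~(1 << i)) | (value << i)
        return NetworkState(self, bits)

    def clamp_bits(self) -> tuple[int, int]:
        """(mask, value) of the clamped bit positions."""
        mask = value = 0
        for name, v in self.clamps.items():
            i = self.index[name]
            mask |= 1 << i
            value |= v << i
        return mask, value

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BooleanNetwork)
            and self.nodes == other.nodes
            and self.functions == other.functions
            and self.clamps == other.clamps
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"BooleanNetwork(n={self.n}, free={self.n_free})"


class NetworkState:
    """A fixed-width binary assignment over a network's nodes (bit-packed)."""

    __slots__ = ("network", "bits")

    def __init__(self, network: BooleanNetwork, bits: int):
        if bits < 0 or bits >> network.n:
            raise ValueError(f"state bits out of range for {network.n} nodes")
        self.network = network
        self.bits = bits

    def __getitem__(self, node: str) -> int:
        return (self.bits >> self.network.index[canonical_name(node)]) & 1

    def as_dict(self) -> dict[str, int]:
        return {n: (self.bits >> i) & 1 for i, n in enumerate(self.network.nodes)}

    def satisfies(self, constraints: Mapping[str, int]) -> bool:
        return all(self[k] == v for k, v in constraints.items())

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, NetworkState)
            and self.bits == other.bits
            and self.network.nodes == other.network.nodes
        )

    def __hash__(self) -> int:
        return hash((self.network.nodes, self.bits))

    def __iter__(self) -> Iterator[int]:
        return ((self.bits >> i) & 1 for i in range(self.network.n))

    def __repr__(self) -> str:
        on = [n for n in self.network.nodes if self[n]]
        return f"NetworkState({', '.join(on) or 'all off'})"


# ---------------------------------------------------------------------------
# Update semantics
# ---------------------------------------------------------------------------


def sync_step(net: BooleanNetwork, state: NetworkState) -> NetworkState:
    """Synchronous update: every free node takes its function value at once."""
    bits = 0
    for i, node in enumerate(net.nodes):
        if _eval(net.effective_function(node), state.__getitem__):
            bits |= 1 << i
    return NetworkState(net, bits)


def async_successors(net: BooleanNetwork, state: NetworkState) -> frozenset[NetworkState]:
    """All single-free-node asynchronous successors (de-duplicated).

    The state itself is a member whenever some free node is stable. For a
    network with no free nodes the (fully clamped) state is its own sole
    successor.
    """
    if net.n_free == 0:
        return frozenset({state})
    out = set()
    for node in net.free_nodes:
        i = net.index[node]
        val = _eval(net.functions[node], state.__getitem__)
        out.add(NetworkState(net, (state.bits & ~(1 << i)) | (val << i)))
    return frozenset(out)


@dataclass(frozen=True)
class Perturbation:
    """A knockout (force 0) or overexpression (force 1) of one node."""

    node: str
    mode: str  # "ko" | "oe"

    def __post_init__(self) -> None:
        object.__setattr__(self, "node", canonical_name(self.node))
        if self.mode not in ("ko", "oe"):
            raise ValueError(f"mode must be 'ko' or 'oe', got {self.mode!r}")

    @property
    def value(self) -> int:
        return 0 if self.mode == "ko" else 1

    @classmethod
    def ko(cls, node: str) -> "Perturbation":
        return cls(node, "ko")

    @classmethod
    def oe(cls, node: str) -> "Perturbation":
        return cls(node, "oe")


class PerturbationConflictError(ValueError):
    """The same node carries both a knockout and an overexpression."""


def apply_perturbation(
    net: BooleanNetwork, perturbations: Iterable[Perturbation]
) -> BooleanNetwork:
    """Return a new network with the perturbed nodes fixed to constants.

    Perturbed nodes are treated as clamped (excluded from free-node
    enumeration). Applying the same perturbation twice is idempotent;
    conflicting modes on one node raise :class:`PerturbationConflictError`.
    """
    values: dict[str, int] = {}
    for p in perturbations:
        if p.node not in net.index:
            raise UnknownNodeError(p.node)
        if p.node in values and values[p.node] != p.value:
            raise PerturbationConflictError(
                f"conflicting perturbations on {p.node}: KO and OE"
            )
        values[p.node] = p.value
    if not values:
        return net
    functions = dict(net.functions)
    clamps = dict(net.clamps)
    for node, value in values.items():
        functions[node] = Const(value)
        clamps[node] = value
    return BooleanNetwork(net.nodes, functions, clamps, net.perturbed | set(values))
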