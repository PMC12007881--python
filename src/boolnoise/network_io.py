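"""Parsing, validation and serialization of Boolean networks.

A Boolean network is a set of named binary nodes, each governed by an update
rule: a Boolean expression over the node names with ``!`` (NOT), ``&`` (AND),
``|`` (OR), parentheses, and the constants ``0``/``1``.  Rule files use the
comma-separated "targets, factors" dialect popularised by BoolNet::

    targets, factors
    A, B & !C
    B, A
    C, 1

Node taxonomy
-------------
* *regular* nodes have a genuine Boolean function of other nodes;
* *identity* nodes carry the identity function on themselves (``G, G``) —
  these are input nodes whose value is never rewritten by the dynamics;
* *fixed* nodes have a constant rule (``C, 1``) and are clamped forever.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "BooleanExpression",
    "Var",
    "Const",
    "Not",
    "And",
    "Or",
    "Edge",
    "BooleanNetwork",
    "NetworkFormatError",
    "parse_expression",
    "parse_network",
    "evaluate_rule",
    "extract_edges",
    "write_network",
]


class NetworkFormatError(ValueError):
    """Raised for malformed rule files or inconsistent network definitions."""


# ---------------------------------------------------------------------------
# Expression trees
# ---------------------------------------------------------------------------

class BooleanExpression:
    """Base class for nodes of a Boolean update-rule expression tree."""

    #: precedence used when rendering: OR < AND < NOT < atom
    _prec: int = 3

    def evaluate(self, state: np.ndarray, index: dict[str, int]) -> np.ndarray:
        """Evaluate on a state array of shape ``(..., n)``; returns bools of
        shape ``(...)``.  Works equally on a single state vector and on a
        batch of states (one row per trajectory)."""
        raise NotImplementedError

    def leaves(self) -> Iterator["Var | Const"]:
        yield self  # type: ignore[misc]

    def variables(self) -> list[str]:
        """Distinct referenced node names, in first-occurrence order."""
        seen: dict[str, None] = {}
        for leaf in self.leaves():
            if isinstance(leaf, Var):
                seen.setdefault(leaf.name)
        return list(seen)

    def _render(self) -> str:
        raise NotImplementedError

    def _child_str(self, child: "BooleanExpression") -> str:
        text = child._render()
        return f"({text})" if child._prec < self._prec else text

    def __str__(self) -> str:
        return self._render()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self._render()!r})"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BooleanExpression) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def _key(self) -> tuple:
        raise NotImplementedError


@dataclass(frozen=True, eq=False)
class Var(BooleanExpression):
    name: str
    _prec = 3

    def evaluate(self, state, index):
        return np.asarray(state, dtype=bool)[..., index[self.name]]

    def _render(self):
        return self.name

    def _key(self):
        return ("var", self.name)


@dataclass(frozen=True, eq=False)
class Const(BooleanExpression):
    value: int  # 0 or 1
    _prec = 3

    def evaluate(self, state, index):
        shape = np.asarray(state).shape[:-1]
        return np.full(shape, bool(self.value))

    def _render(self):
        return str(int(self.value))

    def _key(self):
        return ("const", int(self.value))


@dataclass(frozen=True, eq=False)
class Not(BooleanExpression):
    operand: BooleanExpression
    _prec = 2

    def evaluate(self, state, index):
        return ~self.operand.evaluate(state, index)

    def leaves(self):
        yield from self.operand.leaves()

    def _render(self):
        return "!" + self._child_str(self.operand)

    def _key(self):
        return ("not", self.operand._key())


class _NaryOp(BooleanExpression):
    symbol = "?"

    def __init__(self, *operands: BooleanExpression):
        if len(operands) < 2:
            raise ValueError("n-ary operator needs at least two operands")
        # flatten same-operator children: associativity makes A&(B&C) and
        # (A&B)&C the same rule, and the flat form round-trips through text
        flat: list[BooleanExpression] = []
        for op in operands:
            if type(op) is type(self):
                flat.extend(op.operands)  # type: ignore[attr-defined]
            else:
                flat.append(op)
        self.operands = tuple(flat)

    def leaves(self):
        for op in self.operands:
            yield from op.leaves()

    def _render(self):
        return f" {self.symbol} ".join(self._child_str(op) for op in self.operands)

    def _key(self):
        return (self.symbol, tuple(op._key() for op in self.operands))


class And(_NaryOp):
    symbol = "&"
    _prec = 1

    def evaluate(self, state, index):
        out = self.operands[0].evaluate(state, index)
        for op in self.operands[1:]:
            out = out & op.evaluate(state, index)
        return out


class Or(_NaryOp):
    symbol = "|"
    _prec = 0

    def evaluate(self, state, index):
        out = self.operands[0].evaluate(state, index)
        for op in self.operands[1:]:
            out = out | op.evaluate(state, index)
        return out


# ---------------------------------------------------------------------------
# Expression parser (recursive descent; precedence NOT > AND > OR)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_.]*)|(?P<const>[01])"
                       r"|(?P<op>[!&|()]))")


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise NetworkFormatError(
                f"unexpected character {text[pos:].strip()[0]!r} in expression {text!r}")
        tokens.append(m.group(m.lastgroup))  # type: ignore[arg-type]
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[str], source: str):
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise NetworkFormatError(f"unexpected end of expression in {self.source!r}")
        self.pos += 1
        return tok

    def parse(self) -> BooleanExpression:
        expr = self.or_expr()
        if self.peek() is not None:
            raise NetworkFormatError(
                f"trailing token {self.peek()!r} in expression {self.source!r}")
        return expr

    def or_expr(self) -> BooleanExpression:
        terms = [self.and_expr()]
        while self.peek() == "|":
            self.next()
            terms.append(self.and_expr())
        return terms[0] if len(terms) == 1 else Or(*terms)

    def and_expr(self) -> BooleanExpression:
        factors = [self.factor()]
        while self.peek() == "&":
            self.next()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else And(*factors)

    def factor(self) -> BooleanExpression:
        tok = self.next()
        if tok == "!":
            return Not(self.factor())
        if tok == "(":
            expr = self.or_expr()
            if self.next() != ")":
                raise NetworkFormatError(f"unbalanced parentheses in {self.source!r}")
            return expr
        if tok in ("0", "1"):
            return Const(int(tok))
        if tok in ("&", "|", ")"):
            raise NetworkFormatError(
                f"misplaced operator {tok!r} in expression {self.source!r}")
        return Var(tok)


def parse_expression(text: str) -> BooleanExpression:
    """Parse a single Boolean expression (``!``/``&``/``|``, parens, 0/1)."""
    tokens = _tokenize(text)
    if not tokens:
        raise NetworkFormatError(f"empty expression {text!r}")
    return _Parser(tokens, text).parse()


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

class Edge(NamedTuple):
    """Directed regulatory edge: ``source`` appears in ``target``'s rule."""

    source: str
    target: str


@dataclass
class BooleanNetwork:
    """An ordered collection of nodes with Boolean update rules.

    The node order is fixed at construction and defines both the position of
    each node in state vectors and its bit in the integer state encoding
    (first node = least-significant bit).
    """

    nodes: list[str]
    rules: list[BooleanExpression]
    kinds: list[str] = field(default_factory=list)  # regular | identity | fixed

    def __post_init__(self):
        if len(self.nodes) == 0:
            raise NetworkFormatError("a network needs at least one node")
        if len(set(self.nodes)) != len(self.nodes):
            dup = sorted({x for x in self.nodes if self.nodes.count(x) > 1})
            raise NetworkFormatError(f"duplicate node name(s): {', '.join(dup)}")
        if len(self.rules) != len(self.nodes):
            raise NetworkFormatError("one rule required per node")
        self.index = {name: i for i, name in enumerate(self.nodes)}
        declared = set(self.nodes)
        for name, rule in zip(self.nodes, self.rules):
            for ref in rule.variables():
                if ref not in declared:
                    raise NetworkFormatError(
                        f"rule for {name!r} references undeclared node {ref!r}")
        if not self.kinds:
            self.kinds = [self._classify(i) for i in range(len(self.nodes))]

    def _classify(self, i: int) -> str:
        rule = self.rules[i]
        if isinstance(rule, Const):
            return "fixed"
        if isinstance(rule, Var) and rule.name == self.nodes[i]:
            return "identity"
        return "regular"

    @property
    def n(self) -> int:
        return len(self.nodes)

    def kind(self, node: str) -> str:
        return self.kinds[self.index[node]]

    def fixed_value(self, i: int) -> int:
        rule = self.rules[i]
        if not isinstance(rule, Const):
            raise ValueError(f"node {self.nodes[i]!r} is not fixed")
        return int(rule.value)

    def __repr__(self) -> str:
        return f"BooleanNetwork(n={self.n}, nodes={self.nodes!r})"


def parse_network(text: str) -> BooleanNetwork:
    """Parse a "targets, factors" rule file into a :class:`BooleanNetwork`.

    The first non-comment line must be the header; each following line is
    ``name, expression``.  Lines starting with ``#`` are ignored.  Every node
    referenced in any expression must have its own rule line.
    """
    names: list[str] = []
    rules: list[BooleanExpression] = []
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            normalized = re.sub(r"\s", "", line).lower()
            if normalized not in ("targets,factors", "targets,functions"):
                raise NetworkFormatError(
                    f"line {lineno}: expected 'targets, factors' header, got {line!r}")
            header_seen = True
            continue
        if "," not in line:
            raise NetworkFormatError(f"line {lineno}: missing ',' separator in {line!r}")
        name, _, expr_text = line.partition(",")
        name = name.strip()
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.]*", name):
            raise NetworkFormatError(f"line {lineno}: invalid node name {name!r}")
        try:
            rule = parse_expression(expr_text)
        except NetworkFormatError as exc:
            raise NetworkFormatError(f"line {lineno}: {exc}") from None
        if name in names:
            raise NetworkFormatError(f"line {lineno}: duplicate node name {name!r}")
        names.append(name)
        rules.append(rule)
    if not header_seen:
        raise NetworkFormatError("empty rule file")
    if not names:
        raise NetworkFormatError("rule file declares no nodes")
    return BooleanNetwork(names, rules)


def evaluate_rule(network: BooleanNetwork, i: int, state: Sequence[int]) -> int:
    """Apply node *i*'s update function to a full state vector.

    Deterministic: identity nodes return their own current value, fixed nodes
    their constant.  ``state`` must have one entry per node.
    """
    if not 0 <= i < network.n:
        raise IndexError(f"node index {i} out of range for n={network.n}")
    arr = np.asarray(state)
    if arr.shape[-1] != network.n:
        raise ValueError(f"state has length {arr.shape[-1]}, expected {network.n}")
    return int(network.rules[i].evaluate(arr, network.index))


def extract_edges(network: BooleanNetwork) -> list[Edge]:
    """Directed edge list of the network: one edge per distinct input variable
    of each rule (repeated occurrences collapse to one edge).  Targets appear
    in node order; sources in first-occurrence order within each rule.
    Identity nodes contribute their self-edge; fixed nodes have no inputs.
    """
    edges: list[Edge] = []
    for name, rule in zip(network.nodes, network.rules):
        for source in rule.variables():
            edges.append(Edge(source, name))
    return edges


def write_network(network: BooleanNetwork) -> str:
    """Serialize to the "targets, factors" dialect; ``parse_network`` of the
    result reproduces the original structure."""
    lines = ["targets, factors"]
    for name, rule in zip(network.nodes, network.rules):
        lines.append(f"{name}, {rule}")
    return "\n".join(lines) + "\n"
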