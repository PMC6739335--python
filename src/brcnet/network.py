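"""Synchronous Boolean networks: representation, parsing, dynamics.

A network is a list of named nodes, each with a Boolean update rule stored
as a truth table over its *essential* inputs (inputs the rule's value
actually depends on).  States are unsigned integers with node 0 at the
least-significant bit; every module in the package shares this encoding.
Update semantics are synchronous and deterministic: all nodes evaluate
their rule on the current state simultaneously.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Rule",
    "BooleanNetwork",
    "Attractor",
    "PhenotypeCondition",
    "ParseError",
    "parse_network",
    "synchronous_step",
    "find_attractor",
    "enumerate_attractors_exhaustive",
    "clamp_and_propagate",
    "hamming_distance",
    "state_to_bits",
    "bits_to_state",
    "state_to_string",
    "string_to_state",
]

EXHAUSTIVE_LIMIT = 22


class ParseError(ValueError):
    """Raised when rule text cannot be parsed into a network."""


# ---------------------------------------------------------------------------
# state helpers


def bits_to_state(bits: Sequence[int]) -> int:
    """Pack a bit sequence (node 0 first) into the integer encoding."""
    s = 0
    for i, b in enumerate(bits):
        if b not in (0, 1):
            raise ValueError(f"bit {i} is {b!r}, expected 0 or 1")
        s |= b << i
    return s


def state_to_bits(state: int, n: int) -> tuple[int, ...]:
    """Unpack an integer state into n bits, node 0 first."""
    return tuple((state >> i) & 1 for i in range(n))


def state_to_string(state: int, n: int) -> str:
    """Render a state as a 0/1 string in node order (node 0 leftmost)."""
    return "".join(str((state >> i) & 1) for i in range(n))


def string_to_state(s: str) -> int:
    """Inverse of :func:`state_to_string`."""
    return bits_to_state([int(c) for c in s])


def hamming_distance(a: int, b: int, n: int | None = None) -> int:
    """Number of bit positions where two states differ.

    If ``n`` is given, both states must fit in ``n`` bits.
    """
    if n is not None and (a >> n or b >> n):
        raise ValueError("state wider than declared width")
    return (a ^ b).bit_count()


# ---------------------------------------------------------------------------
# rules


@dataclass(frozen=True)
class Rule:
    """Boolean function of one node, as a truth table over its inputs.

    ``inputs`` are node indices; ``table`` is an integer whose bit at
    position ``idx`` gives the output for the input combination where
    input j contributes bit j of ``idx``.  A rule with no inputs is a
    constant (table 0 or 1).
    """

    inputs: tuple[int, ...]
    table: int

    def __post_init__(self) -> None:
        k = len(self.inputs)
        if not 0 <= self.table < (1 << (1 << k)):
            raise ValueError("truth table out of range for input count")

    def evaluate(self, state: int) -> int:
        idx = 0
        for j, inp in enumerate(self.inputs):
            idx |= ((state >> inp) & 1) << j
        return (self.table >> idx) & 1

    def is_constant(self) -> bool:
        return not self.inputs

    def essential(self) -> "Rule":
        """Drop inputs the table does not depend on, rebuilding the table."""
        k = len(self.inputs)
        keep: list[int] = []
        for j in range(k):
            bit = 1 << j
            if any(
                ((self.table >> idx) & 1) != ((self.table >> (idx | bit)) & 1)
                for idx in range(1 << k)
                if not idx & bit
            ):
                keep.append(j)
        if len(keep) == k:
            return self
        new_table = 0
        for new_idx in range(1 << len(keep)):
            idx = 0
            for m, j in enumerate(keep):
                idx |= ((new_idx >> m) & 1) << j
            new_table |= ((self.table >> idx) & 1) << new_idx
        return Rule(tuple(self.inputs[j] for j in keep), new_table)

    def restrict(self, fixed: Mapping[int, int]) -> "Rule":
        """Partially evaluate: substitute fixed input values, re-prune."""
        if not any(i in fixed for i in self.inputs):
            return self
        keep = [j for j, i in enumerate(self.inputs) if i not in fixed]
        new_table = 0
        for new_idx in range(1 << len(keep)):
            idx = 0
            for m, j in enumerate(keep):
                idx |= ((new_idx >> m) & 1) << j
            for j, i in enumerate(self.inputs):
                if i in fixed:
                    idx |= fixed[i] << j
            new_table |= ((self.table >> idx) & 1) << new_idx
        return Rule(tuple(self.inputs[j] for j in keep), new_table).essential()

    def remap(self, index_map: Mapping[int, int]) -> "Rule":
        return Rule(tuple(index_map[i] for i in self.inputs), self.table)


# ---------------------------------------------------------------------------
# the network


@dataclass(frozen=True)
class BooleanNetwork:
    """A named synchronous Boolean network.

    Edges are functional: (x, y) is an edge iff x is an essential input of
    y's rule.  Rules are pruned to essential inputs on construction.
    """

    nodes: tuple[str, ...]
    rules: tuple[Rule, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.rules):
            raise ValueError("one rule per node required")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        object.__setattr__(self, "rules", tuple(r.essential() for r in self.rules))
        for r in self.rules:
            for i in r.inputs:
                if not 0 <= i < len(self.nodes):
                    raise ValueError(f"rule input index {i} out of range")
        object.__setattr__(
            self, "_index", {name: i for i, name in enumerate(self.nodes)}
        )

    # -- basics ------------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown node {name!r}") from None

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            (self.nodes[i], self.nodes[t])
            for t, r in enumerate(self.rules)
            for i in r.inputs
        )

    def out_degrees(self) -> dict[str, int]:
        deg = {name: 0 for name in self.nodes}
        for r in self.rules:
            for i in r.inputs:
                deg[self.nodes[i]] += 1
        return deg

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BooleanNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.rules == other.rules

    def __hash__(self) -> int:
        return hash((self.nodes, self.rules))

    # -- dynamics ----------------------------------------------------------

    def step(self, state: int) -> int:
        if state >> self.n:
            raise ValueError("state wider than network")
        nxt = 0
        for i, r in enumerate(self.rules):
            nxt |= r.evaluate(state) << i
        return nxt

    def step_batch(self, states: np.ndarray) -> np.ndarray:
        """Vectorized synchronous step on an int64 array of states."""
        if self.n > 62:
            raise ValueError("batch stepping supports up to 62 nodes")
        states = np.asarray(states, dtype=np.int64)
        nxt = np.zeros_like(states)
        for i, r in enumerate(self.rules):
            idx = np.zeros_like(states)
            for j, inp in enumerate(r.inputs):
                idx |= ((states >> inp) & 1) << j
            tab = np.array(
                [(r.table >> t) & 1 for t in range(1 << len(r.inputs))],
                dtype=np.int64,
            )
            nxt |= tab[idx] << i
        return nxt

    def successor_table(self) -> np.ndarray:
        """Successor of every state 0..2^n-1 (requires n ≤ EXHAUSTIVE_LIMIT)."""
        if self.n > EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"exhaustive table needs n ≤ {EXHAUSTIVE_LIMIT}; "
                "use the Monte-Carlo landscape instead"
            )
        states = np.arange(1 << self.n, dtype=np.int64)
        return self.step_batch(states)

    # -- serialization -----------------------------------------------------

    def rule_expression(self, i: int) -> str:
        """Canonical sum-of-products text of node i's rule."""
        r = self.rules[i]
        if not r.inputs:
            return str(r.table & 1)
        terms = []
        for idx in range(1 << len(r.inputs)):
            if (r.table >> idx) & 1:
                lits = []
                for j, inp in enumerate(r.inputs):
                    neg = "" if (idx >> j) & 1 else "!"
                    lits.append(neg + self.nodes[inp])
                terms.append(" & ".join(lits))
        if not terms:
            return "0"
        if len(terms) == 1:
            return terms[0]
        return " | ".join(f"({t})" for t in terms)

    def to_text(self) -> str:
        lines = ["targets, factors"]
        for i, name in enumerate(self.nodes):
            lines.append(f"{name}, {self.rule_expression(i)}")
        return "\n".join(lines) + "\n"

    def attractor_report(self, attractors: "Sequence[Attractor]") -> str:
        """JSON report of attractors (states as 0/1 strings in node order)."""
        payload = [
            {
                "length": len(a.states),
                "states": [state_to_string(s, self.n) for s in a.states],
            }
            for a in attractors
        ]
        return json.dumps({"nodes": list(self.nodes), "attractors": payload}, indent=2)


# ---------------------------------------------------------------------------
# attractors


@dataclass(frozen=True)
class Attractor:
    """A cyclic state sequence closed under the synchronous map.

    Canonical rotation starts at the minimal integer encoding; length-1
    attractors are fixed points.
    """

    states: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("attractor needs at least one state")
        if len(set(self.states)) != len(self.states):
            raise ValueError("attractor states must be distinct")
        object.__setattr__(self, "states", _canonical_rotation(self.states))

    @property
    def length(self) -> int:
        return len(self.states)

    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    def node_values(self, i: int) -> set[int]:
        return {(s >> i) & 1 for s in self.states}

    def verify(self, net: BooleanNetwork) -> bool:
        c = len(self.states)
        return all(
            net.step(self.states[p]) == self.states[(p + 1) % c] for p in range(c)
        )


def _canonical_rotation(states: Sequence[int]) -> tuple[int, ...]:
    k = min(range(len(states)), key=lambda i: states[i])
    return tuple(states[k:]) + tuple(states[:k])


@dataclass(frozen=True)
class PhenotypeCondition:
    """Node=value constraints that must hold in *every* attractor state.

    Used to label attractors desired (all constraints hold), undesired
    (the complemented constraints hold), or neither.
    """

    constraints: tuple[tuple[str, int], ...]

    @classmethod
    def parse(cls, text: str) -> "PhenotypeCondition":
        """Parse "Node=1,Other=0" style condition strings."""
        pairs = []
        for part in text.split(","):
            part = part.strip()
            if not part:
                continue
            name, _, val = part.partition("=")
            if val.strip() not in ("0", "1"):
                raise ValueError(f"bad phenotype term {part!r}")
            pairs.append((name.strip(), int(val)))
        if not pairs:
            raise ValueError("empty phenotype condition")
        return cls(tuple(pairs))

    def satisfied_by(self, net: BooleanNetwork, attractor: Attractor) -> bool:
        return all(
            attractor.node_values(net.index(name)) == {value}
            for name, value in self.constraints
        )

    def complement(self) -> "PhenotypeCondition":
        return PhenotypeCondition(tuple((n, 1 - v) for n, v in self.constraints))

    def label(self, net: BooleanNetwork, attractor: Attractor) -> str:
        if self.satisfied_by(net, attractor):
            return "desired"
        if self.complement().satisfied_by(net, attractor):
            return "undesired"
        return "other"


# ---------------------------------------------------------------------------
# parsing the rule dialect


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<and>&+|\bAND\b)|(?P<or>\|+|\bOR\b)|(?P<not>!|~|\bNOT\b)"
    r"|(?P<lp>\()|(?P<rp>\))|(?P<const>[01])(?![\w])|(?P<name>[A-Za-z_][\w.]*))",
    re.IGNORECASE,
)


def _tokenize(expr: str, line_no: int) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if not m:
            if expr[pos:].strip():
                raise ParseError(f"line {line_no}: cannot tokenize {expr[pos:]!r}")
            break
        pos = m.end()
        kind = m.lastgroup
        tokens.append((kind, m.group().strip()))
    return tokens


class _ExprParser:
    """Recursive descent over: or_expr := and_expr ('|' and_expr)* etc."""

    def __init__(self, tokens: list[tuple[str, str]], line_no: int):
        self.tokens = tokens
        self.pos = 0
        self.line_no = line_no

    def _peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def _next(self) -> tuple[str, str]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self):
        node = self._or()
        if self.pos != len(self.tokens):
            raise ParseError(
                f"line {self.line_no}: trailing tokens after expression"
            )
        return node

    def _or(self):
        left = self._and()
        while self._peek() == "or":
            self._next()
            left = ("or", left, self._and())
        return left

    def _and(self):
        left = self._unary()
        while self._peek() == "and":
            self._next()
            left = ("and", left, self._unary())
        return left

    def _unary(self):
        kind = self._peek()
        if kind is None:
            raise ParseError(f"line {self.line_no}: unexpected end of expression")
        if kind == "not":
            self._next()
            return ("not", self._unary())
        if kind == "lp":
            self._next()
            node = self._or()
            if self._peek() != "rp":
                raise ParseError(f"line {self.line_no}: missing ')'")
            self._next()
            return node
        if kind == "const":
            return ("const", int(self._next()[1]))
        if kind == "name":
            return ("var", self._next()[1])
        raise ParseError(f"line {self.line_no}: unexpected token")


def _ast_vars(ast, acc: list[str]) -> None:
    kind = ast[0]
    if kind == "var" and ast[1] not in acc:
        acc.append(ast[1])
    elif kind in ("and", "or"):
        _ast_vars(ast[1], acc)
        _ast_vars(ast[2], acc)
    elif kind == "not":
        _ast_vars(ast[1], acc)


def _ast_eval(ast, env: Mapping[str, int]) -> int:
    kind = ast[0]
    if kind == "const":
        return ast[1]
    if kind == "var":
        return env[ast[1]]
    if kind == "not":
        return 1 - _ast_eval(ast[1], env)
    a, b = _ast_eval(ast[1], env), _ast_eval(ast[2], env)
    return a & b if kind == "and" else a | b


def parse_network(text: str) -> BooleanNetwork:
    """Parse ".bnet"-style rule text into a network.

    One rule per line, ``target, expression``; an optional
    ``targets, factors`` header and ``#`` comments are ignored.  Rules
    are compiled to truth tables and pruned to essential inputs, so
    syntactically mentioned but functionally irrelevant inputs produce
    no edge.
    """
    entries: list[tuple[str, object, int]] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "," not in line:
            raise ParseError(f"line {line_no}: expected 'target, expression'")
        target, expr = line.split(",", 1)
        target = target.strip()
        if target.lower() == "targets" and expr.strip().lower() == "factors":
            continue
        if not target:
            raise ParseError(f"line {line_no}: empty target name")
        if not expr.strip():
            raise ParseError(f"line {line_no}: empty rule for {target!r}")
        ast = _ExprParser(_tokenize(expr, line_no), line_no).parse()
        entries.append((target, ast, line_no))

    names = [t for t, _, _ in entries]
    seen: set[str] = set()
    for t, _, line_no in entries:
        if t in seen:
            raise ParseError(f"line {line_no}: duplicate target {t!r}")
        seen.add(t)

    rules = []
    for target, ast, line_no in entries:
        var_names: list[str] = []
        _ast_vars(ast, var_names)
        for v in var_names:
            if v not in seen:
                raise ParseError(
                    f"line {line_no}: rule for {target!r} references "
                    f"undeclared node {v!r}"
                )
        k = len(var_names)
        table = 0
        for idx in range(1 << k):
            env = {v: (idx >> j) & 1 for j, v in enumerate(var_names)}
            table |= _ast_eval(ast, env) << idx
        rules.append(Rule(tuple(names.index(v) for v in var_names), table))
    return BooleanNetwork(tuple(names), tuple(rules))


# ---------------------------------------------------------------------------
# dynamics-level operations


def synchronous_step(net: BooleanNetwork, state: int) -> int:
    """One deterministic synchronous update."""
    return net.step(state)


def find_attractor(
    net: BooleanNetwork, state: int, max_steps: int | None = None
) -> tuple[Attractor, int]:
    """Follow a trajectory until a state repeats.

    Returns the attractor (canonical rotation) and the transient length
    (steps before the trajectory first enters the cycle).  Exact cycle
    detection via a visited-state hash map.
    """
    if max_steps is None:
        max_steps = (1 << net.n) + 1
    seen: dict[int, int] = {}
    x = state
    for t in range(max_steps + 1):
        if x in seen:
            cycle_start = seen[x]
            path = sorted(seen, key=seen.get)  # insertion order == position
            return Attractor(tuple(path[cycle_start:])), cycle_start
        seen[x] = t
        x = net.step(x)
    raise RuntimeError("no revisit within max_steps; dynamics bug or cap too low")


def enumerate_attractors_exhaustive(
    net: BooleanNetwork,
) -> tuple[list[Attractor], dict[Attractor, int], np.ndarray]:
    """Exact attractor census over all 2^n states (n ≤ EXHAUSTIVE_LIMIT).

    Returns the attractor list, exact basin sizes, and the per-state
    attractor-index array (basin membership for every state).
    """
    succ = net.successor_table()
    t = succ.copy()
    # pointer doubling: after k squarings t = succ^(2^k); 2^n bounds transients
    for _ in range(net.n + 1):
        t = t[t]
    # every t[s] now lies on a cycle
    on_cycle = np.unique(t)
    rep_of: dict[int, int] = {}
    attractors: list[Attractor] = []
    for s in on_cycle.tolist():
        if s in rep_of:
            continue
        cyc = [s]
        x = int(succ[s])
        while x != s:
            cyc.append(x)
            x = int(succ[x])
        a = Attractor(tuple(cyc))
        idx = len(attractors)
        attractors.append(a)
        for c in cyc:
            rep_of[c] = idx
    lut = np.full(1 << net.n, -1, dtype=np.int64)
    for s, idx in rep_of.items():
        lut[s] = idx
    assignment = lut[t]
    sizes = np.bincount(assignment, minlength=len(attractors))
    basin_sizes = {a: int(sizes[i]) for i, a in enumerate(attractors)}
    return attractors, basin_sizes, assignment


def clamp_and_propagate(
    net: BooleanNetwork, clamps: Mapping[str, int]
) -> tuple[BooleanNetwork, dict[str, int]]:
    """Fix node values and propagate constants to closure.

    Clamped nodes get constant rules; any node whose rule becomes constant
    given already-fixed inputs is fixed too, repeatedly.  Returns the
    reduced network on the still-free nodes (original order, rules with
    fixed inputs substituted) and the full fixed assignment.
    """
    fixed: dict[int, int] = {}
    for name, value in clamps.items():
        i = net.index(name)
        if value not in (0, 1):
            raise ValueError(f"clamp value for {name!r} must be 0 or 1")
        if i in fixed and fixed[i] != value:
            raise ValueError(f"contradictory clamp on {name!r}")
        fixed[i] = value

    rules = list(net.rules)
    for i, v in fixed.items():
        rules[i] = Rule((), v)
    changed = True
    while changed:
        changed = False
        for i in range(net.n):
            if i in fixed:
                continue
            r = rules[i].restrict(fixed)
            rules[i] = r
            if r.is_constant():
                fixed[i] = r.table & 1
                changed = True

    free = [i for i in range(net.n) if i not in fixed]
    index_map = {old: new for new, old in enumerate(free)}
    sub_rules = tuple(rules[i].restrict(fixed).remap(index_map) for i in free)
    reduced = BooleanNetwork(tuple(net.nodes[i] for i in free), sub_rules)
    assignment = {net.nodes[i]: v for i, v in fixed.items()}
    return reduced, assignment


def embed_state(
    net: BooleanNetwork,
    reduced: BooleanNetwork,
    fixed: Mapping[str, int],
    reduced_state: int,
) -> int:
    """Lift a reduced-network state back to the full network's encoding."""
    s = 0
    for name, v in fixed.items():
        s |= v << net.index(name)
    for j, name in enumerate(reduced.nodes):
        s |= ((reduced_state >> j) & 1) << net.index(name)
    return s
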