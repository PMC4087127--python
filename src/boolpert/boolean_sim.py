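"""Boolean update rules, attractor search and edgetic edge-removal scans.

A signed network is converted to per-node update rules of the form

    target, (activator_1 | ... | activator_A | target) & !(inhibitor_1 | ...)

i.e. a node stays or becomes active if one of its activators or the node
itself is active and no inhibitor is active.  Note the self term: unlike the
reconstruction-time propagation rule, an active node here sustains itself
once its activators switch off.  Rules are (de)serialized in the
``targets, factors`` dialect used by Boolean-network attractor tools.

Attractors are found by iterating the synchronous update from a scenario's
initial state (inputs clamped, free nodes zero) until a state repeats; a
steady state (cycle of length one) is additionally verified to be a fixed
point under asynchronous single-node updates.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import NodeRoster, SignalingNetwork

__all__ = [
    "Expr", "Var", "Not", "And", "Or",
    "BooleanRuleSet", "PerturbationScenario", "AttractorResult",
    "network_to_rules", "parse_rules", "write_rules", "parse_expression",
    "synchronous_step", "find_attractors", "exhaustive_steady_states",
    "simulate_drug_panel", "edgetic_scan",
]


# ---------------------------------------------------------------------------
# expression AST

class Expr:
    def evaluate(self, env: Mapping[str, np.ndarray | bool]):
        raise NotImplementedError

    def variables(self) -> set[str]:
        raise NotImplementedError


@dataclass(frozen=True)
class Var(Expr):
    name: str

    def evaluate(self, env):
        return env[self.name]

    def variables(self):
        return {self.name}

    def __str__(self):
        return self.name


@dataclass(frozen=True)
class Not(Expr):
    operand: Expr

    def evaluate(self, env):
        v = self.operand.evaluate(env)
        return ~v if isinstance(v, np.ndarray) else not v

    def variables(self):
        return self.operand.variables()

    def __str__(self):
        return f"!({self.operand})"


def _nary_eval(items, env, op):
    vals = [e.evaluate(env) for e in items]
    out = vals[0]
    for v in vals[1:]:
        out = op(out, v)
    return out


@dataclass(frozen=True)
class And(Expr):
    operands: tuple[Expr, ...]

    def __post_init__(self):
        object.__setattr__(self, "operands", tuple(self.operands))

    def evaluate(self, env):
        return _nary_eval(self.operands, env, lambda a, b: a & b)

    def variables(self):
        return set().union(*(e.variables() for e in self.operands))

    def __str__(self):
        # Or renders its own parentheses; And binds tighter than Or
        return " & ".join(str(o) for o in self.operands)


@dataclass(frozen=True)
class Or(Expr):
    operands: tuple[Expr, ...]

    def __post_init__(self):
        object.__setattr__(self, "operands", tuple(self.operands))

    def evaluate(self, env):
        return _nary_eval(self.operands, env, lambda a, b: a | b)

    def variables(self):
        return set().union(*(e.variables() for e in self.operands))

    def __str__(self):
        return "(" + " | ".join(str(o) for o in self.operands) + ")"


# ---------------------------------------------------------------------------
# parsing (grammar: or := and ('|' and)* ; and := unary ('&' unary)* ;
#                   unary := '!' unary | '(' or ')' | NAME)

_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z0-9_./-]+)|(?P<op>[()&|!]))")


class RuleParseError(ValueError):
    pass


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise RuleParseError(f"unexpected character {text[pos]!r}")
            break
        tokens.append(m.group("name") or m.group("op"))
        pos = m.end()
    return tokens


def parse_expression(text: str) -> Expr:
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take(expected=None):
        nonlocal pos
        tok = peek()
        if tok is None or (expected is not None and tok != expected):
            raise RuleParseError(f"expected {expected or 'token'}, got {tok!r}")
        pos += 1
        return tok

    def parse_or():
        items = [parse_and()]
        while peek() == "|":
            take("|")
            items.append(parse_and())
        return items[0] if len(items) == 1 else Or(tuple(items))

    def parse_and():
        items = [parse_unary()]
        while peek() == "&":
            take("&")
            items.append(parse_unary())
        return items[0] if len(items) == 1 else And(tuple(items))

    def parse_unary():
        tok = peek()
        if tok == "!":
            take("!")
            return Not(parse_unary())
        if tok == "(":
            take("(")
            inner = parse_or()
            take(")")
            return inner
        if tok in ("&", "|", ")", None):
            raise RuleParseError(f"unexpected token {tok!r}")
        return Var(take())

    expr = parse_or()
    if pos != len(tokens):
        raise RuleParseError(f"trailing tokens: {tokens[pos:]}")
    return expr


# ---------------------------------------------------------------------------
# rule sets

@dataclass(frozen=True)
class BooleanRuleSet:
    """Update expression per node; ``fixed`` nodes are clamped inputs."""

    roster: NodeRoster
    rules: Mapping[str, Expr]
    fixed: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "rules", dict(self.rules))
        object.__setattr__(self, "fixed", frozenset(self.fixed))
        missing = set(self.roster.names) - set(self.rules)
        if missing:
            raise ValueError(f"rules missing for nodes: {sorted(missing)}")
        known = set(self.roster.names)
        for node, expr in self.rules.items():
            unknown = expr.variables() - known
            if unknown:
                raise ValueError(
                    f"rule for {node!r} references unknown nodes {sorted(unknown)}"
                )
        for node in self.fixed:
            if self.rules[node] != Var(node):
                raise ValueError(f"fixed node {node!r} must have identity rule")


@dataclass(frozen=True)
class PerturbationScenario:
    """Clamped input values plus initial values for the free nodes."""

    fixed_values: Mapping[str, int]
    free_initial: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "fixed_values",
                           {k: int(v) for k, v in self.fixed_values.items()})
        object.__setattr__(self, "free_initial",
                           {k: int(v) for k, v in self.free_initial.items()})


@dataclass(frozen=True)
class AttractorResult:
    """Attractor reached from a scenario's initial state.

    ``states`` holds the cycle (length 1 for a steady state) as binary
    vectors in roster order.
    """

    roster: NodeRoster
    states: np.ndarray
    is_steady: bool
    reached_from_init: bool = True

    def value_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.states, columns=self.roster.names)

    def node_value(self, node: str):
        """Steady value of a node, or the cycle's tuple of values."""
        j = self.roster.index(node)
        vals = tuple(int(v) for v in self.states[:, j])
        return vals[0] if self.is_steady else vals


def network_to_rules(
    net: SignalingNetwork, input_nodes: Iterable[str]
) -> BooleanRuleSet:
    """Adjacency matrix to logical rules with OR-ed activators plus self term.

    For node j with activators A and inhibitors I the rule is
    ``(a_1 | ... | a_A | j) & !(i_1 | ... | i_I)``; the negation clause is
    omitted when I is empty, and an isolated node keeps its own value.
    """
    inputs = frozenset(input_nodes)
    for node in inputs:
        if net.parents(node):
            raise ValueError(f"input node {node!r} has ingoing edges")
    rules: dict[str, Expr] = {}
    for j, node in enumerate(net.roster.names):
        if node in inputs:
            rules[node] = Var(node)
            continue
        acts = [Var(p) for p in net.parents(node, sign=1)]
        inhs = [Var(p) for p in net.parents(node, sign=-1)]
        pos: Expr = Var(node) if not acts else Or(tuple(acts + [Var(node)]))
        if inhs:
            neg = Not(inhs[0] if len(inhs) == 1 else Or(tuple(inhs)))
            rules[node] = And((pos, neg))
        else:
            rules[node] = pos
    return BooleanRuleSet(net.roster, rules, inputs)


def write_rules(rules: BooleanRuleSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("targets, factors\n")
        for node in rules.roster.names:
            fh.write(f"{node}, {rules.rules[node]}\n")


def parse_rules(path, roster: NodeRoster,
                fixed: Iterable[str] | None = None) -> BooleanRuleSet:
    """Read a ``targets, factors`` rule file.

    Nodes whose rule is their own identity are treated as fixed inputs
    unless ``fixed`` overrides that.
    """
    rules: dict[str, Expr] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.strip().lower().replace(" ", "") != "targets,factors":
            raise RuleParseError(f"bad header line: {header.strip()!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            if "," not in line:
                raise RuleParseError(f"line {lineno}: missing ',' separator")
            node, text = line.split(",", 1)
            node = node.strip()
            if node not in roster.roles:
                raise RuleParseError(f"line {lineno}: unknown target {node!r}")
            try:
                expr = parse_expression(text)
            except RuleParseError as exc:
                raise RuleParseError(f"line {lineno}: {exc}") from None
            unknown = expr.variables() - set(roster.names)
            if unknown:
                raise RuleParseError(
                    f"line {lineno}: unknown literal(s) {sorted(unknown)}"
                )
            rules[node] = expr
    if fixed is None:
        fixed = {n for n, e in rules.items()
                 if e == Var(n) and roster.roles[n] != "protein"}
    return BooleanRuleSet(roster, rules, fixed)


# ---------------------------------------------------------------------------
# dynamics

def _env_from_state(roster: NodeRoster, state: np.ndarray) -> dict:
    return {name: bool(state[i]) for i, name in enumerate(roster.names)}


def synchronous_step(
    rules: BooleanRuleSet,
    state: np.ndarray,
    fixed_values: Mapping[str, int] | None = None,
) -> np.ndarray:
    """All free nodes updated simultaneously; fixed nodes keep their values."""
    fixed_values = fixed_values or {}
    env = _env_from_state(rules.roster, np.asarray(state))
    nxt = np.empty(len(rules.roster), dtype=np.int8)
    for i, node in enumerate(rules.roster.names):
        if node in rules.fixed:
            nxt[i] = fixed_values.get(node, int(state[i]))
        else:
            nxt[i] = int(bool(rules.rules[node].evaluate(env)))
    return nxt


def _initial_state(rules: BooleanRuleSet, scenario: PerturbationScenario
                   ) -> np.ndarray:
    state = np.zeros(len(rules.roster), dtype=np.int8)
    for node, v in scenario.free_initial.items():
        state[rules.roster.index(node)] = v
    for node, v in scenario.fixed_values.items():
        if node not in rules.fixed:
            raise ValueError(f"{node!r} is not a fixed input of the rule set")
        state[rules.roster.index(node)] = v
    return state


def find_attractors(
    rules: BooleanRuleSet, scenario: PerturbationScenario
) -> AttractorResult:
    """Attractor reached by synchronous iteration from the scenario start.

    Steady states are verified to be fixed points under asynchronous
    single-node updates as well (always true for synchronous fixed points).
    """
    state = _initial_state(rules, scenario)
    seen: dict[bytes, int] = {state.tobytes(): 0}
    path = [state]
    while True:
        nxt = synchronous_step(rules, path[-1], scenario.fixed_values)
        key = nxt.tobytes()
        if key in seen:
            cycle = path[seen[key]:]
            break
        seen[key] = len(path)
        path.append(nxt)
    is_steady = len(cycle) == 1
    if is_steady:
        s = cycle[0]
        for i, node in enumerate(rules.roster.names):
            if node in rules.fixed:
                continue
            env = _env_from_state(rules.roster, s)
            if int(bool(rules.rules[node].evaluate(env))) != s[i]:
                raise AssertionError(
                    "steady state is not an asynchronous fixed point"
                )
    return AttractorResult(rules.roster, np.vstack(cycle), is_steady)


def exhaustive_steady_states(
    rules: BooleanRuleSet, fixed_values: Mapping[str, int]
) -> set[tuple[int, ...]]:
    """All synchronous fixed points, by vectorized full enumeration.

    Free nodes are enumerated exhaustively (at most 22); fixed nodes carry
    ``fixed_values``.
    """
    names = rules.roster.names
    free = [n for n in names if n not in rules.fixed]
    if len(free) > 22:
        raise ValueError(f"too many free nodes ({len(free)} > 22)")
    nfree = len(free)
    nstates = 1 << nfree
    grid = ((np.arange(nstates)[:, None] >> np.arange(nfree)[None, :]) & 1
            ).astype(bool)
    env = {}
    for k, n in enumerate(free):
        env[n] = grid[:, k]
    for n in rules.fixed:
        env[n] = np.full(nstates, bool(fixed_values.get(n, 0)))
    ok = np.ones(nstates, dtype=bool)
    for n in names:
        if n in rules.fixed:
            continue
        ok &= rules.rules[n].evaluate(env) == env[n]
    out = set()
    for s in np.nonzero(ok)[0]:
        out.add(tuple(int(env[n][s]) for n in names))
    return out


# ---------------------------------------------------------------------------
# drug panels and edgetic scans

def _attractor_readout(att: AttractorResult, node: str):
    v = att.node_value(node)
    return v if att.is_steady else "cycle"


def simulate_drug_panel(
    rules: BooleanRuleSet,
    drug_nodes: Sequence[str],
    stimulus_nodes: Sequence[str],
    readouts: Sequence[str],
) -> pd.DataFrame:
    """Attractor readouts for every on/off combination of the drug inputs.

    Stimuli are clamped to 1 throughout and free nodes start at 0, so the
    panel has 2**len(drug_nodes) rows (8 for the three-drug design).
    """
    for n in readouts:
        rules.roster.index(n)  # raises on unknown node
    for n in list(drug_nodes) + list(stimulus_nodes):
        if n not in rules.fixed:
            raise ValueError(f"{n!r} is not a fixed input of the rule set")
    rows = []
    for combo in itertools.product((0, 1), repeat=len(drug_nodes)):
        fixed = {s: 1 for s in stimulus_nodes}
        fixed.update(dict(zip(drug_nodes, combo)))
        att = find_attractors(rules, PerturbationScenario(fixed))
        row = dict(zip(drug_nodes, combo))
        row["is_steady"] = att.is_steady
        for r in readouts:
            row[r] = _attractor_readout(att, r)
        rows.append(row)
    return pd.DataFrame(rows)


def edgetic_scan(
    net: SignalingNetwork,
    target_node: str,
    candidate_parents: Sequence[str],
    drug_nodes: Sequence[str],
    stimulus_nodes: Sequence[str],
    readouts: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Drug-panel response after removing subsets of edges into a target.

    Every non-empty subset of the candidate parent edges is deleted in turn
    (k singletons plus 2**k - k - 1 multi-edge combinations), rules are
    regenerated and the drug panel re-simulated; a baseline block with no
    removal is included with ``removed == ""``.  The report is long form:
    one row per (removal set, drug combination).
    """
    parents = set(net.parents(target_node))
    for p in candidate_parents:
        if p not in parents:
            raise ValueError(f"{p!r} is not a parent of {target_node!r}")
    readouts = list(readouts) if readouts is not None else [target_node]
    inputs = list(drug_nodes) + list(stimulus_nodes)
    tj = net.roster.index(target_node)

    subsets = [()]
    for k in range(1, len(candidate_parents) + 1):
        subsets.extend(itertools.combinations(candidate_parents, k))

    frames = []
    for subset in subsets:
        adj = net.adjacency.copy()
        for p in subset:
            adj[net.roster.index(p), tj] = 0
        rules = network_to_rules(net.replace_adjacency(adj), inputs)
        panel = simulate_drug_panel(rules, drug_nodes, stimulus_nodes, readouts)
        panel.insert(0, "removed", "+".join(subset))
        panel["n_removed"] = len(subset)
        frames.append(panel)
    report = pd.concat(frames, ignore_index=True)
    report[f"{target_node}_inactive"] = report[target_node] == 0
    return report
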