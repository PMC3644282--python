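"""Synchronous boolean-network simulation and synthetic data generation.

Two validation data sources live here. The first is a generic boolean-network
simulator with perturbation clamping: all unclamped nodes update
simultaneously from logic rules (AND/OR/NOT), trajectories from random
initial states are followed to an attractor, and one attractor state per
trajectory becomes a sample. The packaged cholesterol-pathway model (see
``models/cholesterol.bnet``) provides the statins-perturbation experiment:
clamping the statins node to 1 shuts down HMG-CoA reductase and every
product downstream of mevalonic acid.

The second is a planted-dependency generator: trinary background variables
drawn i.i.d., with selected variable pairs made dependent (one copies the
other) only inside a designated condition's sample block — ground truth for
parameter-recovery experiments.

Boolean states map to the trinary alphabet as 1 → UP and 0 → DOWN, so
simulated data flows through the standard pipeline unchanged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._seeds import derive_seed
from .io import DOWN, NOCHANGE, UP, ConditionTable, TrinaryMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BooleanNetwork",
    "SimulationDesign",
    "cholesterol_fixture",
    "sample_steady_states",
    "generate_planted",
]


# ---------------------------------------------------------------------------
# Rule expressions
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z_][A-Za-z0-9_]*|[01])")


def _tokenize(text: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise ValueError(f"cannot tokenize rule at: {text[pos:]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser for AND/OR/NOT expressions.

    Grammar (OR binds loosest):
        expr   := term (OR term)*
        term   := factor (AND factor)*
        factor := NOT factor | '(' expr ')' | name | 0 | 1
    Produces nested tuples: ("or", a, b), ("and", a, b), ("not", a),
    ("var", name), ("const", 0|1).
    """

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of rule")
        self.pos += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise ValueError(f"trailing tokens in rule: {self.tokens[self.pos:]!r}")
        return node

    def expr(self):
        node = self.term()
        while self.peek() is not None and self.peek().upper() == "OR":
            self.take()
            node = ("or", node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek() is not None and self.peek().upper() == "AND":
            self.take()
            node = ("and", node, self.factor())
        return node

    def factor(self):
        tok = self.take()
        if tok.upper() == "NOT":
            return ("not", self.factor())
        if tok == "(":
            node = self.expr()
            if self.take() != ")":
                raise ValueError("unbalanced parenthesis in rule")
            return node
        if tok in ("0", "1"):
            return ("const", int(tok))
        if tok == ")":
            raise ValueError("unexpected ')' in rule")
        return ("var", tok)


def _rule_vars(ast) -> set[str]:
    kind = ast[0]
    if kind == "var":
        return {ast[1]}
    if kind == "const":
        return set()
    if kind == "not":
        return _rule_vars(ast[1])
    return _rule_vars(ast[1]) | _rule_vars(ast[2])


def _eval_rule(ast, state: Mapping[str, int]) -> int:
    kind = ast[0]
    if kind == "var":
        return state[ast[1]]
    if kind == "const":
        return ast[1]
    if kind == "not":
        return 1 - _eval_rule(ast[1], state)
    if kind == "and":
        return _eval_rule(ast[1], state) & _eval_rule(ast[2], state)
    return _eval_rule(ast[1], state) | _eval_rule(ast[2], state)


# ---------------------------------------------------------------------------
# Boolean network
# ---------------------------------------------------------------------------

class BooleanNetwork:
    """Named binary nodes with synchronous logic rules and optional clamps.

    Rules are boolean expressions over declared nodes built from AND, OR and
    NOT; a clamped node keeps its clamp value and its rule is ignored.
    """

    def __init__(
        self,
        rules: Mapping[str, str],
        clamps: Mapping[str, int] | None = None,
        name: str = "",
    ) -> None:
        self.name = name
        self.nodes: list[str] = list(rules)
        self.rules = {node: _Parser(_tokenize(expr)).parse() for node, expr in rules.items()}
        self.rule_text = dict(rules)
        declared = set(self.nodes)
        for node, ast in self.rules.items():
            undeclared = _rule_vars(ast) - declared
            if undeclared:
                raise ValueError(
                    f"rule for {node!r} references undeclared node(s): "
                    f"{sorted(undeclared)}"
                )
        self.clamps: dict[str, int] = {}
        for node, value in (clamps or {}).items():
            if node not in declared:
                raise ValueError(f"clamp on undeclared node {node!r}")
            if value not in (0, 1):
                raise ValueError(f"clamp value for {node!r} must be 0 or 1")
            self.clamps[node] = int(value)

    # -- construction --------------------------------------------------------
    @classmethod
    def from_text(cls, text: str, name: str = "") -> "BooleanNetwork":
        """Parse the one-line-per-node ``node = EXPR`` model format."""
        rules: dict[str, str] = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'node = expression'")
            node, expr = line.split("=", 1)
            node = node.strip()
            if node in rules:
                raise ValueError(f"line {lineno}: duplicate rule for node {node!r}")
            rules[node] = expr.strip()
        if not rules:
            raise ValueError("model file declares no nodes")
        return cls(rules, name=name)

    @classmethod
    def from_file(cls, path: str | Path) -> "BooleanNetwork":
        path = Path(path)
        return cls.from_text(path.read_text(), name=path.stem)

    def with_clamps(self, **clamps: int) -> "BooleanNetwork":
        """Copy of the network with additional clamped nodes."""
        merged = {**self.clamps, **clamps}
        net = BooleanNetwork(self.rule_text, merged, name=self.name)
        return net

    # -- structure -----------------------------------------------------------
    def parents_of(self, node: str) -> set[str]:
        return _rule_vars(self.rules[node]) - {node}

    def regulations(self) -> list[tuple[str, str]]:
        """Directed (regulator, target) pairs from the rules, self-loops excluded."""
        out = []
        for node in self.nodes:
            for parent in sorted(self.parents_of(node)):
                out.append((parent, node))
        return sorted(out)

    # -- dynamics ------------------------------------------------------------
    def step(self, state: Mapping[str, int]) -> dict[str, int]:
        """One synchronous update; clamped nodes keep their clamp value."""
        missing = [n for n in self.nodes if n not in state]
        if missing:
            raise ValueError(f"state does not cover node(s): {missing}")
        new = {}
        for node in self.nodes:
            if node in self.clamps:
                new[node] = self.clamps[node]
            else:
                new[node] = _eval_rule(self.rules[node], state)
        return new

    def attractor_from(
        self, state: Mapping[str, int], max_steps: int = 4096
    ) -> tuple[list[dict[str, int]], bool]:
        """Follow the trajectory until a fixed point or cycle.

        Returns (attractor states in cycle order, reached) where a fixed
        point yields a single-state list. If ``max_steps`` updates pass
        without a repeat the last state is returned with ``reached=False``.
        """
        current = {n: int(state[n]) for n in self.nodes}
        for node, value in self.clamps.items():
            current[node] = value
        seen: dict[tuple[int, ...], int] = {}
        trajectory: list[dict[str, int]] = []
        for _ in range(max_steps + 1):
            key = tuple(current[n] for n in self.nodes)
            if key in seen:
                return trajectory[seen[key]:], True
            seen[key] = len(trajectory)
            trajectory.append(current)
            current = self.step(current)
        logger.warning(
            "no attractor within %d steps for %s; emitting last state",
            max_steps,
            self.name or "boolean network",
        )
        return [trajectory[-1]], False


def cholesterol_fixture() -> BooleanNetwork:
    """The packaged cholesterol regulatory pathway model.

    A linear synthesis chain from Acetyl-CoA through HMG-CoA, mevalonic acid
    and the isoprenoid/sterol intermediates to cholesterol; statins inhibits
    HMG-CoA reductase (NOT logic); cholesterol feeds back negatively on
    SREBP-SCAP, whose transcriptional program drives the synthesis enzymes
    (HMG-CoA synthase, HMG-CoA reductase, mevalonate kinase, FPP synthase,
    squalene synthase). All multi-input nodes are AND except cholesterol,
    which ORs its two final synthesis branches.
    """
    text = (resources.files("ctxnet") / "models" / "cholesterol.bnet").read_text()
    return BooleanNetwork.from_text(text, name="cholesterol")


# ---------------------------------------------------------------------------
# Steady-state sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationDesign:
    """Arms (named clamp settings), samples per arm, step cap and seed."""

    arms: Mapping[str, Mapping[str, int]]
    n_samples: int = 100
    max_steps: int = 4096
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if not self.arms:
            raise ValueError("design needs at least one arm")


def sample_steady_states(
    net: BooleanNetwork, design: SimulationDesign
) -> tuple[TrinaryMatrix, ConditionTable]:
    """Attractor samples per arm, as a trinary matrix plus arm labels.

    Per sample: draw a uniformly random initial state, apply the arm's
    clamps, iterate synchronously to an attractor, and emit one uniformly
    chosen attractor state (a fixed point emits itself). Boolean 1 maps to
    UP and 0 to DOWN. Arms are concatenated in design order and reported as
    the condition table.
    """
    nodes = net.nodes
    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    assignments: dict[str, list[str]] = {}
    for arm_name, clamps in design.arms.items():
        arm_net = net.with_clamps(**dict(clamps))
        assignments[arm_name] = []
        for k in range(design.n_samples):
            rng = np.random.default_rng(derive_seed(design.seed, arm_name, k))
            init = {n: int(v) for n, v in zip(nodes, rng.integers(0, 2, len(nodes)))}
            attractor, _ = arm_net.attractor_from(init, design.max_steps)
            state = attractor[rng.integers(0, len(attractor))]
            columns.append(np.array([UP if state[n] else DOWN for n in nodes], dtype=np.int8))
            sid = f"{arm_name}_{k:03d}"
            sample_ids.append(sid)
            assignments[arm_name].append(sid)
    values = np.stack(columns, axis=1)
    data = TrinaryMatrix(values, nodes, sample_ids)
    table = ConditionTable(assignments, sample_ids)
    return data, table


# ---------------------------------------------------------------------------
# Planted-dependency generator
# ---------------------------------------------------------------------------

def generate_planted(
    n_sets: int,
    n_samples: int,
    conditions: int | Mapping[str, Sequence[int]],
    planted_edges: Sequence[tuple[tuple[str, str], str, float]] = (),
    noise: float = 0.0,
    marginals: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
) -> tuple[TrinaryMatrix, ConditionTable, list[tuple[tuple[str, str], str, float]]]:
    """Trinary gene-set matrix with condition-specific planted dependencies.

    Background variables are i.i.d. over (DOWN, NOCHANGE, UP) with the given
    marginals. For each planted ((i, j), T_k, strength): inside T_k's sample
    block, variable j copies variable i with probability ``strength`` (and is
    an independent background draw otherwise); outside the block j is always
    background. Finally every cell is flipped to one of the other two states
    with probability ``noise``.

    ``conditions`` is either a mapping from label to sample indices or an
    integer k for k equal consecutive blocks labelled C1..Ck. Variables are
    named S01, S02, ...; samples s0001, s0002, ...

    Returns (matrix, condition table, planted truth as passed).
    """
    if n_sets < 2:
        raise ValueError("need at least two variables")
    if n_samples < 2:
        raise ValueError("need at least two samples")
    if not 0 <= noise < 1:
        raise ValueError("noise must lie in [0, 1)")
    marginals = np.asarray(marginals, dtype=float)
    if marginals.shape != (3,) or (marginals < 0).any() or not np.isclose(marginals.sum(), 1):
        raise ValueError("marginals must be three non-negative numbers summing to 1")

    width = len(str(n_sets))
    row_ids = [f"S{i + 1:0{width}d}" for i in range(n_sets)]
    sample_ids = [f"s{j + 1:04d}" for j in range(n_samples)]

    if isinstance(conditions, int):
        k = conditions
        if k < 1 or k > n_samples:
            raise ValueError("number of condition blocks out of range")
        bounds = np.linspace(0, n_samples, k + 1).astype(int)
        blocks = {f"C{b + 1}": list(range(bounds[b], bounds[b + 1])) for b in range(k)}
    else:
        blocks = {label: list(ix) for label, ix in conditions.items()}
        for label, ix in blocks.items():
            if any(i < 0 or i >= n_samples for i in ix):
                raise ValueError(f"condition {label!r} has sample indices out of range")

    row_index = {r: i for i, r in enumerate(row_ids)}
    targets: set[str] = set()
    for (src, dst), label, strength in planted_edges:
        if src not in row_index or dst not in row_index:
            raise ValueError(f"planted pair ({src!r}, {dst!r}) names unknown variables")
        if src == dst:
            raise ValueError("planted pair must join two distinct variables")
        if label not in blocks:
            raise ValueError(f"planted condition {label!r} is not a known block")
        if not 0 <= strength <= 1:
            raise ValueError("planted strength must lie in [0, 1]")
        if dst in targets:
            raise ValueError(f"variable {dst!r} is the copy target of two planted edges")
        targets.add(dst)

    rng = np.random.default_rng(derive_seed(seed, "planted"))
    states = np.array([DOWN, NOCHANGE, UP], dtype=np.int8)
    values = rng.choice(states, size=(n_sets, n_samples), p=marginals)

    for (src, dst), label, strength in planted_edges:
        i, j = row_index[src], row_index[dst]
        for s in blocks[label]:
            if rng.random() < strength:
                values[j, s] = values[i, s]

    if noise > 0:
        flip = rng.random(values.shape) < noise
        for i, j in zip(*np.nonzero(flip)):
            others = states[states != values[i, j]]
            values[i, j] = others[rng.integers(0, 2)]

    table = ConditionTable(
        {label: [sample_ids[s] for s in ix] for label, ix in blocks.items()},
        sample_ids,
    )
    return (
        TrinaryMatrix(values, row_ids, sample_ids),
        table,
        [tuple(e) for e in planted_edges],
    )
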