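"""Random small logical models and a brute-force oracle for cross-validation.

The generator samples the structural class the engine is built for: up to six
components, maximal levels 1 or 2, up to two constant inputs, arbitrary rule
tables.  The oracle recomputes targets, enabled transitions, priority
filtering and terminal SCCs from scratch with deliberately naive algorithms
(explicit edge lists, reachability closure by repeated BFS) and shares no
code with the dynamics module, so engine/oracle agreement is a meaningful
check of both.

Seeds are mandatory; there is no global random state anywhere.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .dynamics import PriorityScheme
from .logic_core import (
    DUAL,
    ComponentSpec,
    LogicalModel,
    Perturbation,
    RegulationEdge,
    Rule,
    State,
    validate_model,
)

__all__ = [
    "GeneratorConfig",
    "random_model",
    "random_two_class_scheme",
    "oracle_attractors",
    "oracle_stable_states",
    "oracle_edges",
    "toggle_switch",
    "repressilator",
]

ORACLE_STATE_CAP = 10**4


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling parameters for random models; generation is pure in these."""

    n_components: int = 4
    n_inputs: int = 0
    edge_density: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_components <= 6:
            raise ValueError("n_components must be in 2..6")
        if not 0 <= self.n_inputs <= min(2, self.n_components - 1):
            raise ValueError("n_inputs must be in 0..2 and leave a free component")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must be in (0, 1]")


def random_model(config: GeneratorConfig) -> LogicalModel:
    """Sample a valid random model; the same config yields the same model.

    Every ordered pair (source, non-input target) is an edge candidate with
    probability ``edge_density``; rule-less targets get one forced regulator
    so the model passes validation.  Rule tables are sampled uniformly over
    admissible target levels.
    """
    rng = np.random.default_rng(config.seed)
    names = [f"X{i + 1}" for i in range(config.n_components)]
    components = tuple(
        ComponentSpec(
            name,
            max_level=int(rng.integers(1, 3)),
            is_input=i < config.n_inputs,
        )
        for i, name in enumerate(names)
    )
    by_name = {c.name: c for c in components}
    targets = [c.name for c in components if not c.is_input]

    edges = []
    for src in names:
        for tgt in targets:
            if rng.random() < config.edge_density:
                edges.append(
                    RegulationEdge(
                        src, tgt,
                        threshold=int(rng.integers(1, by_name[src].max_level + 1)),
                        sign=DUAL,
                    )
                )
    regulated = {e.target for e in edges}
    for tgt in targets:
        if tgt not in regulated:
            src = names[int(rng.integers(0, len(names)))]
            edges.append(RegulationEdge(src, tgt, threshold=1, sign=DUAL))

    rules = {}
    for tgt in targets:
        regulators = tuple(sorted({e.source for e in edges if e.target == tgt}))
        axes = [range(by_name[r].max_level + 1) for r in regulators]
        table = {
            combo: int(rng.integers(0, by_name[tgt].max_level + 1))
            for combo in itertools.product(*axes)
        }
        rules[tgt] = Rule(regulators=regulators, table=table)

    model = LogicalModel(
        components=components,
        edges=tuple(edges),
        rules=rules,
        name=f"random_{config.seed}",
    )
    issues = validate_model(model)
    if issues:  # pragma: no cover - generator contract
        raise AssertionError(f"generated model invalid: {issues}")
    return model


def random_two_class_scheme(model: LogicalModel, seed: int) -> PriorityScheme:
    """Place each signed transition of each free component in rank 1 or 2.

    Two classes cover the shape of every setting used for the chicken model
    without attempting arbitrary rank depth.
    """
    rng = np.random.default_rng(seed)
    ranks = {}
    for c in model.components:
        if c.is_input:
            continue
        for direction in (+1, -1):
            ranks[(c.name, direction)] = int(rng.integers(1, 3))
    return PriorityScheme(ranks, default_rank=1, name=f"random2_{seed}")


# ---------------------------------------------------------------------------
# brute-force oracle: no code shared with the dynamics module
# ---------------------------------------------------------------------------

def _oracle_target(model: LogicalModel, state: Mapping[str, int], name: str,
                   perturbation: Mapping[str, int]) -> int:
    if name in perturbation:
        return perturbation[name]
    spec = next(c for c in model.components if c.name == name)
    if spec.is_input:
        return state[name]
    rule = model.rules[name]
    return rule.table[tuple(state[r] for r in rule.regulators)]


def _oracle_moves(model: LogicalModel, state: Mapping[str, int],
                  perturbation: Mapping[str, int],
                  scheme: PriorityScheme | None) -> list[tuple[str, int]]:
    moves = []
    for c in model.components:
        if c.is_input or c.name in perturbation:
            continue
        tgt = _oracle_target(model, state, c.name, perturbation)
        if tgt != state[c.name]:
            moves.append((c.name, 1 if tgt > state[c.name] else -1))
    if scheme is not None and scheme.ranks and moves:
        rank = {m: scheme.ranks.get(m, scheme.default_rank) for m in moves}
        best = min(rank.values())
        moves = [m for m in moves if rank[m] == best]
    return moves


def oracle_edges(
    model: LogicalModel,
    perturbation: Perturbation | None = None,
    scheme: PriorityScheme | None = None,
    root: State | None = None,
    inputs: Mapping[str, int] | None = None,
) -> tuple[set[tuple[int, ...]], set[tuple[tuple[int, ...], tuple[int, ...]]]]:
    """Materialize states and the explicit transition edge list."""
    pert = dict(perturbation or {})
    order = [c.name for c in model.components]

    def as_tuple(s: Mapping[str, int]) -> tuple[int, ...]:
        return tuple(s[n] for n in order)

    def as_dict(t: tuple[int, ...]) -> dict[str, int]:
        return dict(zip(order, t))

    states: set[tuple[int, ...]] = set()
    if root is not None:
        queue = [as_tuple(root)]
        states.add(queue[0])
        edges = set()
        while queue:
            t = queue.pop(0)
            s = as_dict(t)
            for name, d in _oracle_moves(model, s, pert, scheme):
                s2 = dict(s)
                s2[name] += d
                t2 = as_tuple(s2)
                edges.add((t, t2))
                if t2 not in states:
                    states.add(t2)
                    queue.append(t2)
                if len(states) > ORACLE_STATE_CAP:
                    raise RuntimeError("oracle state cap exceeded")
        return states, edges

    fixed = dict(inputs or {})
    fixed.update(pert)
    axes = []
    for c in model.components:
        if c.name in fixed:
            axes.append((fixed[c.name],))
        else:
            axes.append(tuple(range(c.max_level + 1)))
    total = 1
    for a in axes:
        total *= len(a)
    if total > ORACLE_STATE_CAP:
        raise RuntimeError("oracle state cap exceeded")
    edges = set()
    for combo in itertools.product(*axes):
        states.add(combo)
        s = as_dict(combo)
        for name, d in _oracle_moves(model, s, pert, scheme):
            s2 = dict(s)
            s2[name] += d
            edges.add((combo, as_tuple(s2)))
    return states, edges


def oracle_stable_states(
    model: LogicalModel,
    perturbation: Perturbation | None = None,
    inputs: Mapping[str, int] | None = None,
) -> set[tuple[int, ...]]:
    """Fixed points by exhaustive scan (scheme-independent by definition)."""
    states, edges = oracle_edges(model, perturbation, None, None, inputs)
    moving = {src for src, _ in edges}
    return states - moving


def oracle_attractors(
    model: LogicalModel,
    perturbation: Perturbation | None = None,
    scheme: PriorityScheme | None = None,
    root: State | None = None,
    inputs: Mapping[str, int] | None = None,
) -> frozenset[frozenset[tuple[int, ...]]]:
    """Terminal SCCs by repeated reachability closure over the edge list.

    Returns attractors as frozensets of state tuples (the model's component
    order), directly comparable with ``Attractor.state_tuples``.
    """
    states, edges = oracle_edges(model, perturbation, scheme, root, inputs)
    succ: dict[tuple[int, ...], list[tuple[int, ...]]] = {s: [] for s in states}
    for a, b in edges:
        succ[a].append(b)

    reach: dict[tuple[int, ...], set[tuple[int, ...]]] = {}
    for s in states:
        seen = {s}
        stack = [s]
        while stack:
            u = stack.pop()
            for v in succ[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        reach[s] = seen

    attractors = set()
    for s in states:
        scc = {t for t in reach[s] if s in reach[t]}
        if reach[s] <= scc:
            attractors.add(frozenset(scc))
    return frozenset(attractors)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def toggle_switch() -> LogicalModel:
    """Two mutually inhibiting Boolean genes with basal activation.

    The classic bistable switch: stable states (1,0) and (0,1) only.
    """
    components = (ComponentSpec("A"), ComponentSpec("B"))
    edges = (
        RegulationEdge("A", "B", sign="inhibition"),
        RegulationEdge("B", "A", sign="inhibition"),
    )
    rules = {
        "A": Rule(("B",), {(0,): 1, (1,): 0}),
        "B": Rule(("A",), {(0,): 1, (1,): 0}),
    }
    return LogicalModel(components, edges, rules, name="toggle_switch")


def repressilator() -> LogicalModel:
    """Three Boolean genes in an inhibition ring: a single cyclic attractor.

    The odd negative circuit admits no fixed point under asynchronous
    update, exercising the cyclic-attractor branch of the engine.
    """
    components = (ComponentSpec("A"), ComponentSpec("B"), ComponentSpec("C"))
    edges = (
        RegulationEdge("A", "B", sign="inhibition"),
        RegulationEdge("B", "C", sign="inhibition"),
        RegulationEdge("C", "A", sign="inhibition"),
    )
    inv = {(0,): 1, (1,): 0}
    rules = {
        "B": Rule(("A",), dict(inv)),
        "C": Rule(("B",), dict(inv)),
        "A": Rule(("C",), dict(inv)),
    }
    return LogicalModel(components, edges, rules, name="repressilator")
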