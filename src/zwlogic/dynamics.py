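"""Asynchronous state-transition graphs, stable states and attractors.

The asynchronous dynamics can be refined by *priority classes*: a ranked
partition of signed transitions encoding qualitative rate assumptions.  In
any state, only enabled transitions of the fastest occupied rank may fire;
filtering therefore only ever removes edges from the unrestricted graph, and
fixed points are independent of the scheme.

Attractors are the terminal strongly connected components of the (rooted,
priority-filtered) graph.  State spaces in this package are tiny (<=10^6 by
default cap), so exploration is exhaustive breadth-first enumeration — exact
and deterministic, with no sampling or random tie-breaking anywhere.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .logic_core import (
    LogicalModel,
    Perturbation,
    State,
    Transition,
    enabled_transitions,
    successor,
)

__all__ = [
    "PriorityScheme",
    "StateTransitionGraph",
    "Attractor",
    "StateSpaceCapExceeded",
    "filter_by_priority",
    "build_stg",
    "stable_states",
    "reachable_attractors",
]

DEFAULT_STATE_CAP = 10**6


class StateSpaceCapExceeded(RuntimeError):
    """Raised when exploration would visit more states than the cap allows."""


@dataclass(frozen=True)
class PriorityScheme:
    """Ranked classes of signed transitions; rank 1 is fastest.

    ``ranks`` maps (component, direction) to its class rank; transitions not
    named by any class fall into ``default_rank``.  The empty scheme (no
    classes) is the plain asynchronous update.
    """

    ranks: Mapping[tuple[str, int], int] = field(default_factory=dict)
    default_rank: int = 1
    name: str = "none"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranks", dict(self.ranks))
        for (comp, direction), rank in self.ranks.items():
            if direction not in (1, -1):
                raise ValueError(f"{comp}: direction must be +1/-1")
            if rank < 1:
                raise ValueError(f"{comp}: rank must be >= 1")
        if self.default_rank < 1:
            raise ValueError("default_rank must be >= 1")

    def rank_of(self, transition: Transition) -> int:
        return self.ranks.get((transition.component, transition.direction), self.default_rank)

    @property
    def is_empty(self) -> bool:
        return not self.ranks


def filter_by_priority(
    enabled: Iterable[Transition], scheme: PriorityScheme | None
) -> frozenset[Transition]:
    """Keep only enabled transitions of the minimal occupied rank."""
    enabled = frozenset(enabled)
    if scheme is None or scheme.is_empty or not enabled:
        return enabled
    best = min(scheme.rank_of(t) for t in enabled)
    return frozenset(t for t in enabled if scheme.rank_of(t) == best)


@dataclass
class StateTransitionGraph:
    """Priority-filtered asynchronous dynamics over (part of) a state space.

    Vertices are state tuples in the model's component order; edges carry the
    fired transition as label.  ``root`` is set for reachability-restricted
    graphs and None for full-space graphs.
    """

    model: LogicalModel
    graph: nx.DiGraph
    perturbation: dict[str, int]
    scheme: PriorityScheme
    root: tuple[int, ...] | None = None

    @property
    def n_states(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_transitions(self) -> int:
        return self.graph.number_of_edges()

    def states(self) -> Iterator[dict[str, int]]:
        for node in self.graph.nodes:
            yield self.model.state_dict(node)

    def attractors(self) -> list["Attractor"]:
        """Terminal strongly connected components, stable states flagged."""
        out = []
        for scc in nx.strongly_connected_components(self.graph):
            if all(v in scc for u in scc for v in self.graph.successors(u)):
                out.append(Attractor.from_tuples(self.model, scc))
        out.sort(key=lambda a: min(a._tuples))
        return out

    def attractor_states(self) -> frozenset[tuple[int, ...]]:
        return frozenset(t for a in self.attractors() for t in a._tuples)


@dataclass(frozen=True)
class Attractor:
    """A terminal SCC of the dynamics: a stable state or a cyclic attractor."""

    model: LogicalModel
    _tuples: frozenset[tuple[int, ...]]

    @classmethod
    def from_tuples(cls, model: LogicalModel, tuples: Iterable[tuple[int, ...]]) -> "Attractor":
        tuples = frozenset(tuples)
        if not tuples:
            raise ValueError("attractor cannot be empty")
        return cls(model, tuples)

    @property
    def kind(self) -> str:
        return "stable_state" if len(self._tuples) == 1 else "cyclic"

    @property
    def state_tuples(self) -> frozenset[tuple[int, ...]]:
        """States as level tuples in the model's component order."""
        return self._tuples

    @property
    def is_stable_state(self) -> bool:
        return len(self._tuples) == 1

    @property
    def states(self) -> tuple[dict[str, int], ...]:
        return tuple(self.model.state_dict(t) for t in sorted(self._tuples))

    @property
    def state(self) -> dict[str, int]:
        if not self.is_stable_state:
            raise ValueError("not a stable state; use .states")
        return self.states[0]

    def __len__(self) -> int:
        return len(self._tuples)

    def __str__(self) -> str:
        body = "; ".join(
            "|".join(f"{k}:{v}" for k, v in s.items()) for s in self.states
        )
        return f"<{self.kind} {body}>"


def _filtered_transitions(
    model: LogicalModel,
    state: dict[str, int],
    perturbation: Perturbation | None,
    scheme: PriorityScheme | None,
) -> frozenset[Transition]:
    return filter_by_priority(enabled_transitions(model, state, perturbation), scheme)


def _full_space(
    model: LogicalModel,
    perturbation: Perturbation | None,
    inputs: Mapping[str, int],
    cap: int,
) -> Iterator[dict[str, int]]:
    """All states with inputs and clamped components fixed."""
    fixed = dict(inputs)
    for name, value in (perturbation or {}).items():
        fixed[name] = value
    axes = []
    n = 1
    for spec in model.components:
        if spec.name in fixed:
            axes.append((fixed[spec.name],))
        else:
            axes.append(tuple(spec.levels))
        n *= len(axes[-1])
        if n > cap:
            raise StateSpaceCapExceeded(f"state space exceeds cap of {cap}")
    for combo in itertools.product(*axes):
        yield model.state_dict(combo)


def build_stg(
    model: LogicalModel,
    perturbation: Perturbation | None = None,
    scheme: PriorityScheme | None = None,
    root: State | None = None,
    inputs: Mapping[str, int] | None = None,
    cap: int = DEFAULT_STATE_CAP,
) -> StateTransitionGraph:
    """Build the priority-filtered asynchronous state transition graph.

    With a *root*, the graph is restricted to states reachable from it (input
    levels are taken from the root).  Without one, the full state space is
    enumerated with input components fixed to *inputs* (required if the model
    has inputs) and clamped components fixed to their clamp values.
    """
    scheme = scheme or PriorityScheme()
    perturbation = dict(perturbation or {})
    g = nx.DiGraph()

    if root is not None:
        model.check_state(root)
        root_t = model.state_tuple(root)
        frontier = [root_t]
        g.add_node(root_t)
        while frontier:
            node = frontier.pop()
            state = model.state_dict(node)
            for tr in sorted(_filtered_transitions(model, state, perturbation, scheme),
                             key=lambda t: (t.component, t.direction)):
                nxt = model.state_tuple(successor(state, tr))
                if nxt not in g:
                    if g.number_of_nodes() >= cap:
                        raise StateSpaceCapExceeded(f"reachable set exceeds cap of {cap}")
                    g.add_node(nxt)
                    frontier.append(nxt)
                g.add_edge(node, nxt, transition=tr)
        return StateTransitionGraph(model, g, perturbation, scheme, root=root_t)

    if inputs is None:
        if model.inputs:
            raise ValueError("full-graph mode needs input levels for " + ", ".join(model.inputs))
        inputs = {}
    for state in _full_space(model, perturbation, inputs, cap):
        node = model.state_tuple(state)
        g.add_node(node)
        for tr in _filtered_transitions(model, state, perturbation, scheme):
            g.add_edge(node, model.state_tuple(successor(state, tr)), transition=tr)
    return StateTransitionGraph(model, g, perturbation, scheme, root=None)


def stable_states(
    model: LogicalModel,
    perturbation: Perturbation | None = None,
    inputs: Mapping[str, int] | None = None,
    cap: int = DEFAULT_STATE_CAP,
) -> list[dict[str, int]]:
    """All fixed points, by direct enumeration of the (fixed-input) space.

    Stability does not depend on any priority scheme: a state is stable iff
    no transition at all is enabled.
    """
    if inputs is None:
        if model.inputs:
            raise ValueError("need input levels for " + ", ".join(model.inputs))
        inputs = {}
    out = []
    for state in _full_space(model, perturbation, inputs, cap):
        if not enabled_transitions(model, state, perturbation):
            out.append(state)
    out.sort(key=model.state_tuple)
    return out


def reachable_attractors(
    model: LogicalModel,
    perturbation: Perturbation | None = None,
    scheme: PriorityScheme | None = None,
    root: State | None = None,
    cap: int = DEFAULT_STATE_CAP,
) -> list[Attractor]:
    """Attractors of the rooted, priority-filtered dynamics.

    Terminal SCCs of the reachable graph, sorted by their smallest state
    tuple for determinism.
    """
    if root is None:
        raise ValueError("reachable_attractors requires a root state")
    stg = build_stg(model, perturbation, scheme, root=root, cap=cap)
    return stg.attractors()
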