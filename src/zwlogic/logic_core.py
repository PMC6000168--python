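"""Core types and elementary update semantics of multilevel logical models.

A logical model (Thomas formalism) is a directed graph of regulatory
components.  Each component carries a discrete level in ``[0, max_level]``;
a rule (stored as an explicit truth table over the levels of its regulators)
gives the *target* level toward which the component is called.  Dynamics are
asynchronous with unit steps: an enabled component moves one level toward its
target per transition, and the target is re-evaluated in every state.

Inputs (e.g. sex-chromosome constitution) hold their value forever; mutations
are modelled by clamping components to fixed levels (loss of function: 0,
gain of function: a higher level), which overrides the component's rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ComponentSpec",
    "RegulationEdge",
    "Rule",
    "LogicalModel",
    "State",
    "Transition",
    "Perturbation",
    "ValidationIssue",
    "target_level",
    "enabled_transitions",
    "successor",
    "validate_model",
]

#: A state assigns a discrete level to every component.
State = Mapping[str, int]

#: A perturbation clamps components to fixed levels (possibly empty).
Perturbation = Mapping[str, int]

ACTIVATION = "activation"
INHIBITION = "inhibition"
DUAL = "dual"
_SIGNS = (ACTIVATION, INHIBITION, DUAL)


@dataclass(frozen=True)
class ComponentSpec:
    """A regulatory component with a maximal qualitative level.

    ``max_level`` is 1 for Boolean components; multilevel variables (e.g.
    DMRT1 with levels 0/1/2) use higher maxima when distinct functional
    concentrations matter.  Inputs never change level.
    """

    name: str
    max_level: int = 1
    is_input: bool = False

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise ValueError("component name must be a non-empty string")
        if self.max_level < 1:
            raise ValueError(f"{self.name}: max_level must be >= 1")

    @property
    def levels(self) -> range:
        return range(self.max_level + 1)


@dataclass(frozen=True)
class RegulationEdge:
    """A regulatory interaction with an activity threshold.

    The threshold is the smallest level of the source at which the
    interaction is operative (1 by default).
    """

    source: str
    target: str
    threshold: int = 1
    sign: str = ACTIVATION

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError(f"{self.source}->{self.target}: threshold must be >= 1")
        if self.sign not in _SIGNS:
            raise ValueError(f"{self.source}->{self.target}: unknown sign {self.sign!r}")


@dataclass(frozen=True)
class Rule:
    """Target-level function of one component, as an explicit truth table.

    ``regulators`` fixes the tuple order of the table keys; ``table`` maps
    every combination of regulator levels to a target level.  Explicit tables
    make the "depends only on regulators" invariant mechanically checkable
    and keep the on-disk format dialect-free.
    """

    regulators: tuple[str, ...]
    table: Mapping[tuple[int, ...], int]

    def __call__(self, state: State) -> int:
        key = tuple(state[r] for r in self.regulators)
        try:
            return self.table[key]
        except KeyError:
            raise KeyError(
                f"rule table has no row for regulator levels {key} of {self.regulators}"
            ) from None


@dataclass(frozen=True)
class Transition:
    """A signed unit change of one free component (+1 or -1)."""

    component: str
    direction: int

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")

    def __str__(self) -> str:
        return f"{self.component}{'+' if self.direction > 0 else '-'}"


@dataclass(frozen=True)
class ValidationIssue:
    where: str
    message: str

    def __str__(self) -> str:
        return f"{self.where}: {self.message}"


@dataclass
class LogicalModel:
    """A multilevel logical model: components, regulatory edges and rules.

    Component order is significant: it fixes state-tuple layout and label
    order in every export.
    """

    components: Sequence[ComponentSpec]
    edges: Sequence[RegulationEdge]
    rules: Mapping[str, Rule]
    name: str = "model"
    _index: dict[str, ComponentSpec] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.components = tuple(self.components)
        self.edges = tuple(self.edges)
        self.rules = dict(self.rules)
        self._index = {c.name: c for c in self.components}
        if len(self._index) != len(self.components):
            raise ValueError("duplicate component names")

    # -- lookups -----------------------------------------------------------
    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    def component(self, name: str) -> ComponentSpec:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown component {name!r}") from None

    def regulators_of(self, name: str) -> tuple[str, ...]:
        """Sources of edges into *name*, in edge-list order (deduplicated)."""
        seen: dict[str, None] = {}
        for e in self.edges:
            if e.target == name:
                seen.setdefault(e.source, None)
        return tuple(seen)

    @property
    def inputs(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components if c.is_input)

    def free_components(self, perturbation: Perturbation | None = None) -> tuple[str, ...]:
        clamped = set(perturbation or ())
        return tuple(
            c.name for c in self.components if not c.is_input and c.name not in clamped
        )

    def state_space_size(self) -> int:
        n = 1
        for c in self.components:
            n *= c.max_level + 1
        return n

    # -- state helpers -----------------------------------------------------
    def state_tuple(self, state: State) -> tuple[int, ...]:
        return tuple(state[name] for name in self.component_names)

    def state_dict(self, levels: Iterable[int]) -> dict[str, int]:
        return dict(zip(self.component_names, levels, strict=True))

    def check_state(self, state: State) -> None:
        """Raise ValueError naming the offending component if invalid."""
        for c in self.components:
            if c.name not in state:
                raise ValueError(f"state missing component {c.name!r}")
            v = state[c.name]
            if not isinstance(v, int) or not 0 <= v <= c.max_level:
                raise ValueError(
                    f"state level {v!r} of {c.name!r} outside [0, {c.max_level}]"
                )


def target_level(
    model: LogicalModel,
    state: State,
    component: str,
    perturbation: Perturbation | None = None,
) -> int:
    """The level toward which *component* is called in *state*.

    Clamped components return their clamp value, inputs their current value;
    otherwise the rule's target.  Pure in (regulator levels, clamp map).
    """
    spec = model.component(component)
    model.check_state(state)
    if perturbation and component in perturbation:
        value = perturbation[component]
        if not 0 <= value <= spec.max_level:
            raise ValueError(
                f"clamp value {value} of {component!r} outside [0, {spec.max_level}]"
            )
        return value
    if spec.is_input:
        return state[component]
    try:
        rule = model.rules[component]
    except KeyError:
        raise KeyError(f"no rule for non-input component {component!r}") from None
    target = rule(state)
    if not 0 <= target <= spec.max_level:
        raise ValueError(
            f"rule of {component!r} returned {target} outside [0, {spec.max_level}]"
        )
    return target


def enabled_transitions(
    model: LogicalModel,
    state: State,
    perturbation: Perturbation | None = None,
) -> frozenset[Transition]:
    """All unit transitions called in *state* under asynchronous update.

    One transition per free, non-input component whose target differs from
    its current level; the direction is the sign of (target - current).
    Empty iff the state is stable.
    """
    out = []
    for name in model.free_components(perturbation):
        current = state[name]
        target = target_level(model, state, name, perturbation)
        if target > current:
            out.append(Transition(name, +1))
        elif target < current:
            out.append(Transition(name, -1))
    return frozenset(out)


def successor(state: State, transition: Transition) -> dict[str, int]:
    """The state after firing *transition*: one component moved by one unit."""
    nxt = dict(state)
    nxt[transition.component] = state[transition.component] + transition.direction
    return nxt


def validate_model(model: LogicalModel) -> list[ValidationIssue]:
    """Structural validation; an empty report means the model is well formed.

    Checks edge endpoints and thresholds, rule totality and ranges, that
    rules only read declared regulators, and that every non-input component
    has a rule (degenerate rule-less components are rejected).
    """
    issues: list[ValidationIssue] = []
    names = set(model.component_names)

    for e in model.edges:
        where = f"edge {e.source}->{e.target}"
        if e.source not in names:
            issues.append(ValidationIssue(where, f"unknown source {e.source!r}"))
            continue
        if e.target not in names:
            issues.append(ValidationIssue(where, f"unknown target {e.target!r}"))
            continue
        src_max = model.component(e.source).max_level
        if e.threshold > src_max:
            issues.append(
                ValidationIssue(where, f"threshold {e.threshold} > max_level {src_max} of source")
            )
        if model.component(e.target).is_input:
            issues.append(ValidationIssue(where, "input components cannot be regulated"))

    for spec in model.components:
        if spec.is_input:
            if spec.name in model.rules:
                issues.append(ValidationIssue(f"rule {spec.name}", "inputs carry no rule"))
            continue
        rule = model.rules.get(spec.name)
        if rule is None:
            issues.append(ValidationIssue(f"rule {spec.name}", "missing rule for non-input component"))
            continue
        declared = set(model.regulators_of(spec.name))
        extra = set(rule.regulators) - declared
        if extra:
            issues.append(
                ValidationIssue(
                    f"rule {spec.name}",
                    f"depends on non-regulators {sorted(extra)} (no incoming edge)",
                )
            )
        missing_reg = declared - set(rule.regulators)
        if missing_reg:
            issues.append(
                ValidationIssue(
                    f"rule {spec.name}",
                    f"regulators {sorted(missing_reg)} absent from rule table",
                )
            )
        bad_names = [r for r in rule.regulators if r not in names]
        if bad_names:
            issues.append(
                ValidationIssue(f"rule {spec.name}", f"unknown regulators {bad_names}")
            )
            continue
        # totality and range of the table
        ranges = [model.component(r).levels for r in rule.regulators]
        expected = 1
        for r in ranges:
            expected *= len(r)
        if len(rule.table) != expected:
            issues.append(
                ValidationIssue(
                    f"rule {spec.name}",
                    f"table has {len(rule.table)} rows, expected {expected} (not total)",
                )
            )
        for key, value in rule.table.items():
            if len(key) != len(rule.regulators):
                issues.append(
                    ValidationIssue(
                        f"rule {spec.name}", f"row {key} arity != {len(rule.regulators)} regulators"
                    )
                )
                continue
            if any(k not in rng for k, rng in zip(key, ranges)):
                issues.append(
                    ValidationIssue(f"rule {spec.name}", f"row {key} outside regulator ranges")
                )
            if not 0 <= value <= spec.max_level:
                issues.append(
                    ValidationIssue(
                        f"rule {spec.name}",
                        f"row {key} targets {value} outside [0, {spec.max_level}]",
                    )
                )
    return issues
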