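"""Canonical JSON serialization of models and graph export.

Models are stored with explicit rule truth tables — the native in-memory
representation — in a canonical text form (UTF-8, sorted keys, rows sorted
lexicographically by regulator tuple, newline-terminated) so documents are
diff-stable and round-trips are bit-identical.  State transition graphs
export to DOT and GraphML with states labelled in fixed component order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import IO, Union

import networkx as nx

from .dynamics import StateTransitionGraph
from .logic_core import (
    ComponentSpec,
    LogicalModel,
    RegulationEdge,
    Rule,
    validate_model,
)

__all__ = [
    "FORMAT_VERSION",
    "SchemaError",
    "model_to_document",
    "document_to_model",
    "write_model",
    "read_model",
    "dumps_model",
    "loads_model",
    "export_stg",
    "state_label",
]

FORMAT_VERSION = 1

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """A malformed model document; ``path`` locates the offending element."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


def model_to_document(model: LogicalModel) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "name": model.name,
        "components": [
            {"name": c.name, "max_level": c.max_level, "is_input": c.is_input}
            for c in model.components
        ],
        "edges": [
            {"source": e.source, "target": e.target,
             "threshold": e.threshold, "sign": e.sign}
            for e in model.edges
        ],
        "rules": {
            name: {
                "regulators": list(rule.regulators),
                "rows": [
                    [list(key), rule.table[key]] for key in sorted(rule.table)
                ],
            }
            for name, rule in sorted(model.rules.items())
        },
    }


def dumps_model(model: LogicalModel) -> str:
    """Canonical JSON text; deterministic for a given model."""
    return json.dumps(model_to_document(model), sort_keys=True, indent=1) + "\n"


def _expect(obj, key, kind, path):
    if not isinstance(obj, dict):
        raise SchemaError(path, f"expected object, got {type(obj).__name__}")
    if key not in obj:
        raise SchemaError(f"{path}.{key}", "missing")
    value = obj[key]
    if not isinstance(value, kind) or (kind is int and isinstance(value, bool) and key != "is_input"):
        raise SchemaError(f"{path}.{key}", f"expected {kind.__name__}")
    return value


def document_to_model(doc: dict) -> LogicalModel:
    """Parse and validate a model document; raises SchemaError with the path
    to the offending element, then runs structural validation."""
    version = _expect(doc, "format_version", int, "$")
    if version != FORMAT_VERSION:
        raise SchemaError("$.format_version",
                          f"unsupported version {version}, expected {FORMAT_VERSION}")
    name = _expect(doc, "name", str, "$")

    components = []
    for i, c in enumerate(_expect(doc, "components", list, "$")):
        p = f"$.components[{i}]"
        components.append(ComponentSpec(
            name=_expect(c, "name", str, p),
            max_level=_expect(c, "max_level", int, p),
            is_input=bool(_expect(c, "is_input", bool, p)),
        ))

    edges = []
    for i, e in enumerate(_expect(doc, "edges", list, "$")):
        p = f"$.edges[{i}]"
        edges.append(RegulationEdge(
            source=_expect(e, "source", str, p),
            target=_expect(e, "target", str, p),
            threshold=_expect(e, "threshold", int, p),
            sign=_expect(e, "sign", str, p),
        ))

    rules = {}
    for comp, spec in sorted(_expect(doc, "rules", dict, "$").items()):
        p = f"$.rules.{comp}"
        regulators = tuple(_expect(spec, "regulators", list, p))
        if not all(isinstance(r, str) for r in regulators):
            raise SchemaError(f"{p}.regulators", "regulator names must be strings")
        table = {}
        for j, row in enumerate(_expect(spec, "rows", list, p)):
            rp = f"{p}.rows[{j}]"
            if (not isinstance(row, list) or len(row) != 2
                    or not isinstance(row[0], list) or not isinstance(row[1], int)):
                raise SchemaError(rp, "expected [levels, target] pair")
            key = tuple(row[0])
            if len(key) != len(regulators):
                raise SchemaError(rp, f"tuple arity {len(key)} != {len(regulators)} regulators")
            if not all(isinstance(k, int) and not isinstance(k, bool) for k in key):
                raise SchemaError(rp, "levels must be integers")
            if key in table:
                raise SchemaError(rp, f"duplicate row for {key}")
            table[key] = row[1]
        rules[comp] = Rule(regulators=regulators, table=table)

    model = LogicalModel(components=components, edges=edges, rules=rules, name=name)
    issues = validate_model(model)
    if issues:
        raise SchemaError("$", "model fails validation: " + "; ".join(map(str, issues)))
    return model


def loads_model(text: str) -> LogicalModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError("$", f"not valid JSON: {exc}") from exc
    return document_to_model(doc)


def write_model(model: LogicalModel, destination: PathLike | IO[str]) -> str:
    """Write canonical JSON; returns the text written."""
    text = dumps_model(model)
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text, encoding="utf-8")
    return text


def read_model(source: PathLike | IO[str]) -> LogicalModel:
    if hasattr(source, "read"):
        return loads_model(source.read())
    return loads_model(Path(source).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# state transition graph export
# ---------------------------------------------------------------------------

def state_label(model: LogicalModel, node: tuple[int, ...]) -> str:
    """Fixed-order state label, e.g. ``DMRT1:2|SOX9:1|...``."""
    return "|".join(f"{n}:{v}" for n, v in zip(model.component_names, node))


def export_stg(stg: StateTransitionGraph, fmt: str, destination: PathLike | IO[str]) -> None:
    """Export a state transition graph as DOT or GraphML.

    One node per state, labelled in fixed component order; attractor members
    carry ``attractor=true`` (and double peripheries in DOT); edges carry the
    fired transition.
    """
    fmt = fmt.lower()
    if fmt not in ("dot", "graphml"):
        raise ValueError(f"unknown format {fmt!r}; expected 'dot' or 'graphml'")

    model = stg.model
    marked = stg.attractor_states()

    if fmt == "dot":
        lines = [f'digraph "{model.name}" {{']
        for node in sorted(stg.graph.nodes):
            attrs = [f'label="{state_label(model, node)}"']
            if node in marked:
                attrs.append("peripheries=2")
                attrs.append('attractor="true"')
            lines.append(f'  "{state_label(model, node)}" [{", ".join(attrs)}];')
        for a, b, data in sorted(stg.graph.edges(data=True)):
            tr = data["transition"]
            lines.append(
                f'  "{state_label(model, a)}" -> "{state_label(model, b)}" [label="{tr}"];'
            )
        lines.append("}")
        text = "\n".join(lines) + "\n"
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            Path(destination).write_text(text, encoding="utf-8")
        return

    g = nx.DiGraph(name=model.name)
    for node in stg.graph.nodes:
        g.add_node(state_label(model, node), attractor=int(node in marked))
    for a, b, data in stg.graph.edges(data=True):
        g.add_edge(state_label(model, a), state_label(model, b), label=str(data["transition"]))
    if hasattr(destination, "write"):
        nx.write_graphml(g, destination)
    else:
        nx.write_graphml(g, str(destination))
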