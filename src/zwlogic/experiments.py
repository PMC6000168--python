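"""The simulation campaign: wild-type, mutant and chromosomal-variant gonads.

Each experiment fixes a genotype, an initial DMRT1 level, a perturbation
(loss or gain of function as value clamps) and a priority setting, then asks
which attractors the asynchronous dynamics reaches from the undifferentiated
initial state and what gonadal phenotype each one encodes.

Expected outcomes are data (``EXPECTED_OUTCOMES``), kept separate from the
runner so the regression surface is explicit and auditable row by row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .chicken import (
    NEITHER,
    OVARY,
    TESTIS,
    build_chicken_model,
    classify_phenotype,
    initial_state,
    priority_scheme,
)
from .dynamics import Attractor, build_stg
from .logic_core import LogicalModel

__all__ = [
    "ExperimentSpec",
    "ExperimentResult",
    "Table2Row",
    "EXPECTED_OUTCOMES",
    "run_experiment",
    "mutant_catalog",
    "reproduce_table2",
]

BOTH = "both"


@dataclass(frozen=True)
class ExperimentSpec:
    """One simulation setting of the campaign."""

    label: str
    genotype: str
    dmrt1_init: int = 1
    perturbation: Mapping[str, int] = field(default_factory=dict)
    scheme: str = "none"

    def __post_init__(self) -> None:
        object.__setattr__(self, "perturbation", dict(self.perturbation))


@dataclass(frozen=True)
class ExperimentResult:
    """Attractors reached by one experiment, with phenotype calls.

    Phenotype calls are recomputed from the attractor state vectors, never
    stored free-hand.  ``deterministic`` is True when a single attractor is
    reached.
    """

    spec: ExperimentSpec
    attractors: tuple[Attractor, ...]
    n_states_explored: int

    @property
    def phenotypes(self) -> tuple[str, ...]:
        calls = []
        for a in self.attractors:
            # a cyclic attractor has no single phenotype; call each state and
            # collapse only if unanimous
            votes = {classify_phenotype(s, self.spec.perturbation) for s in a.states}
            calls.append(votes.pop() if len(votes) == 1 else NEITHER)
        return tuple(calls)

    @property
    def deterministic(self) -> bool:
        return len(self.attractors) == 1

    @property
    def outcome(self) -> str:
        """Collapsed phenotype: a single call, 'both' for ovary+testis, else
        the sorted joined calls."""
        calls = set(self.phenotypes)
        if len(calls) == 1:
            return calls.pop()
        if calls == {OVARY, TESTIS}:
            return BOTH
        return "+".join(sorted(calls))


def run_experiment(spec: ExperimentSpec, model: LogicalModel | None = None) -> ExperimentResult:
    """Run one experiment: reachable attractors from its initial state."""
    model = model or build_chicken_model()
    root = initial_state(spec.genotype, spec.dmrt1_init, spec.perturbation)
    stg = build_stg(
        model,
        perturbation=spec.perturbation,
        scheme=priority_scheme(spec.scheme),
        root=root,
    )
    return ExperimentResult(spec, tuple(stg.attractors()), stg.n_states)


def mutant_catalog() -> list[ExperimentSpec]:
    """The fixed 21-experiment catalogue: wild types, mutants, Z0 and ZZW."""
    return [
        # wild-type gonads
        ExperimentSpec("ZZ wild type", "ZZ"),
        ExperimentSpec("ZZ wild type (PC1)", "ZZ", scheme="PC1"),
        ExperimentSpec("ZW wild type", "ZW"),
        ExperimentSpec("ZW wild type (PC2)", "ZW", scheme="PC2"),
        ExperimentSpec("ZW wild type, DMRT1 init 0", "ZW", dmrt1_init=0),
        # loss- and gain-of-function mutants
        ExperimentSpec("DMRT1 LOF ZZ", "ZZ", perturbation={"DMRT1": 0}),
        ExperimentSpec("DMRT1 GOF ZW", "ZW", perturbation={"DMRT1": 2}),
        ExperimentSpec("DMRT1 partial GOF ZW", "ZW", perturbation={"DMRT1": 1}),
        ExperimentSpec("HEMGN LOF ZZ", "ZZ", perturbation={"HEMGN": 0}),
        ExperimentSpec("HEMGN GOF ZW (PC1)", "ZW", perturbation={"HEMGN": 1}, scheme="PC1"),
        ExperimentSpec("SOX9 LOF ZZ (PC1)", "ZZ", perturbation={"SOX9": 0}, scheme="PC1"),
        ExperimentSpec("SOX9+HEMGN LOF ZZ", "ZZ", perturbation={"SOX9": 0, "HEMGN": 0}),
        ExperimentSpec("SOX9 GOF ZW", "ZW", perturbation={"SOX9": 1}),
        ExperimentSpec("FOXL2 LOF ZW (PC3)", "ZW", perturbation={"FOXL2": 0}, scheme="PC3"),
        ExperimentSpec("FOXL2 GOF ZZ", "ZZ", perturbation={"FOXL2": 1}),
        ExperimentSpec("AROMATASE LOF ZW (PC3)", "ZW", perturbation={"AROMATASE": 0}, scheme="PC3"),
        ExperimentSpec("AROMATASE GOF ZZ (PC4)", "ZZ", perturbation={"AROMATASE": 1}, scheme="PC4"),
        ExperimentSpec("OESTROGEN LOF ZW (PC3)", "ZW", perturbation={"OESTROGEN": 0}, scheme="PC3"),
        ExperimentSpec("OESTROGEN GOF ZZ (PC4)", "ZZ", perturbation={"OESTROGEN": 1}, scheme="PC4"),
        # chromosomal variants
        ExperimentSpec("Z0", "Z0"),
        ExperimentSpec("ZZW", "ZZW"),
    ]


#: Narrated outcome for every catalogue row; the regression surface.
EXPECTED_OUTCOMES: Mapping[str, str] = {
    "ZZ wild type": BOTH,
    "ZZ wild type (PC1)": TESTIS,
    "ZW wild type": BOTH,
    "ZW wild type (PC2)": OVARY,
    "ZW wild type, DMRT1 init 0": OVARY,
    "DMRT1 LOF ZZ": OVARY,
    "DMRT1 GOF ZW": TESTIS,
    "DMRT1 partial GOF ZW": OVARY,
    "HEMGN LOF ZZ": OVARY,
    "HEMGN GOF ZW (PC1)": TESTIS,
    "SOX9 LOF ZZ (PC1)": NEITHER,
    "SOX9+HEMGN LOF ZZ": OVARY,
    "SOX9 GOF ZW": TESTIS,
    "FOXL2 LOF ZW (PC3)": TESTIS,
    "FOXL2 GOF ZZ": OVARY,
    "AROMATASE LOF ZW (PC3)": TESTIS,
    "AROMATASE GOF ZZ (PC4)": OVARY,
    "OESTROGEN LOF ZW (PC3)": TESTIS,
    "OESTROGEN GOF ZZ (PC4)": OVARY,
    "Z0": BOTH,
    "ZZW": BOTH,
}


@dataclass(frozen=True)
class Table2Row:
    """One report row: the experiment, what it reached, and the expectation."""

    spec: ExperimentSpec
    result: ExperimentResult
    expected: str

    @property
    def matches(self) -> bool:
        return self.result.outcome == self.expected


def reproduce_table2(model: LogicalModel | None = None) -> list[Table2Row]:
    """Run the full catalogue and compare against the expectation table.

    Mismatches are reported per row (``Table2Row.matches``), never raised
    mid-run.
    """
    model = model or build_chicken_model()
    rows = []
    for spec in mutant_catalog():
        result = run_experiment(spec, model)
        rows.append(Table2Row(spec, result, EXPECTED_OUTCOMES[spec.label]))
    return rows


def table2_tsv(rows: Sequence[Table2Row], component_order: Sequence[str]) -> str:
    """Render report rows as TSV, one line per attractor, fixed column order."""
    header = ["experiment", "genotype", "perturbation", "scheme",
              *component_order, "phenotype", "outcome", "expected", "match"]
    lines = ["\t".join(header)]
    for row in rows:
        pert = ",".join(f"{k}={v}" for k, v in sorted(row.spec.perturbation.items())) or "-"
        for attractor, phenotype in zip(row.result.attractors, row.result.phenotypes):
            for state in attractor.states:
                lines.append("\t".join([
                    row.spec.label, row.spec.genotype, pert, row.spec.scheme,
                    *(str(state[c]) for c in component_order),
                    phenotype, row.result.outcome, row.expected,
                    "yes" if row.matches else "NO",
                ]))
    return "\n".join(lines) + "\n"
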