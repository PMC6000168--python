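"""The chicken primary sex-determination network as a logical model.

Nine components: three constant inputs carrying the sex-chromosome
constitution (Z1 and Z2, one per Z chromosome, each "acting as a DMRT1
activator"; W, the W-linked factor repressing DMRT1 through the MHM region),
the ternary Z-linked candidate primary signal DMRT1 (levels 0/1/2 encode the
Z-dosage hypothesis), and five Boolean genes: HEMGN, SOX9 and the
female-promoting cascade FOXL2 -> AROMATASE -> OESTROGEN.

The wiring integrates both prevailing hypotheses — Z dosage and dominant W —
and resolves sex through the DMRT1/FOXL2 cross-inhibition: two Z doses keep
DMRT1 at its intermediate level, HEMGN boosts it to level 2, which switches
on SOX9; SOX9 auto-regulation then locks DMRT1 high and blocks FOXL2.  With
a single effective Z dose (or the W factor active), DMRT1 decays, FOXL2
rises, and the hormonal cascade maintains the ovarian programme.

Priority classes PC1-PC4 encode the qualitative rate restrictions under
which a single sexual fate is reached (e.g. PC1: DMRT1 and HEMGN increases
outpace the basal FOXL2 increase in ZZ gonads).
"""

from __future__ import annotations

import itertools
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping

from .dynamics import PriorityScheme
from .logic_core import (
    ACTIVATION,
    INHIBITION,
    ComponentSpec,
    LogicalModel,
    Perturbation,
    RegulationEdge,
    Rule,
    State,
)

__all__ = [
    "COMPONENT_ORDER",
    "GENOTYPES",
    "PRIORITY_NAMES",
    "TESTIS",
    "OVARY",
    "NEITHER",
    "build_chicken_model",
    "bundled_model_path",
    "genotype_inputs",
    "initial_state",
    "priority_scheme",
    "classify_phenotype",
]

COMPONENT_ORDER = (
    "Z1", "Z2", "W", "DMRT1", "HEMGN", "SOX9", "FOXL2", "AROMATASE", "OESTROGEN",
)

#: Input levels induced by each sex-chromosome constitution.
GENOTYPES: Mapping[str, Mapping[str, int]] = {
    "ZZ": {"Z1": 1, "Z2": 1, "W": 0},
    "ZW": {"Z1": 1, "Z2": 0, "W": 1},
    "Z0": {"Z1": 1, "Z2": 0, "W": 0},
    "ZZW": {"Z1": 1, "Z2": 1, "W": 1},
}

PRIORITY_NAMES = ("none", "PC1", "PC2", "PC3", "PC4")

TESTIS = "testis"
OVARY = "ovary"
NEITHER = "undifferentiated_or_other"


def _table(
    regulators: tuple[str, ...],
    max_levels: Mapping[str, int],
    fn: Callable[[Mapping[str, int]], int],
) -> Rule:
    """Tabulate *fn* over every combination of regulator levels."""
    axes = [range(max_levels[r] + 1) for r in regulators]
    table = {
        combo: fn(dict(zip(regulators, combo)))
        for combo in itertools.product(*axes)
    }
    return Rule(regulators=regulators, table=table)


def _dmrt1_target(r: Mapping[str, int]) -> int:
    # First matching clause wins.  SOX9 maintenance outranks FOXL2 repression
    # (SOX9-GOF ZW gonads reach testis without priorities), which in turn
    # outranks the HEMGN boost (HEMGN-GOF ZW gonads need PC1).  With two Z
    # doses and no W factor the basal level is 1; a single effective dose
    # decays to 0.
    n_z = r["Z1"] + r["Z2"]
    if n_z == 0:
        return 0
    if r["SOX9"] == 1:
        return 2
    if r["FOXL2"] == 1:
        return 0
    if r["HEMGN"] == 1:
        return 2
    if n_z == 2 and r["W"] == 0:
        return 1
    return 0


def build_chicken_model() -> LogicalModel:
    """Construct the chicken sex-determination model.

    Deterministic: repeated calls build identical models, and the result
    serializes bit-identically to the bundled ``chicken.model.json``.
    """
    components = (
        ComponentSpec("Z1", 1, is_input=True),
        ComponentSpec("Z2", 1, is_input=True),
        ComponentSpec("W", 1, is_input=True),
        ComponentSpec("DMRT1", 2),
        ComponentSpec("HEMGN", 1),
        ComponentSpec("SOX9", 1),
        ComponentSpec("FOXL2", 1),
        ComponentSpec("AROMATASE", 1),
        ComponentSpec("OESTROGEN", 1),
    )
    edges = (
        RegulationEdge("Z1", "DMRT1", 1, ACTIVATION),
        RegulationEdge("Z2", "DMRT1", 1, ACTIVATION),
        RegulationEdge("W", "DMRT1", 1, INHIBITION),
        RegulationEdge("HEMGN", "DMRT1", 1, ACTIVATION),
        RegulationEdge("SOX9", "DMRT1", 1, ACTIVATION),
        RegulationEdge("FOXL2", "DMRT1", 1, INHIBITION),
        RegulationEdge("DMRT1", "HEMGN", 1, ACTIVATION),
        RegulationEdge("SOX9", "HEMGN", 1, INHIBITION),
        RegulationEdge("DMRT1", "SOX9", 2, ACTIVATION),
        RegulationEdge("SOX9", "SOX9", 1, ACTIVATION),
        RegulationEdge("FOXL2", "SOX9", 1, INHIBITION),
        RegulationEdge("DMRT1", "FOXL2", 2, INHIBITION),
        RegulationEdge("OESTROGEN", "FOXL2", 1, ACTIVATION),
        RegulationEdge("FOXL2", "AROMATASE", 1, ACTIVATION),
        RegulationEdge("AROMATASE", "OESTROGEN", 1, ACTIVATION),
    )
    lv = {c.name: c.max_level for c in components}
    rules = {
        "DMRT1": _table(("Z1", "Z2", "W", "HEMGN", "SOX9", "FOXL2"), lv, _dmrt1_target),
        # HEMGN: activated by any DMRT1 activity, shut off by SOX9.
        "HEMGN": _table(
            ("DMRT1", "SOX9"), lv,
            lambda r: 1 if r["DMRT1"] >= 1 and r["SOX9"] == 0 else 0,
        ),
        # SOX9: needs high DMRT1 to switch on, self-maintains, FOXL2 represses.
        "SOX9": _table(
            ("DMRT1", "SOX9", "FOXL2"), lv,
            lambda r: 1 if r["FOXL2"] == 0 and (r["DMRT1"] == 2 or r["SOX9"] == 1) else 0,
        ),
        # FOXL2: basal activation unless DMRT1 sits at its high level.  The
        # OESTROGEN input is a declared regulator but the reconstructed rule
        # is independent of it: at equilibrium the hormonal feedback is
        # already implied by DMRT1's level.
        "FOXL2": _table(
            ("DMRT1", "OESTROGEN"), lv,
            lambda r: 1 if r["DMRT1"] <= 1 else 0,
        ),
        "AROMATASE": _table(("FOXL2",), lv, lambda r: r["FOXL2"]),
        "OESTROGEN": _table(("AROMATASE",), lv, lambda r: r["AROMATASE"]),
    }
    return LogicalModel(components=components, edges=edges, rules=rules, name="chicken_sex_determination")


def bundled_model_path() -> Path:
    """Path to the shipped ``chicken.model.json`` snapshot; the file is
    regenerated bit-identically by ``build_chicken_model``."""
    return Path(resources.files("zwlogic").joinpath("data/chicken.model.json"))


def genotype_inputs(genotype: str) -> dict[str, int]:
    """Input levels for a chromosomal constitution (ZZ, ZW, Z0 or ZZW)."""
    try:
        return dict(GENOTYPES[genotype])
    except KeyError:
        raise ValueError(
            f"unknown genotype {genotype!r}; expected one of {', '.join(GENOTYPES)}"
        ) from None


def initial_state(
    genotype: str,
    dmrt1_init: int = 1,
    perturbation: Perturbation | None = None,
) -> dict[str, int]:
    """The undifferentiated-gonad initial state.

    Inputs per genotype; DMRT1 at *dmrt1_init* (intermediate level 1 by
    default); every other free component at 0.  Clamped components start at
    their clamp value so the state is compatible with the perturbation.
    """
    if dmrt1_init not in (0, 1, 2):
        raise ValueError(f"dmrt1_init must be 0, 1 or 2, got {dmrt1_init}")
    state = {name: 0 for name in COMPONENT_ORDER}
    state.update(genotype_inputs(genotype))
    state["DMRT1"] = dmrt1_init
    for name, value in (perturbation or {}).items():
        state[name] = value
    return state


def priority_scheme(name: str = "none") -> PriorityScheme:
    """The update settings used in the simulations.

    - ``none``: plain asynchronous update.
    - ``PC1``: DMRT1 & HEMGN increases are faster than FOXL2 increase.
    - ``PC2``: DMRT1 decrease is faster than HEMGN & DMRT1 increases.
    - ``PC3``: DMRT1 decrease is slower than HEMGN & DMRT1 increases, which
      are faster than FOXL2 increase (W-linked effect overcome, on top of
      the PC1 setting).
    - ``PC4``: FOXL2 increase is faster than HEMGN & DMRT1 increases
      (counterpart of PC1, e.g. under overexpressed FOXL2 activators).

    Transitions not named by a setting sit in its fastest class.
    """
    if name == "none":
        return PriorityScheme(name="none")
    if name == "PC1":
        return PriorityScheme({("FOXL2", +1): 2}, default_rank=1, name="PC1")
    if name == "PC2":
        return PriorityScheme({("DMRT1", -1): 1}, default_rank=2, name="PC2")
    if name == "PC3":
        return PriorityScheme({("FOXL2", +1): 2, ("DMRT1", -1): 2}, default_rank=1, name="PC3")
    if name == "PC4":
        return PriorityScheme({("FOXL2", +1): 1}, default_rank=2, name="PC4")
    raise ValueError(f"unknown priority setting {name!r}; expected one of {', '.join(PRIORITY_NAMES)}")


def classify_phenotype(state: State, perturbation: Perturbation | None = None) -> str:
    """Call the gonadal phenotype of a (terminal) state.

    Testis: SOX9 active, DMRT1 at its high level, FOXL2 off.  Ovary: FOXL2,
    AROMATASE and OESTROGEN active with SOX9 off (DMRT1/HEMGN presence is not
    disqualifying: a partial DMRT1 gain of function still yields an ovary).
    Anything else is neither.  Clamped components are evaluated at their
    clamped values.
    """
    s = dict(state)
    s.update(perturbation or {})
    if s["SOX9"] == 1 and s["DMRT1"] == 2 and s["FOXL2"] == 0:
        return TESTIS
    if s["SOX9"] == 0 and s["FOXL2"] == 1 and s["AROMATASE"] == 1 and s["OESTROGEN"] == 1:
        return OVARY
    return NEITHER
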