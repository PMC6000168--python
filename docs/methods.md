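# Methods

## The modelling framework

`zwlogic` implements multilevel logical models in the Thomas formalism. A
model is a directed graph of components; component *i* carries a discrete
level `x_i ∈ [0, m_i]` (`m_i = 1` for Boolean components) and a logical
function `K_i` mapping the levels of its regulators to a target level. Rules
are stored as **explicit truth tables** over regulator-level tuples rather
than expression strings: this makes the invariant "a rule depends only on
declared regulators" mechanically checkable (`validate_model`) and keeps the
on-disk format dialect-free. Each regulatory edge carries a threshold — the
smallest source level at which the interaction is operative — and a sign;
thresholds and signs are structural annotations checked for consistency, the
dynamics itself is driven entirely by the tables.

**Update semantics.** The update is asynchronous with unit steps: in state
`x`, every free, non-input component with `K_i(x) ≠ x_i` yields one enabled
transition moving `x_i` by one unit toward the target, and the target is
re-evaluated in every intermediate state. Unit-step semantics matter for the
ternary DMRT1: a call from 0 to 2 passes through level 1, where races
against FOXL2 activation at the intermediate level become expressible —
these races are precisely what the priority settings resolve.

**Priority classes.** A scheme maps signed transitions `(component, ±1)` to
integer ranks (rank 1 fastest); transitions not named by a scheme default to
its fastest class, since the settings used here name only the races that
need resolving. In each state, only enabled transitions of the minimal
occupied rank may fire. Filtering is therefore edge-subtractive, and fixed
points are scheme-invariant — both properties are asserted in the test
suite.

**Mutations.** Loss/gain of function clamps a component to a fixed level (0
for LOF, a higher level for GOF). A clamp overrides the component's rule
entirely: the clamped component produces no transitions and is evaluated at
its clamp value everywhere, including in phenotype calls.

**Attractors.** An attractor is a terminal strongly connected component of
the (priority-filtered) state-transition graph; a singleton with no enabled
transitions is a stable state, anything larger is cyclic. The engine
computes SCCs via networkx on an exhaustively enumerated graph — state
spaces here are tiny (96 states per chicken genotype; a configurable cap of
10⁶ guards the general engine), so exploration is exact, deterministic
breadth-first enumeration with no sampling or random tie-breaks anywhere.
The chicken analyses only ever produce stable states, but the engine reports
cyclic attractors if a model admits them (the three-gene repression ring in
`synthetic.repressilator` exercises that branch).

## The chicken network

Nine components: inputs `Z1`, `Z2` (one per Z chromosome, each acting as a
DMRT1 activator) and `W` (the W-linked factor repressing DMRT1, abstracting
the MHM-region mechanism); ternary `DMRT1` (0/1/2 — the Z-dosage hypothesis
needs two distinct functional levels); Boolean `HEMGN`, `SOX9`, `FOXL2`,
`AROMATASE`, `OESTROGEN`. Genotypes fix the inputs: ZZ = (1,1,0),
ZW = (1,0,1), Z0 = (1,0,0), ZZW = (1,1,1). With inputs fixed, the free
state space is 3·2⁵ = 96 states.

The logical functions (tabulated in `chicken.py` and shipped as
`data/chicken.model.json`):

- **DMRT1** (first matching clause wins; `nZ = Z1 + Z2`):
  1. `nZ = 0 → 0` — no Z dose, no product;
  2. `SOX9 = 1 → 2` — SOX9 feedback maintains the high level;
  3. `FOXL2 = 1 → 0` — cross-inhibition;
  4. `HEMGN = 1 → 2` — the HEMGN boost;
  5. `nZ = 2 ∧ W = 0 → 1` — two doses, no W factor: stable basal level;
  6. otherwise `→ 0` — a single effective dose decays.
- **HEMGN** = 1 iff `DMRT1 ≥ 1 ∧ SOX9 = 0`.
- **SOX9** = 1 iff `FOXL2 = 0 ∧ (DMRT1 = 2 ∨ SOX9 = 1)`.
- **FOXL2** = 1 iff `DMRT1 ≤ 1`.
- **AROMATASE** = FOXL2; **OESTROGEN** = AROMATASE.

The clause order in DMRT1 is behaviourally forced: SOX9 maintenance must
precede FOXL2 repression (a SOX9-GOF ZW gonad reaches testis without any
priority setting), and FOXL2 repression must precede the HEMGN boost (a
HEMGN-GOF ZW gonad needs PC1). The FOXL2 rule keeps OESTROGEN as a declared
regulator (the edge exists in the network) but is independent of its level:
at equilibrium the hormonal feedback onto FOXL2 is already implied by
DMRT1's level, so the edge is logically redundant in this reconstruction —
a known open point, since only terminal outcomes constrain it.

**Phenotype calls.** Testis: `SOX9 = 1 ∧ DMRT1 = 2 ∧ FOXL2 = 0`. Ovary:
`SOX9 = 0 ∧ FOXL2 = AROMATASE = OESTROGEN = 1`. Everything else is
undifferentiated/other. The operational rules deliberately make DMRT1/HEMGN
expression non-disqualifying for the ovary (a partial DMRT1 GOF with DMRT1
clamped at 1 is still an ovary) and SOX9 activity necessary for the testis
(a SOX9-LOF gonad expressing DMRT1 and HEMGN is neither fate).

**Priority settings.** Two-class schemes: PC1 (`FOXL2+` slow), PC2
(`DMRT1−` fast), PC3 (`FOXL2+` and `DMRT1−` slow — the W-linked effect
overcome, on top of PC1), PC4 (`FOXL2+` fast). For ZW loss-of-function
mutants of the female-promoting genes the campaign uses PC3, which subsumes
the PC1 behaviour while also deferring the W-driven DMRT1 decrease.

**Initial states.** Inputs per genotype, DMRT1 at its intermediate level 1
unless stated otherwise, every other free component at 0; clamped components
start at their clamp value so the initial state is compatible with the
perturbation.

## The simulation campaign

`experiments.mutant_catalog()` is the fixed 21-row campaign: five wild-type
settings (ZZ and ZW with and without their priority settings, ZW with DMRT1
initialized at 0), fourteen LOF/GOF mutants, and the chromosomal variants Z0
and ZZW. Expected outcomes live in a separate checked-in table
(`EXPECTED_OUTCOMES`), keeping the regression surface explicit; the runner
recomputes every phenotype from the attractor vectors and reports mismatches
per row rather than raising mid-run. Bistable outcomes ("both") are recorded
as attractor sets, never as a call on a single state. The whole campaign is
deterministic and re-runs bit-identically.

## Synthetic models and the oracle

`synthetic.random_model` samples the structural class the engine targets:
2–6 components, 0–2 constant inputs, per-component maximal level 1 or 2,
every ordered (source, non-input target) pair an edge candidate with the
configured density (rule-less targets get one forced regulator so every
model validates), and rule tables uniform over admissible target levels.
Generation is a pure function of the config (seed included); there is no
global random state. Random two-class priority schemes place each signed
transition independently in rank 1 or 2, covering the shape of PC1–PC4
without attempting arbitrary rank depth.

`synthetic.oracle_attractors` is a deliberately naive re-implementation for
cross-validation: it re-evaluates targets straight from the rule tables,
materializes the full transition relation as an explicit edge list, and
finds terminal SCCs by repeated reachability closure (per-state BFS). It
shares no code with the dynamics module — in particular it does not use
networkx — so engine/oracle agreement on 100+ seeded models is a meaningful
check of both implementations. A hypothesis-driven twin of the sweep shrinks
any disagreement to a minimal configuration.

What the synthetic generator does *not* emulate: realistic regulatory
topology (no scale-free structure, no sign-consistent rules), so passing the
sweep certifies the *engine semantics*, not biological plausibility of
random networks. Conclusions about the chicken network rest on the encoded
model and its regression suite, not on the sweep.

## Numerical and design choices

- No floating point anywhere: levels, ranks and counts are integers, so
  there are no tolerances to tune and every comparison is exact.
- Attractor lists are sorted by smallest member state tuple; states by the
  fixed component order — all outputs are canonical and diff-stable.
- Serialization is canonical JSON (sorted keys, rows sorted by regulator
  tuple, newline-terminated); `read ∘ write` is the identity and repeated
  writes are bit-identical, which the bundled `chicken.model.json` snapshot
  pins down.
- Degenerate models (a non-input component with no rule) are rejected at
  validation, keeping the update map total.
- Full-graph construction requires explicit input levels rather than
  enumerating input combinations: a genotype is a fixed environment, and
  mixing genotypes in one graph would conflate incomparable dynamics.
- Problem sizes: the campaign explores at most a few dozen states per
  experiment (root-restricted graphs of a 96-state space); the acceptance
  self-check uses 20 random models and the test sweep 100, enough to cover
  the component-count/level/density grid while keeping the whole suite in
  the seconds range.

## Known limitations

- The rule reconstruction is constrained only by reported terminal outcomes;
  rules observationally equivalent on those outcomes (e.g. an
  OESTROGEN-dependent FOXL2 rule) cannot be distinguished here.
- The network is the reduced core: the extended map (WPKCI, FET1, the
  explicit MHM methylation mechanism, left/right gonad asymmetry) and real
  developmental timing in embryonic days are out of scope.
- Priority classes encode qualitative rate orderings only; no kinetic
  parameters are fitted, and synchronous or stochastic (continuous-time)
  update schemes are not provided.
- SBML-qual / GINsim import-export is future work; the canonical JSON format
  is the only on-disk representation.
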