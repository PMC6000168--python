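# zwlogic

Qualitative dynamics of chicken primary sex determination.

In the chicken, sex is set by a ZZ (male) / ZW (female) chromosome system,
but how the bi-potential embryonic gonad commits to testis or ovary is still
debated between two hypotheses: **Z dosage** (two doses of the Z-linked gene
*DMRT1* drive male development) and **dominant W** (a W-linked factor forces
female development). `zwlogic` encodes a multilevel logical model that
integrates both: the gonadal fate emerges from the resolution of the mutual
inhibition between *DMRT1* and *FOXL2*, with *HEMGN* boosting *DMRT1*, *SOX9*
auto-regulation locking the male programme, and the
*FOXL2* → *AROMATASE* → *OESTROGEN* cascade maintaining the female one.

The package has two layers:

- a **generic engine** for multilevel logical models (Thomas formalism):
  components with discrete levels, explicit rule truth tables, asynchronous
  unit-step update, priority classes, state-transition graphs, stable states
  and attractors as terminal strongly connected components;
- the **chicken network** on top of it: nine components (inputs `Z1`, `Z2`,
  `W`; ternary `DMRT1` ∈ {0,1,2}; Boolean `HEMGN`, `SOX9`, `FOXL2`,
  `AROMATASE`, `OESTROGEN`), the four genotypes ZZ/ZW/Z0/ZZW, the priority
  settings PC1–PC4, loss-/gain-of-function clamping, phenotype calls, and the
  full 21-experiment simulation campaign.

## The model in brief

Each component \(i\) has a level \(x_i \in [0, m_i]\) and a logical function
\(K_i(x)\) giving its target level. Asynchronously, any component with
\(K_i(x) \ne x_i\) may move one unit toward its target; concurrent calls
yield alternative trajectories. A *priority class* scheme ranks signed
transitions (e.g. PC1: `DMRT1+`/`HEMGN+` faster than `FOXL2+`) and only the
fastest occupied rank fires. A mutation clamps a variable (loss of function:
0; gain of function: a higher level). Attractors — here the stable states
*testis* (`DMRT1=2, SOX9=1, FOXL2=0`) and *ovary*
(`FOXL2=AROMATASE=OESTROGEN=1, SOX9=0, DMRT1=0`) — correspond to the
differentiated gonads.

## Worked example

Female-to-male sex reversal of a ZW gonad lacking FOXL2 function, under the
PC3 setting (the W-linked repression of DMRT1 is overcome by the HEMGN/DMRT1
upregulation):

```text
$ zwlogic run --genotype ZW --init-dmrt1 1 --clamp FOXL2=0 --priority PC3
explored 5 states
experiment	scheme	Z1	Z2	W	DMRT1	HEMGN	SOX9	FOXL2	AROMATASE	OESTROGEN	phenotype
ZW init=1 clamp[FOXL2=0]	PC3	1	0	1	2	0	1	0	0	0	testis
```

Five states are explored from the undifferentiated initial state and a single
attractor is reached: a stable state with DMRT1 at its high level and SOX9
active — a testis, despite the ZW constitution. The stable states of the
wild-type ZZ space show the two possible fates:

```text
$ zwlogic attractors --genotype ZZ
Z1	Z2	W	DMRT1	HEMGN	SOX9	FOXL2	AROMATASE	OESTROGEN	phenotype
1	1	0	0	0	0	1	1	1	ovary
1	1	0	2	0	1	0	0	0	testis
```

`zwlogic table2` runs the whole campaign (wild types, 14 mutants, Z0 and
ZZW) and checks every row against its expected outcome. The same operations
are available as a library:

```python
from zwlogic import ExperimentSpec, run_experiment

result = run_experiment(ExperimentSpec("demo", "ZW", scheme="PC2"))
print(result.outcome)          # "ovary"
print(result.attractors[0])    # the stable state vector
```

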