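# Methods

## Scope and design

fluxkit implements the computational machinery of database-derived
flux-balance modeling at desk scale: the model description layer, network
construction, the two-stage LP engine, and the two benchmark screens
(gene essentiality, nutrient utilization). It deliberately does not ship
a genome-scale reconstruction; instead, a set of small, fully balanced
fixture networks exercises every code path and reproduces the published
desk-scale checkpoints exactly. Everything stochastic is a pure function
of an explicit seed.

## Model description layer

Metabolites carry an element-map formula and integer charge, either of
which may be absent ("structure-unknown"); a reaction containing such a
species has an *undetermined* balance state. Stoichiometric coefficients
are exact rationals (`fractions.Fraction`); floating point enters only at
LP assembly. Mass balance is checked element-wise with protons counted
like any element, and charge is checked alongside: a charge-only
imbalance is *unbalanced*. Whether charge participates is a configuration
switch (`include_charge`), since proton bookkeeping is exactly what the
respiratory-chain benchmark turns on.

Gene–product associations are sets of catalyst units (a unit = the gene
set of one enzyme; multiple units = isozymes) plus per-substrate supplier
genes. A knockout set K disables a reaction iff every catalyst unit
intersects K, or some substrate's declared suppliers are all in K. A
supplier is replaceable only by another *declared* supplier of the same
substrate; suppliers are never inferred from pathway context. Empty
catalysts mean spontaneous/orphan and are never gene-disabled.

## Network construction

Class-containing reactions are instantiated first: the Cartesian product
runs over the distinct classes (the same class on both sides binds to the
same instance), keeping only bindings whose instance reaction is mass-
and charge-balanced. A reaction whose permutation count exceeds the cap
(default 10,000) is rejected under `permutation-cap`; a class slot with
no instances, or no balanced binding at all, is `ambiguous-instantiation`.

The per-reaction filters then run in a fixed order — one-sidedness,
balance, physiological relevance, type flags, string-only substrates,
variable stoichiometry — and the disconnected filter runs last, iterated
to a fixed point because one removal can strand others. Two documented
choices here: (1) instantiation precedes filtering, and (2) one-sidedness
takes categorization precedence over the balance check, because a
one-sided reaction is unbalanced by construction and the log should name
the actual cause. The exclusion log partitions the source reactions:
every reaction appears exactly once as retained or excluded.

Exchanges are attached per declared nutrient (uptake bounded above by the
nutrient coefficient; unconstrained means a large default bound of
3000 mmol/gCDW/hr, configurable — far above the largest desk-scale flux
of 216 but harmless to LP conditioning) and per secretion (unbounded
efflux). Nutrients declared in the cytosol (ammonium, mirroring passive
diffusion at experimental concentrations) exchange directly into the
cytosol; everything else sits in the periplasm.

## Two-stage solver

Stage 1 maximizes the objective flux with HiGHS (through
`scipy.optimize.linprog`), which is deterministic at fixed input; rows
and columns are assembled in lexicographic order so flux vectors are
reproducible across runs. Stage 2 splits each flux into positive and
negative parts and minimizes their sum with the objective *fixed by an
equality row at its stage-1 optimum*; if that equality is numerically
infeasible the stage falls back to an inequality with relative slack
1e-8 (and, failing that, reports the stage-1 vertex). The equality-first
policy is what makes the benchmark fluxes land exactly on the printed
integers rather than within 1e-6 of them.

The growth call is `objective > ε` with ε = 1e-6 (configurable),
operationalizing "any growth at all"; ε must exceed the solver tolerance.
Infeasible and unbounded statuses propagate — they are never silently
coerced to no-growth, because an unbounded maximization indicates a
thermodynamically broken cycle touching the objective, which is a model
bug, not a phenotype. Screens solve stage 1 only: the growth call depends
only on the optimum, and skipping the taxicab stage roughly halves screen
time.

## Maintenance energy

GAM (53.95 mmol ATP/gCDW) enters the biomass reaction as an ATP + H2O →
ADP + Pi + H+ term scaled by growth; NGAM (3.15 mmol ATP/gCDW/hr) is a
lower flux bound on the ATP hydrolysis reaction. Both default to the
standard *E. coli* values and are fields of the biomass objective.

## The core energy benchmark and its proton coefficients

The aerobic benchmark network contains exactly the published reaction
set: glucose PTS uptake, glycolysis through the
fructose-6-phosphate-aldolase/dihydroxyacetone-PTS branch (there is no
pyruvate kinase; the two PTS steps consume all PEP), pyruvate
dehydrogenase, the complete TCA cycle, transhydrogenase, NADH
dehydrogenase and succinate dehydrogenase feeding a cytochrome *bo*
oxidase, ATP synthase, and ATP hydrolysis as the objective, plus
diffusion steps and exchanges for glucose, O2, CO2, water and protons.
Every reaction is mass- and charge-balanced with explicit
periplasmic/cytosolic proton accounting; the whole fixture passes the
filter cascade with zero exclusions.

The two electron-transport conventions fix the NADH-dehydrogenase
translocation (4 or 3 H+ per 2 e-) and the oxidase bookkeeping (whole vs
half O2), but two coefficients remain open: the H+ appearing in the
periplasm per O2 at the oxidase, and the periplasmic H+ consumed per ATP
at the synthase. These are *derived*, not chosen: at steady state the
periplasmic proton balance of the published benchmark fluxes reads
`synthase_flux × n = nadh_flux × h + o2_turnover × b` per convention,
with `b` shared across conventions (same enzyme chemistry). Requiring
integral solutions leaves exactly one minimal answer — b = 8 H+/O2
(4 pumped + 4 scalar), n = 5 under the 4 H+/2e- convention and n = 4
under the 3 H+/2e- convention — and `derive_proton_stoichiometry`
performs this search at import of the fixture builders. The cytosolic
proton balance then *forces* the benchmark optima (216 and 235
mmol ATP/gCDW/hr at glucose 10); the test suite verifies both the
derivation and the resulting flux table.

## Fermentation network and the miniature biomass

The fermentation fixture extends the core network with pyruvate-formate
lyase, the acetate (phosphotransacetylase/acetate kinase) and ethanol
(acetaldehyde/alcohol dehydrogenase) branches, lactate dehydrogenase, the
PEP-carboxylase/fumarate-reductase succinate branch, formate-hydrogen
lyase (bounds zero by default), glutamate synthesis from cytosolic
ammonium, phosphate/fructose/pyruvate transport, and proton-coupled acid
efflux. Two structural points matter:

* **Acids leave with their protons.** Efflux of acetate, formate,
  lactate and succinate is proton-symported; this is what makes acid
  secretion a net cytosolic proton sink, without which the LP cannot
  reach the acetate branch anaerobically and the 1:2:1
  acetate:formate:ethanol optimum would not exist.
* **Growth needs phosphofructokinase.** The aldolase/DHA-PTS glycolysis
  of the benchmark network is exactly PEP-neutral (two PEP consumed per
  glucose, two produced), so net precursor export is impossible through
  it; the fermentation network adds the PFK/FBP-aldolase route (with the
  pfkA/pfkB isozyme pair) to make biomass production feasible. The
  same structure makes the triose-phosphate-isomerase knockout
  essential — aldolase-produced DHAP is stranded without it — mirroring
  the real organism.

The biomass objective is a miniature 13-member set of central-carbon
precursors (hexose/triose phosphates, PEP, pyruvate, TCA intermediates,
glutamate) at magnitudes typical of measured precursor demands.
Cofactor-moiety species (CoA esters, NAD pools) are excluded because
their moieties cannot be synthesized at this network scale and a drain
would simply empty a conserved pool. The anaerobic modification switch
zeroes the O2 uptake bound, enables formate-hydrogen lyase, and drops
the two oxygen-dependent biomass demands (protoheme, pyridoxal
5'-phosphate) when present — exactly three changes, asserted by
structural diff in the tests.

## Synthetic experimental datasets

The essentiality generator draws a bimodal OD600 table: a non-growing
mode concentrated below the narrow threshold (0.005), a growing mode
around 0.35, and a "severe growth defect" tail between the narrow and
broad thresholds on which the two criteria disagree by construction.
Defaults (18% non-growing, 5% defect) sit at the proportions of the
full-scale screen. With noise scales at zero, classification recovers
the generated truth exactly — the noiseless-recovery oracle used in the
acceptance checks. The PM generator draws per-well ground truth
(58.5% positive, the full screen's consensus-positive fraction) and, with
a configurable probability (default 70/383), flips one dataset to the
opposite class, which under the unanimity policy yields a no-consensus
well.

Consensus is unanimity after binarization — the only reading consistent
with "conflict-free" — with a majority policy exposed as an alternative.
Boundary OD values equal to a threshold classify as essential (the
criteria are "≤"). Genes lacking the 48-hour measurement under narrow
criteria are refused rather than guessed. Percentages print half-up to
one decimal, computed on exact fractions.

## What the fixtures do and do not show

The fixtures reproduce exactly those published quantities that are
properties of the *method* rather than of the full database: the
ATP-yield flux table (all of it), the confusion-matrix arithmetic of the
screens, the 1:2:1 fermentation optimum and the order in which oxygen
retires the fermentation products. Quantities that depend on the
genome-scale reconstruction — chemostat growth rates such as μ = 0.272,
the 1445-gene screen itself, model size counts — are out of desk-scale
reach and are covered instead by property checks: LP homogeneity of the
chemostat protocol, knockout-growth monotonicity over the full fixture
gene set, noiseless recovery on the synthetic datasets, steady-state
residuals ≤ 1e-6 on every optimum, filter-cascade idempotence, and
agreement of class instantiation with exhaustive enumeration. On the
oxygen sweep, acetate's extinction lies at O2 = 60 for glucose 10 —
beyond the published 0–20 window — so the sweep checks assert the
elimination *ordering* with acetate still positive at the window's edge.

A passing suite therefore shows the machinery is correct, not that any
particular genome-scale reconstruction is accurate; the fixture networks
are stand-ins for a curated database, synthetic by design, and say
nothing about organism biology beyond the central-carbon stoichiometry
they encode.

## Numerical choices

* LP tolerances: solver defaults (HiGHS); reported fluxes below 1e-9 are
  zeroed for readability.
* Stage-2 objective fixing: equality first, relative-slack (1e-8)
  fallback, stage-1 vertex as last resort.
* Growth threshold ε = 1e-6, strictly above solver tolerance (enforced).
* Degenerate inputs: empty retained sets, empty media, and zero-uptake
  chemostats are valid and produce zero-growth or empty outputs rather
  than errors; infeasible NGAM floors report `infeasible`.
* Problem sizes: the benchmark LPs have ~34 reactions, the fermentation
  screens ~80; the complete suite (163 tests, every LP included) runs in
  a few seconds on one CPU.
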