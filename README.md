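# fluxkit

Constraint-based metabolic modeling the way database-derived genome-scale
models are built: **fluxkit** turns a curated, database-style description of
metabolism (metabolites with formulas and charges, reactions with exact
stoichiometry, gene–product associations) into a solvable flux-balance
model, solves it with a two-stage linear program, and benchmarks its
predictions against knockout-essentiality and nutrient-utilization screens.

It is written for systems biologists who work with *E. coli*-style
central-carbon models and want the full pipeline — network construction
with an auditable filter cascade, parsimonious FBA, gene-knockout screens
with OD600-based experimental criteria, and phenotype-microarray growth
prediction — at desk scale, with every step testable against bundled,
fully mass- and charge-balanced fixture networks.

## The model

Flux balance analysis poses metabolism as a linear program over the
stoichiometric matrix **S** (metabolites × reactions):

```
maximize    v_obj
subject to  S v = 0,   lb ≤ v ≤ ub
```

Fluxes `v` are in mmol/gCDW/hr. A biomass pseudo-reaction drains precursor
metabolites at measured coefficients (mmol/gCDW) plus a growth-associated
maintenance ATP hydrolysis (GAM, default 53.95 mmol ATP/gCDW); a fixed
flux floor on the ATP hydrolysis reaction encodes non-growth-associated
maintenance (NGAM, default 3.15 mmol ATP/gCDW/hr). A biomass flux of 1.0
is a specific growth rate μ of 1.0 hr⁻¹.

After the optimum `z*` is found, a second stage fixes `v_obj = z*` and
minimizes the taxicab norm `Σ|v|` (parsimonious FBA), which removes
alternate-optima degeneracy and thermodynamically absurd loops from the
reported flux vector. Because of this stage, the stoichiometric *scaling*
of equations matters, so model reactions are normalized to minimum
whole-integer stoichiometry.

Network construction mirrors run-time model generation from a curated
database: reactions containing compound classes are instantiated into all
mass-balanced concrete versions (with a permutation cap, default 10,000),
and a filter cascade removes reactions that are unbalanced or
balance-undetermined, physiologically irrelevant, polymerization-,
polymer-segment- or protein-modification-flagged, one-sided, described
only by strings, of variable stoichiometry, or disconnected — each
removal logged with its category.

A gene knockout disables every reaction whose catalyst units all lose a
member (complexes need every subunit; isozymes are alternative units) and
re-solves: any growth at all is nonessential. Experimental calls use
either the *narrow* criteria (OD600 ≤ 0.005 at 24 **and** 48 hr) or the
*broad* criteria (OD600 ≤ 0.091 at 24 hr). Phenotype-microarray wells swap
one elemental source (C/N/P/S) of a minimal medium for a test nutrient;
respiration scores from several datasets are binarized (normal/low →
positive) and consensus-reduced before comparison with the growth call.

## A worked example

The bundled core energy network (glucose PTS uptake, glycolysis through
the fructose-6-phosphate-aldolase branch, TCA cycle, electron transport
chain) reproduces the classic aerobic ATP-yield benchmark. From
`examples/atp_yield_benchmark.py`:

```
--- core-energy-ecocyc (4 H+/2e-, whole-O2 oxidase)
max ATP turnover: 216.0 mmol/gCDW/hr
  NADH-DEHYDROG-A-RXN            100.0
  ATP-SYNTHASE-RXN               176.0
  CYTOCHROME-BO-OXIDASE-RXN       60.0
  EX-OXYGEN[p]                    60.0
  SEC-CO2[p]                      60.0
--- core-energy-ijo (3 H+/2e-, half-O2 oxidase)
max ATP turnover: 235.0 mmol/gCDW/hr
```

At a glucose uptake of 10 mmol/gCDW/hr the network yields 21.6 ATP per
glucose under the 4 H⁺/2e⁻ NADH-dehydrogenase convention and 23.5 under
the 3 H⁺/2e⁻ convention — the entire difference traces to proton
bookkeeping in the respiratory chain. Anaerobically
(`examples/mixed_acid_fermentation.py`) the same model secretes acetate,
formate and ethanol in the stoichiometrically optimal 1:2:1 ratio, and an
oxygen sweep from 0 to 20 mmol/gCDW/hr retires ethanol first (by O2=10),
then formate (by O2=20), with acetate persisting — the classic mixed-acid
transition.

The other examples run a complete single-gene knockout screen
(`examples/knockout_screen.py`: 62 genes, 15 predicted essential on
glucose, including the expected cut vertices `eno`, `pgk`, `icd` and the
pfkA/pfkB double-knockout synthetic lethality) and a
phenotype-microarray screen (`examples/nutrient_screen.py`).

A thin CLI wraps the same capabilities:

```sh
fluxkit fixtures --name core-energy-ecocyc --out core
fluxkit fba --config core/run.fba            # prints objective (ATPM): 216
fluxkit report --confusion 1175 58 12 200    # accuracy 95.2% ...
```

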