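"""Deterministic fixture networks and synthetic experimental datasets.

The fixtures make every layer of the toolkit testable at desk scale
without any database download:

* a core aerobic energy network (glucose PTS uptake, glycolysis with the
  fructose-6-phosphate aldolase / dihydroxyacetone-PTS branch, pyruvate
  dehydrogenase, the full TCA cycle, transhydrogenase, NADH dehydrogenase
  and succinate dehydrogenase feeding a cytochrome *bo* oxidase, ATP
  synthase, and an ATP-hydrolysis objective), constructible under two
  electron-transport conventions: 4 H+ translocated per 2 e- at NADH
  dehydrogenase with a whole-O2 oxidase, or 3 H+ per 2 e- with a half-O2
  oxidase;
* a fermentation extension (pyruvate-formate lyase, acetate and ethanol
  branches, lactate, the PEP-carboxylase/fumarate-reductase succinate
  branch, formate-hydrogen lyase disabled by default) plus a miniature
  biomass objective;
* toy networks (a two-route diamond for taxicab tie-breaking, a
  blocked-biomass network for the reachability scan);
* synthetic gene-essentiality OD600 tables with a bimodal structure and a
  "severe growth defect" tail on which narrow and broad criteria disagree;
* synthetic phenotype-microarray score tables with a controlled
  cross-dataset disagreement rate.

Every reaction in the generated networks is mass- and charge-balanced,
including explicit periplasmic/cytosolic proton accounting, so the
networks pass the construction filter cascade with zero exclusions.

The two proton-translocation coefficients that the electron-transport
conventions do not pin down (oxidase H+ appearing in the periplasm per
whole O2, and ATP synthase periplasmic H+ consumed per ATP) are *derived*,
not invented: :func:`derive_proton_stoichiometry` solves the periplasmic
proton steady-state balance of the published benchmark flux vectors and
returns the unique integral solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .build import FluxNetwork, build_network
from .core import (
    IRREVERSIBLE_FORWARD,
    REVERSIBLE,
    GeneProductAssociation,
    Metabolite,
    MetaboliteSet,
    ModelDefinition,
    Reaction,
    SetMember,
    parse_formula,
)
from .engine import BiomassObjective

__all__ = [
    "FixtureSpec",
    "ECOCYC_CONVENTION",
    "IJO_CONVENTION",
    "TABLE2_BENCHMARK",
    "ProtonStoichiometry",
    "derive_proton_stoichiometry",
    "build_core_energy_network",
    "core_energy_nutrients",
    "core_energy_secretions",
    "core_energy_problem",
    "build_fermentation_network",
    "fermentation_nutrients",
    "fermentation_secretions",
    "fermentation_biomass",
    "fermentation_problem",
    "build_diamond_toy",
    "build_blocked_biomass_toy",
    "SyntheticEssentialityConfig",
    "generate_essentiality_table",
    "generate_pm_dataset",
]


# ---------------------------------------------------------------------------
# conventions and the proton-coefficient derivation

# Published ATP-maximization benchmark fluxes (mmol/gCDW/hr) at glucose
# uptake 10 for the two stoichiometric conventions.  These are inputs to
# the coefficient derivation; the oxidase flux is expressed in whole-O2
# turnover units (the half-O2 convention writes the same turnover as a
# reaction flux of 120).
TABLE2_BENCHMARK = {
    "ecocyc": {
        "objective": 216.0,
        "atp_synthase": 176.0,
        "nadh_dehydrogenase": 100.0,
        "oxidase_o2_turnover": 60.0,
        "nadh_h_per_2e": 4,
    },
    "ijo": {
        "objective": 235.0,
        "atp_synthase": 195.0,
        "nadh_dehydrogenase": 100.0,
        "oxidase_o2_turnover": 60.0,
        "nadh_h_per_2e": 3,
    },
}


@dataclass(frozen=True)
class ProtonStoichiometry:
    """Derived electron-transport proton coefficients.

    ``oxidase_h_per_o2``: H+ appearing in the periplasm per whole O2
    reduced at the terminal oxidase (pumped plus scalar chemistry).
    ``synthase_h_per_atp``: periplasmic H+ consumed per ATP synthesized,
    keyed by convention.
    """

    oxidase_h_per_o2: int
    synthase_h_per_atp: dict[str, int]


def derive_proton_stoichiometry(
    benchmark: dict | None = None, max_coefficient: int = 20
) -> ProtonStoichiometry:
    """Solve the periplasmic proton balance for the unknown coefficients.

    At steady state the periplasmic proton production of NADH
    dehydrogenase and the oxidase must equal ATP synthase consumption:
    ``synthase_flux * n = nadh_flux * h + o2_turnover * b`` for each
    convention, with the oxidase coefficient ``b`` shared (same enzyme
    chemistry, different bookkeeping).  Requiring integral ``b`` and per-
    convention integral ``n`` leaves a unique minimal solution, which is
    returned; anything else raises.
    """
    bench = benchmark or TABLE2_BENCHMARK
    conventions = sorted(bench)
    solutions = []
    for b in range(1, max_coefficient + 1):
        ns = {}
        for conv in conventions:
            row = bench[conv]
            pumped = row["nadh_dehydrogenase"] * row["nadh_h_per_2e"] + row[
                "oxidase_o2_turnover"
            ] * b
            n = pumped / row["atp_synthase"]
            if abs(n - round(n)) > 1e-9 or round(n) < 1:
                break
            ns[conv] = int(round(n))
        else:
            solutions.append(ProtonStoichiometry(b, ns))
    if not solutions:
        raise ValueError("no integral proton stoichiometry satisfies the benchmark fluxes")
    return solutions[0]


@dataclass(frozen=True)
class FixtureSpec:
    """Convention parameters for the core energy network."""

    name: str = "core-energy-ecocyc"
    nadh_h_per_2e: int = 4
    oxidase_o2: str = "whole"  # whole | half
    synthase_h_per_atp: int | None = None  # derived when None

    def __post_init__(self) -> None:
        if self.oxidase_o2 not in ("whole", "half"):
            raise ValueError("oxidase_o2 must be 'whole' or 'half'")
        if self.nadh_h_per_2e < 1:
            raise ValueError("NADH dehydrogenase must translocate at least 1 H+/2e-")

    @property
    def convention(self) -> str:
        return "ecocyc" if self.nadh_h_per_2e == 4 else "ijo"

    def resolved_synthase_coefficient(self) -> int:
        if self.synthase_h_per_atp is not None:
            return self.synthase_h_per_atp
        derived = derive_proton_stoichiometry()
        return derived.synthase_h_per_atp[self.convention]


ECOCYC_CONVENTION = FixtureSpec("core-energy-ecocyc", nadh_h_per_2e=4, oxidase_o2="whole")
IJO_CONVENTION = FixtureSpec("core-energy-ijo", nadh_h_per_2e=3, oxidase_o2="half")


# ---------------------------------------------------------------------------
# metabolite catalog (formulas at physiological protonation, iJO-style)

_FORMULAS: dict[str, tuple[str, int]] = {
    "GLC": ("C6H12O6", 0),
    "FRU": ("C6H12O6", 0),
    "XYLOSE": ("C5H10O5", 0),
    "G6P": ("C6H11O9P", -2),
    "F6P": ("C6H11O9P", -2),
    "DHA": ("C3H6O3", 0),
    "DHAP": ("C3H5O6P", -2),
    "FBP": ("C6H10O12P2", -4),
    "GAP": ("C3H5O6P", -2),
    "DPG": ("C3H4O10P2", -4),
    "PG3": ("C3H4O7P", -3),
    "PG2": ("C3H4O7P", -3),
    "PEP": ("C3H2O6P", -3),
    "PYR": ("C3H3O3", -1),
    "ACCOA": ("C23H34N7O17P3S", -4),
    "COA": ("C21H32N7O16P3S", -4),
    "CIT": ("C6H5O7", -3),
    "ICIT": ("C6H5O7", -3),
    "AKG": ("C5H4O5", -2),
    "SUCCOA": ("C25H35N7O19P3S", -5),
    "SUC": ("C4H4O4", -2),
    "FUM": ("C4H2O4", -2),
    "MAL": ("C4H4O5", -2),
    "OAA": ("C4H2O5", -2),
    "GLU": ("C5H8NO4", -1),
    "NH4": ("H4N", 1),
    "NAD": ("C21H26N7O14P2", -1),
    "NADH": ("C21H27N7O14P2", -2),
    "NADP": ("C21H25N7O17P3", -3),
    "NADPH": ("C21H26N7O17P3", -4),
    "UQ8": ("C49H74O4", 0),
    "UQ8H2": ("C49H76O4", 0),
    "ATP": ("C10H12N5O13P3", -4),
    "ADP": ("C10H12N5O10P2", -3),
    "Pi": ("HO4P", -2),
    "WATER": ("H2O", 0),
    "PROTON": ("H", 1),
    "CO2": ("CO2", 0),
    "OXYGEN": ("O2", 0),
    "ACET": ("C2H3O2", -1),
    "ACTP": ("C2H3O5P", -2),
    "ACALD": ("C2H4O", 0),
    "ETOH": ("C2H6O", 0),
    "FOR": ("CHO2", -1),
    "LAC": ("C3H5O3", -1),
    "H2": ("H2", 0),
    "FE+2": ("Fe", 2),
    "SULFATE": ("O4S", -2),
    "PROTOHEME": ("C34H30FeN4O4", -2),
    "PYRIDOXAL-5P": ("C8H8NO6P", -2),
}


def _met(model: ModelDefinition, base: str, compartment: str) -> str:
    key = f"{base}[{compartment}]"
    if key not in model.metabolites:
        formula, charge = _FORMULAS[base]
        model.add_metabolite(
            Metabolite(base, name=base, formula=parse_formula(formula), charge=charge,
                       compartment=compartment)
        )
    return key


def _rxn(
    model: ModelDefinition,
    rid: str,
    stoich: dict[str, int | Fraction],
    direction: str = IRREVERSIBLE_FORWARD,
    genes: Sequence[Sequence[str]] | None = None,
    spontaneous: bool = False,
) -> None:
    reaction = Reaction(
        rid,
        {k: Fraction(v) for k, v in stoich.items()},
        direction=direction,
        spontaneous=spontaneous or not genes,
    )
    assoc = None
    if genes:
        assoc = GeneProductAssociation(
            rid, catalysts=frozenset(frozenset(unit) for unit in genes)
        )
    model.add_reaction(reaction, assoc)


# ---------------------------------------------------------------------------
# core energy network


def build_core_energy_network(spec: FixtureSpec = ECOCYC_CONVENTION) -> ModelDefinition:
    """Aerobic glucose -> ATP benchmark network under a convention.

    The reaction set is the published ATP-maximization benchmark: PTS
    uptake, glycolysis via the F6P-aldolase/DHA-PTS branch (no pyruvate
    kinase: all PEP is consumed by the two PTS steps), pyruvate
    dehydrogenase, the full TCA cycle, transhydrogenase, and the electron
    transport chain with convention-dependent proton bookkeeping.
    """
    m = ModelDefinition()
    c = lambda b: _met(m, b, "c")  # noqa: E731
    p = lambda b: _met(m, b, "p")  # noqa: E731

    h = spec.nadh_h_per_2e
    n_syn = spec.resolved_synthase_coefficient()
    b_ox = derive_proton_stoichiometry().oxidase_h_per_o2

    # transport / diffusion
    _rxn(m, "GLC-PTS-RXN",
         {p("GLC"): -1, c("PEP"): -1, c("G6P"): 1, c("PYR"): 1},
         genes=[["ptsG", "ptsH", "ptsI", "crr"]])
    _rxn(m, "O2-DIFFUSION-RXN", {p("OXYGEN"): -1, c("OXYGEN"): 1}, REVERSIBLE)
    _rxn(m, "CO2-DIFFUSION-RXN", {c("CO2"): -1, p("CO2"): 1}, REVERSIBLE)
    _rxn(m, "H2O-DIFFUSION-RXN", {c("WATER"): -1, p("WATER"): 1}, REVERSIBLE)

    # glycolysis, F6P-aldolase branch
    _rxn(m, "PGLUCISOM-RXN", {c("G6P"): -1, c("F6P"): 1}, REVERSIBLE, [["pgi"]])
    _rxn(m, "RXN0-313", {c("F6P"): -1, c("DHA"): 1, c("GAP"): 1},
         genes=[["fsaA"]])
    _rxn(m, "2.7.1.121-RXN",
         {c("DHA"): -1, c("PEP"): -1, c("DHAP"): 1, c("PYR"): 1},
         genes=[["dhaK", "dhaL", "dhaM"]])
    _rxn(m, "TRIOSEPISOMERIZATION-RXN", {c("DHAP"): -1, c("GAP"): 1}, REVERSIBLE,
         [["tpiA"]])
    _rxn(m, "GAPOXNPHOSPHN-RXN",
         {c("GAP"): -1, c("NAD"): -1, c("Pi"): -1,
          c("DPG"): 1, c("NADH"): 1, c("PROTON"): 1},
         REVERSIBLE, [["gapA"], ["gapB"]])
    _rxn(m, "PHOSGLYPHOS-RXN",
         {c("DPG"): -1, c("ADP"): -1, c("PG3"): 1, c("ATP"): 1},
         REVERSIBLE, [["pgk"]])
    _rxn(m, "3PGAREARR-RXN", {c("PG3"): -1, c("PG2"): 1}, REVERSIBLE, [["gpmA"]])
    _rxn(m, "2PGADEHYDRAT-RXN", {c("PG2"): -1, c("PEP"): 1, c("WATER"): 1},
         REVERSIBLE, [["eno"]])
    _rxn(m, "PYRUVDEH-RXN",
         {c("PYR"): -1, c("COA"): -1, c("NAD"): -1,
          c("ACCOA"): 1, c("CO2"): 1, c("NADH"): 1},
         genes=[["aceE", "aceF", "lpd"]])

    # TCA cycle
    _rxn(m, "CITSYN-RXN",
         {c("OAA"): -1, c("ACCOA"): -1, c("WATER"): -1,
          c("CIT"): 1, c("COA"): 1, c("PROTON"): 1},
         genes=[["gltA"]])
    _rxn(m, "ACONITATEDEHYDR-RXN", {c("CIT"): -1, c("ICIT"): 1}, REVERSIBLE,
         [["acnA"], ["acnB"]])
    _rxn(m, "ISOCITDEH-RXN",
         {c("ICIT"): -1, c("NADP"): -1, c("AKG"): 1, c("CO2"): 1, c("NADPH"): 1},
         REVERSIBLE, [["icd"]])
    _rxn(m, "2OXOGLUTARATEDEH-RXN",
         {c("AKG"): -1, c("COA"): -1, c("NAD"): -1,
          c("SUCCOA"): 1, c("CO2"): 1, c("NADH"): 1},
         genes=[["sucA", "sucB", "lpd"]])
    _rxn(m, "SUCCOASYN-RXN",
         {c("SUCCOA"): -1, c("ADP"): -1, c("Pi"): -1,
          c("SUC"): 1, c("COA"): 1, c("ATP"): 1},
         REVERSIBLE, [["sucC", "sucD"]])
    _rxn(m, "SUCC-DEHYDROGENASE-RXN",
         {c("SUC"): -1, c("UQ8"): -1, c("FUM"): 1, c("UQ8H2"): 1},
         genes=[["sdhA", "sdhB", "sdhC", "sdhD"]])
    _rxn(m, "FUMHYDR-RXN", {c("FUM"): -1, c("WATER"): -1, c("MAL"): 1},
         REVERSIBLE, [["fumA"], ["fumB"], ["fumC"]])
    _rxn(m, "MALATE-DEH-RXN",
         {c("MAL"): -1, c("NAD"): -1, c("OAA"): 1, c("NADH"): 1, c("PROTON"): 1},
         REVERSIBLE, [["mdh"]])
    _rxn(m, "PYRNUTRANSHYDROGEN-RXN",
         {c("NADPH"): -1, c("NAD"): -1, c("NADP"): 1, c("NADH"): 1},
         genes=[["sthA"]])

    # electron transport chain and phosphorylation
    _rxn(m, "NADH-DEHYDROG-A-RXN",
         {c("NADH"): -1, c("UQ8"): -1, c("PROTON"): -(h + 1),
          c("NAD"): 1, c("UQ8H2"): 1, p("PROTON"): h},
         genes=[["nuoA", "nuoB"]])
    if spec.oxidase_o2 == "whole":
        oxidase = {c("UQ8H2"): -2, c("OXYGEN"): -1, c("PROTON"): -b_ox,
                   c("UQ8"): 2, c("WATER"): 2, p("PROTON"): b_ox}
    else:
        oxidase = {c("UQ8H2"): -1, c("OXYGEN"): Fraction(-1, 2),
                   c("PROTON"): -Fraction(b_ox, 2),
                   c("UQ8"): 1, c("WATER"): 1, p("PROTON"): Fraction(b_ox, 2)}
    _rxn(m, "CYTOCHROME-BO-OXIDASE-RXN", oxidase, genes=[["cyoA", "cyoB"]])
    _rxn(m, "ATP-SYNTHASE-RXN",
         {c("ADP"): -1, c("Pi"): -1, p("PROTON"): -n_syn,
          c("ATP"): 1, c("WATER"): 1, c("PROTON"): n_syn - 1},
         genes=[["atpA", "atpB", "atpC"]])
    _rxn(m, "ATPM",
         {c("ATP"): -1, c("WATER"): -1, c("ADP"): 1, c("Pi"): 1, c("PROTON"): 1},
         spontaneous=True)
    return m


def core_energy_nutrients(glucose_bound: float = 10.0) -> MetaboliteSet:
    return MetaboliteSet(
        "core-nutrients",
        (
            SetMember("GLC[p]", coefficient=glucose_bound, role="C"),
            SetMember("OXYGEN[p]"),
            SetMember("WATER[p]"),
            SetMember("CO2[p]"),
            SetMember("PROTON[p]"),
        ),
    )


def core_energy_secretions() -> MetaboliteSet:
    return MetaboliteSet(
        "core-secretions",
        (
            SetMember("WATER[p]"),
            SetMember("CO2[p]"),
            SetMember("PROTON[p]"),
        ),
    )


def core_energy_problem(
    spec: FixtureSpec = ECOCYC_CONVENTION, glucose_bound: float = 10.0
) -> FluxNetwork:
    """Ready-to-solve ATP-maximization problem for a convention."""
    model = build_core_energy_network(spec)
    net = build_network(model, core_energy_nutrients(glucose_bound), core_energy_secretions())
    net.objective_id = "ATPM"
    return net


# ---------------------------------------------------------------------------
# fermentation network


def build_fermentation_network(spec: FixtureSpec = ECOCYC_CONVENTION) -> ModelDefinition:
    """Core energy network extended with mixed-acid fermentation branches.

    Adds pyruvate-formate lyase, the acetate (phosphotransacetylase +
    acetate kinase) and ethanol (acetaldehyde/alcohol dehydrogenase)
    branches, lactate dehydrogenase, the PEP-carboxylase/fumarate-
    reductase succinate branch, formate-hydrogen lyase (disabled by
    default via its run bounds), glutamate synthesis from ammonium, and
    transporters for phosphate, fructose and pyruvate.
    """
    m = build_core_energy_network(spec)
    c = lambda b: _met(m, b, "c")  # noqa: E731
    p = lambda b: _met(m, b, "p")  # noqa: E731

    # ATP-driven lower glycolysis: the F6P-aldolase/DHA-PTS branch of the
    # core network is exactly PEP-neutral, so net precursor export (growth)
    # requires the phosphofructokinase route
    _rxn(m, "6PFRUCTPHOS-RXN",
         {c("F6P"): -1, c("ATP"): -1, c("FBP"): 1, c("ADP"): 1, c("PROTON"): 1},
         genes=[["pfkA"], ["pfkB"]])
    _rxn(m, "F16ALDOLASE-RXN",
         {c("FBP"): -1, c("DHAP"): 1, c("GAP"): 1},
         REVERSIBLE, [["fbaA"], ["fbaB"]])
    _rxn(m, "PYRUVFORMLY-RXN",
         {c("PYR"): -1, c("COA"): -1, c("ACCOA"): 1, c("FOR"): 1},
         genes=[["pflB"]])
    _rxn(m, "PHOSACETYLTRANS-RXN",
         {c("ACCOA"): -1, c("Pi"): -1, c("ACTP"): 1, c("COA"): 1},
         REVERSIBLE, [["pta"]])
    _rxn(m, "ACETATEKIN-RXN",
         {c("ACTP"): -1, c("ADP"): -1, c("ACET"): 1, c("ATP"): 1},
         REVERSIBLE, [["ackA"]])
    _rxn(m, "ACETALD-DEHYDROG-RXN",
         {c("ACCOA"): -1, c("NADH"): -1, c("PROTON"): -1,
          c("ACALD"): 1, c("COA"): 1, c("NAD"): 1},
         REVERSIBLE, [["adhE"]])
    _rxn(m, "ALCOHOL-DEHYDROG-RXN",
         {c("ACALD"): -1, c("NADH"): -1, c("PROTON"): -1, c("ETOH"): 1, c("NAD"): 1},
         REVERSIBLE, [["adhE"]])
    _rxn(m, "D-LACTATE-DEHYDROGENASE-RXN",
         {c("PYR"): -1, c("NADH"): -1, c("PROTON"): -1, c("LAC"): 1, c("NAD"): 1},
         genes=[["ldhA"]])
    _rxn(m, "FHLMULTI-RXN",
         {c("FOR"): -1, c("PROTON"): -1, c("CO2"): 1, c("H2"): 1},
         genes=[["fdhF", "hycE"]])
    _rxn(m, "PEPCARBOX-RXN",
         {c("PEP"): -1, c("CO2"): -1, c("WATER"): -1,
          c("OAA"): 1, c("Pi"): 1, c("PROTON"): 1},
         genes=[["ppc"]])
    # fumarate reductase carries the published redundant-activity pattern:
    # the four-subunit complex coexists with individually active subunits,
    # so knocking out frdA alone never disables the reaction.
    _rxn(m, "FUMARATE-REDUCTASE-RXN",
         {c("FUM"): -1, c("UQ8H2"): -1, c("SUC"): 1, c("UQ8"): 1},
         genes=[["frdA", "frdB", "frdC", "frdD"], ["frdB"], ["frdC"], ["frdD"]])
    _rxn(m, "GLUTDEHYD-RXN",
         {c("AKG"): -1, c("NH4"): -1, c("NADPH"): -1, c("PROTON"): -1,
          c("GLU"): 1, c("NADP"): 1, c("WATER"): 1},
         genes=[["gdhA"]])
    _rxn(m, "PI-TRANSPORT-RXN",
         {p("Pi"): -1, p("PROTON"): -1, c("Pi"): 1, c("PROTON"): 1},
         genes=[["pitA"]])
    _rxn(m, "FRU-PTS-RXN",
         {p("FRU"): -1, c("PEP"): -1, c("F6P"): 1, c("PYR"): 1},
         genes=[["fruA", "ptsH", "ptsI"]])
    _rxn(m, "PYR-TRANSPORT-RXN",
         {p("PYR"): -1, p("PROTON"): -1, c("PYR"): 1, c("PROTON"): 1},
         REVERSIBLE, [["btsT"]])
    # fermentation-product efflux; acids leave with their protons, which
    # is what makes anaerobic acid secretion a net cytosolic proton sink
    _rxn(m, "ACETATE-EFFLUX-RXN",
         {c("ACET"): -1, c("PROTON"): -1, p("ACET"): 1, p("PROTON"): 1})
    _rxn(m, "FORMATE-EFFLUX-RXN",
         {c("FOR"): -1, c("PROTON"): -1, p("FOR"): 1, p("PROTON"): 1})
    _rxn(m, "LACTATE-EFFLUX-RXN",
         {c("LAC"): -1, c("PROTON"): -1, p("LAC"): 1, p("PROTON"): 1})
    _rxn(m, "SUCCINATE-EFFLUX-RXN",
         {c("SUC"): -1, c("PROTON"): -2, p("SUC"): 1, p("PROTON"): 2})
    _rxn(m, "ETHANOL-DIFFUSION-RXN", {c("ETOH"): -1, p("ETOH"): 1}, REVERSIBLE)
    _rxn(m, "H2-DIFFUSION-RXN", {c("H2"): -1, p("H2"): 1}, REVERSIBLE)
    # declared but route-free species for nutrient-screen negatives
    _met(m, "XYLOSE", "p")
    _met(m, "FE+2", "p")
    _met(m, "SULFATE", "p")
    return m


def fermentation_nutrients(
    glucose_bound: float = 10.0, oxygen_bound: float | None = None
) -> MetaboliteSet:
    """Glucose minimal medium for the fermentation fixture.

    Ammonium is supplied directly in the cytosol (passive diffusion at the
    experimental concentration); every other nutrient sits in the
    periplasm.  ``oxygen_bound=None`` leaves O2 unconstrained (aerobic);
    pass 0.0 for anaerobic runs, or use the anaerobic modification helper.
    """
    return MetaboliteSet(
        "glucose-minimal",
        (
            SetMember("GLC[p]", coefficient=glucose_bound, role="C"),
            SetMember("NH4[c]", role="N"),
            SetMember("Pi[p]", role="P"),
            SetMember("SULFATE[p]", role="S"),
            SetMember("OXYGEN[p]", coefficient=oxygen_bound),
            SetMember("FE+2[p]"),
            SetMember("WATER[p]"),
            SetMember("CO2[p]"),
            SetMember("PROTON[p]"),
        ),
    )


def fermentation_secretions() -> MetaboliteSet:
    return MetaboliteSet(
        "secretions",
        (
            SetMember("ACET[p]"),
            SetMember("FOR[p]"),
            SetMember("ETOH[p]"),
            SetMember("LAC[p]"),
            SetMember("SUC[p]"),
            SetMember("H2[p]"),
            SetMember("WATER[p]"),
            SetMember("CO2[p]"),
            SetMember("PROTON[p]"),
        ),
    )


def fermentation_biomass(gam: float = 53.95, ngam: float = 3.15) -> BiomassObjective:
    """Miniature 13-member biomass over central-carbon precursors.

    Coefficients are mmol/gCDW, chosen at the magnitude of measured
    precursor demands; cofactor-moiety species (CoA esters, NAD pools) are
    deliberately excluded because their moieties cannot be synthesized at
    this network scale.
    """
    return BiomassObjective(
        {
            "G6P[c]": 0.205,
            "F6P[c]": 0.071,
            "DHAP[c]": 0.129,
            "GAP[c]": 0.129,
            "PG3[c]": 1.496,
            "PEP[c]": 0.519,
            "PYR[c]": 2.833,
            "OAA[c]": 1.787,
            "AKG[c]": 1.079,
            "CIT[c]": 0.1,
            "SUC[c]": 0.1,
            "MAL[c]": 0.1,
            "GLU[c]": 0.25,
        },
        variant="core",
        gam=gam,
        ngam=ngam,
    )


def fermentation_problem(
    spec: FixtureSpec = ECOCYC_CONVENTION,
    glucose_bound: float = 10.0,
    oxygen_bound: float | None = None,
    fhl_enabled: bool = False,
) -> FluxNetwork:
    """Fermentation fixture with exchanges attached, ATP-max objective.

    Formate-hydrogen lyase ships disabled (the aerobic default); enable it
    explicitly or through the anaerobic modification helper.
    """
    model = build_fermentation_network(spec)
    net = build_network(
        model,
        fermentation_nutrients(glucose_bound, oxygen_bound),
        fermentation_secretions(),
    )
    if not fhl_enabled:
        net.set_bounds("FHLMULTI-RXN", 0.0, 0.0)
    net.objective_id = "ATPM"
    return net


# ---------------------------------------------------------------------------
# toy networks


def build_diamond_toy() -> ModelDefinition:
    """Two routes (2 reactions vs 3) from nutrient to target, equal yield.

    Taxicab minimization must select the shorter route at the same
    objective.  All species are C1 isomers so every step balances.
    """
    m = ModelDefinition()
    for base in "ABCDT":
        m.add_metabolite(
            Metabolite(base, formula={"C": 1, "H": 2, "O": 1}, charge=0, compartment="c")
        )
    _rxn(m, "R1-A-TO-B", {"A[c]": -1, "B[c]": 1})
    _rxn(m, "R2-B-TO-T", {"B[c]": -1, "T[c]": 1})
    _rxn(m, "R3-A-TO-C", {"A[c]": -1, "C[c]": 1})
    _rxn(m, "R4-C-TO-D", {"C[c]": -1, "D[c]": 1})
    _rxn(m, "R5-D-TO-T", {"D[c]": -1, "T[c]": 1})
    return m


def diamond_problem() -> FluxNetwork:
    net = build_network(
        build_diamond_toy(),
        MetaboliteSet("n", (SetMember("A[c]", coefficient=10.0),)),
        MetaboliteSet("s", (SetMember("T[c]"),)),
    )
    net.objective_id = "SEC-T[c]"
    return net


def build_blocked_biomass_toy(balanced: bool = False) -> ModelDefinition:
    """Nutrient N feeds A; B is made by a deliberately unbalanced reaction.

    With ``balanced=False`` the B-producing reaction fails the balance
    filter, so B is a blocked biomass member; restoring balance flips it.
    """
    m = ModelDefinition()
    m.add_metabolite(Metabolite("N", formula={"C": 2, "H": 4, "O": 2}, charge=0))
    m.add_metabolite(Metabolite("A", formula={"C": 2, "H": 4, "O": 2}, charge=0))
    m.add_metabolite(Metabolite("B", formula={"C": 2, "H": 2, "O": 2}, charge=0))
    m.add_metabolite(Metabolite("H2X", formula={"H": 2}, charge=0))
    _rxn(m, "N-TO-A", {"N[c]": -1, "A[c]": 1})
    if balanced:
        _rxn(m, "N-TO-B", {"N[c]": -1, "B[c]": 1, "H2X[c]": 1})
    else:
        _rxn(m, "N-TO-B", {"N[c]": -1, "B[c]": 1})
    return m


# ---------------------------------------------------------------------------
# synthetic experimental datasets


@dataclass(frozen=True)
class SyntheticEssentialityConfig:
    """Two-mode OD600 generator mirroring the bimodal knockout histogram.

    A fraction of strains does not grow (OD concentrated below the narrow
    threshold), a small "severe growth defect" tail lands between the
    narrow and broad thresholds (so the two criteria disagree on it), and
    the rest grows to a healthy mode.
    """

    n_genes: int = 200
    fraction_non_growing: float = 0.18
    fraction_defect: float = 0.05
    growing_location: float = 0.35
    growing_scale: float = 0.08
    non_growing_location: float = 0.002
    non_growing_scale: float = 0.001
    defect_low: float = 0.010
    defect_high: float = 0.085
    seed: int = 0


def generate_essentiality_table(
    config: SyntheticEssentialityConfig,
    genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic OD600 table plus ground-truth essentiality labels.

    Returns ``(observations, truth)``: observations carry gene,
    od600_24h, od600_48h, media; truth carries the narrow/broad labels the
    generator drew.  Same config and seed -> identical tables.  With both
    noise scales at zero, classification recovers the truth exactly.
    """
    rng = np.random.default_rng(config.seed)
    names = list(genes) if genes is not None else [
        f"g{i:04d}" for i in range(1, config.n_genes + 1)
    ]
    n = len(names)
    draw = rng.random(n)
    groups = np.where(
        draw < config.fraction_non_growing,
        "non-growing",
        np.where(draw < config.fraction_non_growing + config.fraction_defect,
                 "defect", "growing"),
    )
    od24 = np.empty(n)
    od48 = np.empty(n)
    for i, group in enumerate(groups):
        if group == "non-growing":
            base = config.non_growing_location + config.non_growing_scale * rng.normal()
            od24[i] = max(base, 0.0)
            od48[i] = max(base + config.non_growing_scale * rng.normal(), 0.0)
        elif group == "defect":
            centre = 0.5 * (config.defect_low + config.defect_high)
            half = 0.5 * (config.defect_high - config.defect_low)
            od24[i] = centre + half * (2 * rng.random() - 1) * (
                1.0 if config.growing_scale > 0 else 0.0
            )
            od48[i] = od24[i] * 1.5
        else:
            od24[i] = max(
                config.growing_location + config.growing_scale * rng.normal(), 0.15
            )
            od48[i] = od24[i] * 1.15
    table = pd.DataFrame(
        {
            "gene": names,
            "od600_24h": np.round(od24, 4),
            "od600_48h": np.round(od48, 4),
            "media": "glucose",
        }
    )
    truth = pd.DataFrame(
        {
            "gene": names,
            "group": groups,
            "narrow_essential": groups == "non-growing",
            "broad_essential": (groups == "non-growing") | (groups == "defect"),
        }
    )
    return table, truth


def generate_pm_dataset(
    wells: Sequence[tuple[str, str, str]] | int,
    n_datasets: int = 4,
    disagreement_rate: float = 70 / 383,
    positive_rate: float = 0.585,
    seed: int = 0,
):
    """Synthetic multi-dataset PM score records with controlled conflict.

    ``wells`` is either a list of (well, nutrient-key, role) triples or a
    well count (ids are synthesized).  Each well draws a ground-truth
    respiration phenotype; all datasets agree on it except that, with
    probability ``disagreement_rate``, one randomly chosen dataset reports
    the opposite class, which under the unanimity policy produces a
    no-consensus well.  Returns ``(records, truth)``.
    """
    from .phenotype import PMWellRecord

    rng = np.random.default_rng(seed)
    if isinstance(wells, int):
        wells = [(f"PM1-{i:03d}", f"NUTRIENT-{i:03d}[p]", "C") for i in range(1, wells + 1)]
    records: list[PMWellRecord] = []
    truth_rows = []
    for well, nutrient, role in wells:
        positive = rng.random() < positive_rate
        conflicted = rng.random() < disagreement_rate and n_datasets > 1
        scores = []
        for _ in range(n_datasets):
            if positive:
                scores.append("normal" if rng.random() < 0.7 else "low")
            else:
                scores.append("none")
        if conflicted:
            flip = int(rng.integers(n_datasets))
            scores[flip] = "none" if positive else "low"
        records.append(PMWellRecord(well, nutrient, role, tuple(scores)))
        truth_rows.append(
            {
                "well": well,
                "nutrient": nutrient,
                "role": role,
                "respiration": "positive" if positive else "negative",
                "conflicted": conflicted,
            }
        )
    return records, pd.DataFrame(truth_rows)
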