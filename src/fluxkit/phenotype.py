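"""Nutrient-utilization (phenotype-microarray-style) growth prediction.

A PM well supplies a standard minimal medium whose source of one element
(C, N, P or S) is swapped for the well's test nutrient.  Experimental
respiration scores from several datasets are binarized (normal/low ->
positive, none -> negative) and reduced to a consensus; wells without
consensus are excluded.  Each consensus well is then simulated: build the
medium, attach exchanges, solve, and compare the growth call with the
consensus, aggregating a confusion matrix in growth-positive orientation.

The respiration assay is compared directly with FBA growth because
elemental starvation arrests respiration (checkpoint linkage), which is
what lets a redox-dye assay probe nitrogen/phosphorus/sulfur sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from .build import FluxNetwork, attach_exchanges
from .core import MetaboliteSet, ModelDefinition, SetMember
from .engine import (
    BIOMASS_ID,
    BiomassObjective,
    EngineConfig,
    assemble_biomass,
    solve,
)
from .knockout import ConfusionMatrix, ScreenResult

__all__ = [
    "MediaDefinition",
    "PMWellRecord",
    "ConsensusCall",
    "build_media_nutrients",
    "apply_anaerobic_mods",
    "consensus",
    "pm_screen",
]

ELEMENT_ROLES = ("C", "N", "P", "S")

# Anaerobic biomass relaxation: these biosynthetic demands are dropped when
# oxygen is removed (their synthesis needs molecular oxygen).
ANAEROBIC_DROPPED_BIOMASS = ("PROTOHEME[c]", "PYRIDOXAL-5P[c]")
FHL_REACTION_ID = "FHLMULTI-RXN"
FERRIC_TO_FERROUS = {"FE+3": "FE+2"}


@dataclass(frozen=True)
class MediaDefinition:
    """A minimal medium with one variable nutrient of a given element role."""

    label: str
    base: MetaboliteSet
    variable_nutrient: str  # metabolite key, e.g. "SUC[p]"
    role: str  # element role in ELEMENT_ROLES
    aerobic: bool = True
    variable_bound: float = 10.0

    def __post_init__(self) -> None:
        if self.role not in ELEMENT_ROLES:
            raise ValueError(f"element role must be one of {ELEMENT_ROLES}")


@dataclass(frozen=True)
class PMWellRecord:
    well: str
    nutrient: str  # metabolite key
    role: str
    scores: tuple[str, ...]  # per dataset: normal | low | none

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValueError(f"{self.well}: at least one dataset score required")
        bad = set(self.scores) - {"normal", "low", "none"}
        if bad:
            raise ValueError(f"{self.well}: unknown scores {sorted(bad)}")


@dataclass(frozen=True)
class ConsensusCall:
    value: str  # positive | negative | no-consensus


def _base_id(key: str) -> str:
    return key.rsplit("[", 1)[0]


def build_media_nutrients(media: MediaDefinition) -> MetaboliteSet:
    """Base minimal nutrients with the element-role source swapped.

    Removes every base member tagged with the varied role, adds the well's
    variable nutrient under that role, and replaces ferric with ferrous
    iron (no enterobactin-style ferric uptake at this level of modeling).
    Self-replacement (the variable nutrient is the base source) is the
    identity.  An unknown variable nutrient is kept in the set — downstream
    exchange attachment will skip it with a warning, making the medium a
    no-uptake one and the prediction no-growth.
    """
    members: list[SetMember] = []
    for member in media.base.members:
        if member.role == media.role:
            continue
        base = _base_id(member.key)
        if base in FERRIC_TO_FERROUS:
            comp = member.key[len(base) + 1 : -1]
            members.append(replace(member, key=f"{FERRIC_TO_FERROUS[base]}[{comp}]"))
        else:
            members.append(member)
    members.append(
        SetMember(media.variable_nutrient, coefficient=media.variable_bound, role=media.role)
    )
    if not media.aerobic:
        members = [m for m in members if _base_id(m.key) != "OXYGEN"]
    return MetaboliteSet(f"nutrients-{media.label}", tuple(members))


def apply_anaerobic_mods(
    network: FluxNetwork,
    biomass: BiomassObjective,
    fhl_id: str = FHL_REACTION_ID,
    oxygen_exchange: str = "EX-OXYGEN[p]",
) -> tuple[FluxNetwork, BiomassObjective]:
    """Switch an aerobically configured problem to anaerobic conditions.

    Exactly three things change: the oxygen uptake bound drops to zero, the
    formate-hydrogen lyase reaction is enabled, and the oxygen-dependent
    biomass demands (protoheme, pyridoxal 5'-phosphate) are removed.
    Members absent from the biomass are a logged no-op; applying the
    modification twice equals applying it once.
    """
    net = network.copy()
    if oxygen_exchange in net.reactions:
        net.set_bounds(oxygen_exchange, 0.0, 0.0)
    if fhl_id in net.reactions:
        lb, ub = net.bounds[fhl_id]
        if ub <= 0.0:
            net.set_bounds(fhl_id, 0.0, net.default_bound)
    missing = [k for k in ANAEROBIC_DROPPED_BIOMASS if k not in biomass.members]
    if missing:
        warnings.warn(
            f"anaerobic biomass relaxation: members not present, no-op for {missing}",
            stacklevel=2,
        )
    return net, biomass.without(ANAEROBIC_DROPPED_BIOMASS)


def consensus(record: PMWellRecord, policy: str = "unanimity") -> ConsensusCall:
    """Cross-dataset consensus of binarized respiration scores.

    normal/low map to positive, none to negative.  Under the default
    unanimity policy the consensus is positive/negative only when every
    dataset agrees ('conflict-free'); the majority policy (a strict
    majority decides) is exposed as an alternative reading.
    """
    binary = ["positive" if s in ("normal", "low") else "negative" for s in record.scores]
    pos = binary.count("positive")
    neg = binary.count("negative")
    if policy == "unanimity":
        if neg == 0:
            return ConsensusCall("positive")
        if pos == 0:
            return ConsensusCall("negative")
        return ConsensusCall("no-consensus")
    if policy == "majority":
        if pos > neg:
            return ConsensusCall("positive")
        if neg > pos:
            return ConsensusCall("negative")
        return ConsensusCall("no-consensus")
    raise ValueError(f"unknown consensus policy {policy!r}")


@dataclass
class PMScreenConfig:
    policy: str = "unanimity"
    engine: EngineConfig = field(default_factory=lambda: EngineConfig(minimize_fluxes=False))


def pm_screen(
    network: FluxNetwork,
    wells: Sequence[PMWellRecord],
    base_media: MetaboliteSet,
    secretions: MetaboliteSet,
    biomass: BiomassObjective,
    aerobic: bool = True,
    config: PMScreenConfig | None = None,
    atpm_id: str = "ATPM",
) -> ScreenResult:
    """Growth-prediction benchmark over a list of PM well records.

    ``network`` must be the exchange-free metabolic network (exchanges are
    attached per well from the constructed medium).  Wells lacking a
    consensus are listed separately and excluded from the matrix.
    """
    config = config or PMScreenConfig()
    rows = []
    unscored: list[str] = []
    tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for record in wells:
        call = consensus(record, config.policy)
        if call.value == "no-consensus":
            unscored.append(record.well)
            rows.append(
                {
                    "well": record.well,
                    "nutrient": record.nutrient,
                    "exp": "no-consensus",
                    "sim": None,
                    "category": "unscored",
                }
            )
            continue
        media = MediaDefinition(
            label=record.well,
            base=base_media,
            variable_nutrient=record.nutrient,
            role=record.role,
            aerobic=aerobic,
        )
        nutrients = build_media_nutrients(media)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # unknown nutrients -> no-uptake medium
            net = attach_exchanges(network, nutrients, secretions)
        bm = biomass
        if not aerobic:
            net, bm = apply_anaerobic_mods(net, bm)
        net = assemble_biomass(net, bm, atpm_id=atpm_id)
        sol = solve(net, config.engine, objective_id=BIOMASS_ID)
        if sol.status == "unbounded":
            rows.append(
                {
                    "well": record.well,
                    "nutrient": record.nutrient,
                    "exp": call.value,
                    "sim": None,
                    "category": f"excluded:{sol.status}",
                }
            )
            continue
        sim_growth = sol.status == "optimal" and sol.growth
        exp_growth = call.value == "positive"
        category = {
            (True, True): "tp",
            (True, False): "fp",
            (False, True): "fn",
            (False, False): "tn",
        }[(sim_growth, exp_growth)]
        tally[category] += 1
        rows.append(
            {
                "well": record.well,
                "nutrient": record.nutrient,
                "exp": call.value,
                "sim": "growth" if sim_growth else "no-growth",
                "category": category,
            }
        )
    matrix = ConfusionMatrix(tally["tp"], tally["fp"], tally["fn"], tally["tn"])
    return ScreenResult(pd.DataFrame(rows), matrix, unscored)
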