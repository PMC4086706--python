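"""Gene-knockout essentiality screening.

A simulated knockout removes every reaction that loses all of its catalyst
units (and any reaction whose substrate loses all declared suppliers) and
re-solves the FBA problem: any growth at all scores the gene nonessential,
a blocked biomass scores it essential.  Experimental calls come from
OD600 measurements under either the narrow criteria (no perceptible
growth: OD600 <= 0.005 at both 24 and 48 hr) or the broad criteria
(impaired growth: OD600 <= 0.091 at 24 hr).  Agreement is summarized in a
confusion matrix oriented positive = growth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .build import FluxNetwork
from .core import ModelDefinition, gene_disabled_reactions
from .engine import EngineConfig, FluxSolution, solve

__all__ = [
    "ExperimentalObservation",
    "EssentialityCriteria",
    "ConfusionMatrix",
    "ScreenResult",
    "simulate_knockout",
    "classify_experimental",
    "screen",
    "percent",
]

NARROW_THRESHOLD = 0.005
BROAD_THRESHOLD = 0.091


def percent(numerator: int | Fraction, denominator: int | Fraction | None = None) -> float:
    """Percentage rounded half-up to one decimal, as the field prints it."""
    frac = Fraction(numerator) if denominator is None else Fraction(numerator, denominator)
    q = Decimal(frac.numerator * 100) / Decimal(frac.denominator)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ExperimentalObservation:
    gene: str
    od600_24h: float
    od600_48h: float | None = None
    media: str = "glucose"

    def __post_init__(self) -> None:
        if self.od600_24h < 0 or (self.od600_48h is not None and self.od600_48h < 0):
            raise ValueError("optical densities must be non-negative")


@dataclass(frozen=True)
class EssentialityCriteria:
    """Narrow or broad experimental essentiality classification."""

    mode: str = "broad"
    narrow_threshold: float = NARROW_THRESHOLD
    broad_threshold: float = BROAD_THRESHOLD

    def __post_init__(self) -> None:
        if self.mode not in ("narrow", "broad"):
            raise ValueError("mode must be 'narrow' or 'broad'")
        if self.narrow_threshold <= 0 or self.broad_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts in growth-positive orientation.

    tp = sim growth / exp growth, fp = sim growth / exp no-growth,
    fn = sim no-growth / exp growth, tn = sim no-growth / exp no-growth.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> Fraction:
        return Fraction(self.tp + self.tn, self.total)

    @property
    def sensitivity(self) -> Fraction:
        """Share of growth outcomes correctly predicted as growth."""
        return Fraction(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Fraction:
        """Share of no-growth outcomes correctly predicted as no-growth."""
        return Fraction(self.tn, self.tn + self.fp)

    @property
    def accuracy_pct(self) -> float:
        return percent(self.accuracy)

    @property
    def sensitivity_pct(self) -> float:
        return percent(self.sensitivity)

    @property
    def specificity_pct(self) -> float:
        return percent(self.specificity)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    def summary(self) -> str:
        return (
            f"TP {self.tp}  FP {self.fp}  FN {self.fn}  TN {self.tn}  "
            f"accuracy {self.accuracy_pct}%  sensitivity {self.sensitivity_pct}%  "
            f"specificity {self.specificity_pct}%"
        )


@dataclass
class ScreenResult:
    calls: pd.DataFrame
    matrix: ConfusionMatrix
    unscored: list[str] = field(default_factory=list)


def simulate_knockout(
    network: FluxNetwork,
    model: ModelDefinition,
    genes: str | Iterable[str],
    config: EngineConfig = EngineConfig(minimize_fluxes=False),
) -> FluxSolution:
    """Solve the network with all gene-disabled reactions removed.

    ``genes`` may be one gene or a set (multi-gene knockouts are a
    generalization of the single-gene screen).  Unknown genes warn and
    leave the network unchanged.  The growth call of the returned solution
    is the essentiality prediction: growth = nonessential.
    """
    knockout = {genes} if isinstance(genes, str) else set(genes)
    disabled_sources = gene_disabled_reactions(model, knockout)
    net = network.copy()
    for rid, (source, _) in net.provenance.items():
        if source in disabled_sources or rid in disabled_sources:
            net.set_bounds(rid, 0.0, 0.0)
    return solve(net, config)


def classify_experimental(
    obs: ExperimentalObservation, criteria: EssentialityCriteria
) -> str:
    """'essential' or 'nonessential' from OD600 data.

    Narrow mode requires both time points and calls essential iff OD600 is
    at or below the threshold at 24 and 48 hr; broad mode uses 24 hr only.
    Boundary equality classifies as essential (the criteria are '<=').
    """
    if criteria.mode == "narrow":
        if obs.od600_48h is None:
            raise ValueError(f"{obs.gene}: narrow criteria need the 48 hr measurement")
        essential = (
            obs.od600_24h <= criteria.narrow_threshold
            and obs.od600_48h <= criteria.narrow_threshold
        )
    else:
        essential = obs.od600_24h <= criteria.broad_threshold
    return "essential" if essential else "nonessential"


def screen(
    network: FluxNetwork,
    model: ModelDefinition,
    genes: Sequence[str],
    observations: Mapping[str, ExperimentalObservation] | Sequence[ExperimentalObservation],
    criteria: EssentialityCriteria = EssentialityCriteria(),
    config: EngineConfig = EngineConfig(minimize_fluxes=False),
) -> ScreenResult:
    """Single-gene knockout screen against experimental essentiality data.

    Iterates genes in the given (deterministic) order; genes without
    experimental data land in ``unscored`` and are excluded from the
    confusion matrix.  The wild-type problem is solved once; knockouts that
    disable no reaction reuse the wild-type growth call.
    """
    if not isinstance(observations, Mapping):
        observations = {obs.gene: obs for obs in observations}
    wild_type = solve(network, config)
    if wild_type.status != "optimal" or not wild_type.growth:
        warnings.warn("wild-type network does not grow; screen is degenerate", stacklevel=2)
    rows = []
    unscored: list[str] = []
    tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for gene in genes:
        disabled = gene_disabled_reactions(model, {gene}) if gene in model.genes else set()
        if disabled:
            sol = simulate_knockout(network, model, gene, config)
            sim_growth = sol.status == "optimal" and sol.growth
        else:
            sim_growth = wild_type.status == "optimal" and wild_type.growth
        sim_call = "nonessential" if sim_growth else "essential"
        obs = observations.get(gene)
        if obs is None:
            unscored.append(gene)
            rows.append(
                {"gene": gene, "sim": sim_call, "exp": None, "category": "unscored"}
            )
            continue
        exp_call = classify_experimental(obs, criteria)
        exp_growth = exp_call == "nonessential"
        category = {
            (True, True): "tp",
            (True, False): "fp",
            (False, True): "fn",
            (False, False): "tn",
        }[(sim_growth, exp_growth)]
        tally[category] += 1
        rows.append({"gene": gene, "sim": sim_call, "exp": exp_call, "category": category})
    matrix = ConfusionMatrix(tally["tp"], tally["fp"], tally["fn"], tally["tn"])
    return ScreenResult(pd.DataFrame(rows), matrix, unscored)
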