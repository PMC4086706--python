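"""Construction of a solvable flux network from a model definition.

The builder mirrors the run-time network construction of database-driven
FBA tools: reactions containing compound classes are instantiated into
concrete, mass-balanced versions, then a filter cascade removes reactions
that cannot take part in a stoichiometrically sound steady-state model
(unbalanced, balance-undetermined, physiologically irrelevant,
polymerization/polymer-segment/protein-modification, one-sided,
string-only substrates, variable stoichiometry, over the instantiation
permutation cap, or disconnected).  Every removal is logged with its
category so the construction is auditable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

from .core import (
    IRREVERSIBLE_REVERSE,
    REVERSIBLE,
    Metabolite,
    MetaboliteSet,
    ModelDefinition,
    Reaction,
    check_mass_balance,
)

__all__ = [
    "FluxNetwork",
    "FilterReport",
    "apply_filters",
    "instantiate_classes",
    "attach_exchanges",
    "build_network",
    "DEFAULT_EXCHANGE_BOUND",
    "DEFAULT_PERMUTATION_CAP",
]

# Large default bound for "unconstrained" exchanges; must exceed any
# realistic flux (the largest desk-scale optimum is 216) without hurting
# LP conditioning.
DEFAULT_EXCHANGE_BOUND = 3000.0
DEFAULT_PERMUTATION_CAP = 10000

FILTER_CATEGORIES = (
    "unbalanced",
    "undetermined",
    "irrelevant",
    "polymerization",
    "polymer-segment",
    "protein-modification",
    "one-sided",
    "string-substrate",
    "variable-stoichiometry",
    "permutation-cap",
    "ambiguous-instantiation",
    "disconnected",
)


@dataclass
class FilterReport:
    """Ordered exclusion log plus per-category counts."""

    exclusions: list[tuple[str, str]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    instantiated: dict[str, list[str]] = field(default_factory=dict)
    provenance: dict[str, tuple[str, dict[str, str]]] = field(default_factory=dict)

    def exclude(self, reaction_id: str, category: str) -> None:
        if category not in FILTER_CATEGORIES:
            raise ValueError(f"unknown filter category {category!r}")
        self.exclusions.append((reaction_id, category))

    @property
    def counts(self) -> dict[str, int]:
        out = {cat: 0 for cat in FILTER_CATEGORIES}
        for _, cat in self.exclusions:
            out[cat] += 1
        return {cat: n for cat, n in out.items() if n}

    def excluded_ids(self) -> set[str]:
        return {rid for rid, _ in self.exclusions}

    def to_text(self) -> str:
        lines = ["# network construction report"]
        lines.append(f"retained: {len(self.retained)}")
        for cat, n in sorted(self.counts.items()):
            lines.append(f"excluded[{cat}]: {n}")
        for rid, cat in self.exclusions:
            lines.append(f"exclude\t{rid}\t{cat}")
        return "\n".join(lines) + "\n"


@dataclass
class FluxNetwork:
    """The filtered, instantiated stoichiometric system.

    ``reactions`` hold only concrete (instance) metabolites; ``bounds`` are
    flux bounds in mmol/gCDW/hr; ``provenance`` traces each network
    reaction to its source reaction and class-binding map; ``exchanges``
    records attached exchange reactions by kind.
    """

    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    provenance: dict[str, tuple[str, dict[str, str]]] = field(default_factory=dict)
    exchanges: dict[str, str] = field(default_factory=dict)  # reaction id -> kind
    objective_id: str | None = None
    report: FilterReport | None = None
    default_bound: float = DEFAULT_EXCHANGE_BOUND

    def copy(self) -> "FluxNetwork":
        return FluxNetwork(
            metabolites=dict(self.metabolites),
            reactions=dict(self.reactions),
            bounds=dict(self.bounds),
            provenance=dict(self.provenance),
            exchanges=dict(self.exchanges),
            objective_id=self.objective_id,
            report=self.report,
            default_bound=self.default_bound,
        )

    def add_reaction(
        self,
        rxn: Reaction,
        bounds: tuple[float, float] | None = None,
        source: str | None = None,
        kind: str | None = None,
    ) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate network reaction {rxn.id}")
        self.reactions[rxn.id] = rxn
        self.bounds[rxn.id] = bounds if bounds is not None else direction_bounds(
            rxn, self.default_bound
        )
        self.provenance[rxn.id] = (source if source is not None else rxn.id, {})
        if kind:
            self.exchanges[rxn.id] = kind

    def set_bounds(self, reaction_id: str, lower: float, upper: float) -> None:
        if reaction_id not in self.reactions:
            raise KeyError(f"no network reaction {reaction_id}")
        if lower > upper:
            raise ValueError(f"{reaction_id}: lower bound above upper bound")
        self.bounds[reaction_id] = (lower, upper)

    def reaction_order(self) -> list[str]:
        return sorted(self.reactions)

    def stoichiometric_matrix(self):
        """Dense S (metabolite x reaction) plus row/column orderings."""
        import numpy as np

        rxn_ids = self.reaction_order()
        met_ids = sorted(self.metabolites)
        met_index = {k: i for i, k in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for key, coeff in self.reactions[rid].stoichiometry.items():
                S[met_index[key], j] = float(coeff)
        return S, met_ids, rxn_ids


def direction_bounds(rxn: Reaction, big: float = DEFAULT_EXCHANGE_BOUND) -> tuple[float, float]:
    if rxn.direction == REVERSIBLE:
        return (-big, big)
    if rxn.direction == IRREVERSIBLE_REVERSE:
        return (-big, 0.0)
    return (0.0, big)


# ---------------------------------------------------------------------------
# instantiation


class _Rejected(Exception):
    def __init__(self, category: str):
        self.category = category


def instantiate_classes(
    reaction: Reaction,
    metabolites: dict[str, Metabolite],
    cap: int = DEFAULT_PERMUTATION_CAP,
    include_charge: bool = True,
) -> list[Reaction]:
    """Replace compound classes by all mass-balanced instance bindings.

    The Cartesian product runs over the distinct classes in the reaction —
    the same class appearing on both sides binds to the same instance
    (paired binding).  Bindings whose instance reaction is not mass- and
    charge-balanced are dropped.  Raises a permutation-cap or
    ambiguous-instantiation rejection (consumed by :func:`apply_filters`)
    when the product exceeds ``cap`` or no balanced binding exists.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    class_keys = [
        key
        for key in reaction.stoichiometry
        if key in metabolites and metabolites[key].is_class
    ]
    if not class_keys:
        return [reaction]
    slots: list[tuple[str, list[str]]] = []
    permutations = 1
    for key in class_keys:
        met = metabolites[key]
        instances = [
            f"{inst}[{met.compartment}]"
            for inst in met.instance_ids
            if f"{inst}[{met.compartment}]" in metabolites
        ]
        if not instances:
            raise _Rejected("ambiguous-instantiation")
        slots.append((key, instances))
        permutations *= len(instances)
    if permutations > cap:
        raise _Rejected("permutation-cap")

    out: list[Reaction] = []
    for binding in itertools.product(*(inst for _, inst in slots)):
        mapping = {key: inst for (key, _), inst in zip(slots, binding)}
        stoich: dict[str, Fraction] = {}
        for key, coeff in reaction.stoichiometry.items():
            target = mapping.get(key, key)
            stoich[target] = stoich.get(target, Fraction(0)) + coeff
        stoich = {k: v for k, v in stoich.items() if v != 0}
        if not stoich:
            continue
        suffix = "__".join(mapping[key].split("[")[0] for key, _ in slots)
        candidate = reaction.with_stoichiometry(stoich, new_id=f"{reaction.id}__{suffix}")
        status = check_mass_balance(candidate, metabolites, include_charge=include_charge)
        if status.balanced:
            out.append(candidate)
            # remember the binding on the instance for provenance
            out[-1] = candidate
    if not out:
        raise _Rejected("ambiguous-instantiation")
    return out


# ---------------------------------------------------------------------------
# filter cascade


def apply_filters(
    model: ModelDefinition,
    cap: int = DEFAULT_PERMUTATION_CAP,
    include_charge: bool = True,
    exchange_metabolites: set[str] | None = None,
) -> tuple[list[Reaction], FilterReport]:
    """Run the construction filter cascade over a model definition.

    Class-containing reactions are instantiated first; the per-reaction
    filters then run in a fixed order (balance, relevance, type flags,
    one-sidedness, string-only substrates, variable stoichiometry), and the
    disconnected filter runs last, iterated to a fixed point because a
    removal can disconnect further reactions.  ``exchange_metabolites`` are
    counted as connections (nutrient/secretion/biomass set members).
    """
    report = FilterReport()
    provenance: dict[str, tuple[str, dict[str, str]]] = {}
    candidates: list[Reaction] = []

    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        has_unknown = any(k not in model.metabolites for k in rxn.stoichiometry)
        has_class = not has_unknown and any(
            model.metabolites[k].is_class for k in rxn.stoichiometry
        )
        if has_class:
            try:
                instances = instantiate_classes(
                    rxn, model.metabolites, cap=cap, include_charge=include_charge
                )
            except _Rejected as rej:
                report.exclude(rid, rej.category)
                continue
            report.instantiated[rid] = [inst.id for inst in instances]
            for inst in instances:
                binding = _binding_of(rxn, inst, model)
                provenance[inst.id] = (rid, binding)
                candidates.append(inst)
        else:
            provenance[rid] = (rid, {})
            candidates.append(rxn)

    retained: list[Reaction] = []
    for rxn in candidates:
        category = _per_reaction_category(rxn, model, include_charge)
        if category is None:
            retained.append(rxn)
        else:
            report.exclude(rxn.id, category)

    # disconnected filter, to a fixed point
    anchor = set(exchange_metabolites or ())
    while True:
        dropped = _disconnected(retained, anchor)
        if not dropped:
            break
        for rxn in dropped:
            report.exclude(rxn.id, "disconnected")
        dropped_ids = {r.id for r in dropped}
        retained = [r for r in retained if r.id not in dropped_ids]

    report.retained = [r.id for r in retained]
    report.provenance = {
        rxn.id: provenance.get(rxn.id, (rxn.id, {})) for rxn in retained
    }
    return retained, report


def _binding_of(source: Reaction, instance: Reaction, model: ModelDefinition) -> dict[str, str]:
    binding: dict[str, str] = {}
    source_keys = set(source.stoichiometry)
    for key in source_keys:
        if key in model.metabolites and model.metabolites[key].is_class:
            for new_key in instance.stoichiometry:
                if new_key not in source_keys:
                    base, comp = new_key[:-1].rsplit("[", 1)
                    met = model.metabolites[key]
                    if comp == met.compartment and base in met.instance_ids:
                        binding.setdefault(key, new_key)
    return binding


def _per_reaction_category(
    rxn: Reaction, model: ModelDefinition, include_charge: bool
) -> str | None:
    # one-sidedness takes categorization precedence: a one-sided reaction
    # is unbalanced by construction, and the log should name the cause
    if rxn.one_sided:
        return "one-sided"
    has_unknown = any(k not in model.metabolites for k in rxn.stoichiometry)
    if not has_unknown:
        status = check_mass_balance(rxn, model.metabolites, include_charge=include_charge)
        if status.value == "unbalanced":
            return "unbalanced"
        if status.value == "undetermined":
            return "undetermined"
    if not rxn.physiologically_relevant:
        return "irrelevant"
    for flag in ("polymerization", "polymer-segment", "protein-modification"):
        if flag in rxn.type_flags:
            return flag
    if has_unknown:
        return "string-substrate"
    if "variable-stoichiometry" in rxn.type_flags:
        return "variable-stoichiometry"
    return None


def _disconnected(reactions: list[Reaction], anchor: set[str]) -> list[Reaction]:
    out = []
    for rxn in reactions:
        keys = set(rxn.stoichiometry)
        if keys & anchor:
            continue
        shared = any(
            keys & set(other.stoichiometry) for other in reactions if other.id != rxn.id
        )
        if not shared:
            out.append(rxn)
    return out


# ---------------------------------------------------------------------------
# exchanges and assembly


def attach_exchanges(
    network: FluxNetwork,
    nutrients: MetaboliteSet,
    secretions: MetaboliteSet,
) -> FluxNetwork:
    """Attach uptake and efflux exchange reactions to a network copy.

    Each nutrient gets an uptake exchange producing the metabolite in its
    declared compartment, bounded above by its coefficient (or the default
    large bound when unconstrained); each secretion gets an unbounded
    efflux.  Members referencing unknown metabolites are skipped with a
    warning.  Positive exchange flux therefore means uptake for nutrients
    and production for secretions, matching the reporting convention.
    """
    net = network.copy()
    for member in nutrients.members:
        if member.key not in net.metabolites:
            warnings.warn(f"nutrient {member.key} absent from network; skipped", stacklevel=2)
            continue
        rid = f"EX-{member.key}"
        ub = float(member.coefficient) if member.coefficient is not None else net.default_bound
        rxn = Reaction(rid, {member.key: Fraction(1)}, spontaneous=True)
        if rid in net.reactions:
            net.set_bounds(rid, 0.0, ub)
            continue
        net.add_reaction(rxn, bounds=(0.0, ub), kind="nutrient")
    for member in secretions.members:
        if member.key not in net.metabolites:
            warnings.warn(f"secretion {member.key} absent from network; skipped", stacklevel=2)
            continue
        rid = f"SEC-{member.key}"
        if rid in net.reactions:
            continue
        rxn = Reaction(rid, {member.key: Fraction(-1)}, spontaneous=True)
        net.add_reaction(rxn, bounds=(0.0, net.default_bound), kind="secretion")
    return net


def build_network(
    model: ModelDefinition,
    nutrients: MetaboliteSet | None = None,
    secretions: MetaboliteSet | None = None,
    cap: int = DEFAULT_PERMUTATION_CAP,
    include_charge: bool = True,
) -> FluxNetwork:
    """Full construction pipeline: filter cascade, then exchange attachment."""
    anchors = set()
    for s in (nutrients, secretions):
        if s is not None:
            anchors |= set(s.keys())
    retained, report = apply_filters(
        model, cap=cap, include_charge=include_charge, exchange_metabolites=anchors
    )
    net = FluxNetwork(report=report)
    used_keys: set[str] = set()
    for rxn in retained:
        used_keys |= set(rxn.stoichiometry)
    net.metabolites = {
        key: met
        for key, met in model.metabolites.items()
        if key in used_keys and not met.is_class
    }
    for rxn in retained:
        source, binding = report.provenance.get(rxn.id, (rxn.id, {}))
        net.add_reaction(rxn, source=source)
        net.provenance[rxn.id] = (source, binding)
    if nutrients is not None or secretions is not None:
        net = attach_exchanges(
            net,
            nutrients or MetaboliteSet("nutrients"),
            secretions or MetaboliteSet("secretions"),
        )
    return net
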