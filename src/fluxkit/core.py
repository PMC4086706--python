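"""Domain types for database-style metabolic models.

A :class:`ModelDefinition` is the curated-database view of metabolism:
metabolites with chemical formulas and charges, reactions with exact
(rational) stoichiometry and directionality, and gene-product associations
linking genes to the reactions their products catalyze or feed as
substrates.  Everything downstream — network construction, flux balance
analysis, knockout and nutrient screens — consumes these types.

Conventions
-----------
* Metabolites are compartmentalized: a metabolite's :attr:`~Metabolite.key`
  is ``"<id>[<compartment>]"`` and reaction stoichiometries reference keys.
* Stoichiometric coefficients are :class:`fractions.Fraction` (exact),
  negative for consumption, positive for production.  Conversion to
  floating point happens only when a linear program is assembled.
* Mass balance is checked element-wise, protons counted like any element,
  and charge is checked alongside (a charge-only imbalance is unbalanced).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

__all__ = [
    "Metabolite",
    "Reaction",
    "GeneProductAssociation",
    "BalanceStatus",
    "ModelDefinition",
    "MetaboliteSet",
    "SetMember",
    "parse_formula",
    "format_formula",
    "check_mass_balance",
    "gene_disabled_reactions",
    "normalize_stoichiometry",
    "IRREVERSIBLE_FORWARD",
    "IRREVERSIBLE_REVERSE",
    "REVERSIBLE",
]

IRREVERSIBLE_FORWARD = "irreversible-forward"
IRREVERSIBLE_REVERSE = "irreversible-reverse"
REVERSIBLE = "reversible"

_DIRECTIONS = frozenset({IRREVERSIBLE_FORWARD, IRREVERSIBLE_REVERSE, REVERSIBLE})
_TYPE_FLAGS = frozenset(
    {"polymerization", "polymer-segment", "protein-modification", "variable-stoichiometry"}
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-notation formula string (``"C6H12O6"``) into an element map."""
    text = text.strip()
    if not text:
        raise ValueError("empty formula string")
    out: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        element, count = match.group(1), match.group(2)
        out[element] = out.get(element, 0) + (int(count) if count else 1)
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return out


def format_formula(formula: Mapping[str, int]) -> str:
    """Render an element map in Hill order (C, H, then alphabetical)."""

    def order(element: str) -> tuple[int, str]:
        return ({"C": 0, "H": 1}.get(element, 2), element)

    return "".join(
        f"{el}{formula[el] if formula[el] != 1 else ''}"
        for el in sorted(formula, key=order)
        if formula[el]
    )


@dataclass(frozen=True)
class Metabolite:
    """A compartmentalized chemical species.

    ``formula``/``charge`` may be ``None`` for structure-unknown species
    (these make any reaction containing them balance-undetermined).
    ``is_class`` marks compound classes; ``instance_ids`` lists the ids of
    member instances (same compartment) and is non-empty only for classes.
    """

    id: str
    name: str = ""
    formula: Mapping[str, int] | None = None
    charge: int | None = None
    compartment: str = "c"
    is_class: bool = False
    instance_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.is_class and self.instance_ids:
            raise ValueError(f"{self.id}: instance_ids only allowed on classes")
        if self.formula is not None:
            object.__setattr__(self, "formula", dict(self.formula))

    @property
    def key(self) -> str:
        return f"{self.id}[{self.compartment}]"

    @property
    def structure_known(self) -> bool:
        return self.formula is not None and self.charge is not None


@dataclass(frozen=True)
class Reaction:
    """A reaction with exact stoichiometry over metabolite keys."""

    id: str
    stoichiometry: Mapping[str, Fraction]
    direction: str = IRREVERSIBLE_FORWARD
    physiologically_relevant: bool = True
    type_flags: frozenset[str] = frozenset()
    spontaneous: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"{self.id}: unknown direction {self.direction!r}")
        bad = set(self.type_flags) - _TYPE_FLAGS
        if bad:
            raise ValueError(f"{self.id}: unknown type flags {sorted(bad)}")
        stoich = {k: Fraction(v) for k, v in self.stoichiometry.items()}
        if not stoich:
            raise ValueError(f"{self.id}: empty stoichiometry")
        if any(v == 0 for v in stoich.values()):
            raise ValueError(f"{self.id}: zero stoichiometric coefficient")
        object.__setattr__(self, "stoichiometry", stoich)
        object.__setattr__(self, "type_flags", frozenset(self.type_flags))

    @property
    def substrates(self) -> dict[str, Fraction]:
        return {k: -v for k, v in self.stoichiometry.items() if v < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        return {k: v for k, v in self.stoichiometry.items() if v > 0}

    @property
    def one_sided(self) -> bool:
        """True when all participants sit on one side of the equation."""
        signs = {v > 0 for v in self.stoichiometry.values()}
        return len(signs) == 1

    def with_stoichiometry(self, stoich: Mapping[str, Fraction], new_id: str | None = None) -> "Reaction":
        return replace(self, id=new_id or self.id, stoichiometry=stoich)


@dataclass(frozen=True)
class GeneProductAssociation:
    """Gene-protein-reaction structure for one reaction.

    ``catalysts`` is a set of enzyme units; each unit is the set of genes of
    one enzyme (a multi-gene unit is a complex, several units are isozymes).
    ``substrate_suppliers`` maps a substrate metabolite key to the genes
    whose products supply it (e.g. carrier proteins).
    """

    reaction_id: str
    catalysts: frozenset[frozenset[str]] = frozenset()
    substrate_suppliers: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "catalysts", frozenset(frozenset(unit) for unit in self.catalysts)
        )
        object.__setattr__(
            self,
            "substrate_suppliers",
            {k: frozenset(v) for k, v in dict(self.substrate_suppliers).items()},
        )

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for unit in self.catalysts:
            out |= unit
        for suppliers in self.substrate_suppliers.values():
            out |= suppliers
        return frozenset(out)

    def disabled_by(self, knockout: frozenset[str] | set[str]) -> bool:
        """Is the reaction gene-disabled by knockout set ``knockout``?

        Disabled iff every catalyst unit intersects the knockout set (so no
        intact enzyme remains), or some substrate's declared suppliers are
        all knocked out.  Empty catalysts = spontaneous/orphan: never
        disabled via catalysis.
        """
        knockout = frozenset(knockout)
        if self.catalysts and all(unit & knockout for unit in self.catalysts):
            return True
        for suppliers in self.substrate_suppliers.values():
            if suppliers and suppliers <= knockout:
                return True
        return False


@dataclass(frozen=True)
class BalanceStatus:
    """Outcome of a mass/charge balance check."""

    value: str  # balanced | unbalanced | undetermined
    per_element_delta: Mapping[str, int] | None = None
    charge_delta: int | None = None

    @property
    def balanced(self) -> bool:
        return self.value == "balanced"


@dataclass(frozen=True)
class SetMember:
    """One member of a nutrient/secretion/biomass metabolite set.

    ``coefficient`` is the uptake bound (mmol/gCDW/hr) for nutrients or the
    demand coefficient (mmol/gCDW) for biomass members; ``None`` means
    unconstrained.  ``role`` tags the elemental role (C/N/P/S) a nutrient
    fulfils, used by phenotype-microarray media construction.
    """

    key: str
    coefficient: float | None = None
    role: str | None = None
    note: str = ""


@dataclass(frozen=True)
class MetaboliteSet:
    name: str
    members: tuple[SetMember, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))

    def keys(self) -> list[str]:
        return [m.key for m in self.members]

    def get(self, key: str) -> SetMember | None:
        for m in self.members:
            if m.key == key:
                return m
        return None

    def without(self, keys: Iterable[str]) -> "MetaboliteSet":
        drop = set(keys)
        return MetaboliteSet(self.name, tuple(m for m in self.members if m.key not in drop))

    def with_member(self, member: SetMember) -> "MetaboliteSet":
        return MetaboliteSet(self.name, self.members + (member,))


@dataclass
class ModelDefinition:
    """Container for the database-like model description."""

    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    associations: dict[str, GeneProductAssociation] = field(default_factory=dict)
    compartments: dict[str, str] = field(
        default_factory=lambda: {"c": "cytosol", "p": "periplasm", "e": "extracellular"}
    )

    def add_metabolite(self, met: Metabolite) -> None:
        if met.key in self.metabolites:
            raise ValueError(f"duplicate metabolite {met.key}")
        if met.compartment not in self.compartments:
            raise ValueError(f"{met.key}: undeclared compartment {met.compartment!r}")
        self.metabolites[met.key] = met

    def add_reaction(self, rxn: Reaction, association: GeneProductAssociation | None = None) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction {rxn.id}")
        self.reactions[rxn.id] = rxn
        if association is not None:
            if association.reaction_id != rxn.id:
                raise ValueError("association reaction_id mismatch")
            self.associations[rxn.id] = association

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for assoc in self.associations.values():
            out |= assoc.genes
        return frozenset(out)

    def validate(self) -> None:
        """Referential-integrity check across all id references."""
        for rxn in self.reactions.values():
            for key in rxn.stoichiometry:
                if key not in self.metabolites:
                    raise KeyError(f"reaction {rxn.id} references unknown metabolite {key}")
        for assoc in self.associations.values():
            if assoc.reaction_id not in self.reactions:
                raise KeyError(f"association references unknown reaction {assoc.reaction_id}")
        for met in self.metabolites.values():
            for inst in met.instance_ids:
                if f"{inst}[{met.compartment}]" not in self.metabolites:
                    raise KeyError(f"class {met.key} lists unknown instance {inst}")


# ---------------------------------------------------------------------------
# operations


def check_mass_balance(
    reaction: Reaction,
    metabolites: Mapping[str, Metabolite],
    include_charge: bool = True,
) -> BalanceStatus:
    """Element- and charge-balance a reaction.

    Returns ``undetermined`` when any participant lacks a formula or charge;
    otherwise ``balanced``/``unbalanced`` with the per-element net deltas
    (products minus substrates).  Protons are counted like any element.
    """
    for key in reaction.stoichiometry:
        if key not in metabolites:
            raise KeyError(f"reaction {reaction.id} references unknown metabolite {key}")
    participants = [(metabolites[k], v) for k, v in reaction.stoichiometry.items()]
    if any(m.formula is None or (include_charge and m.charge is None) for m, _ in participants):
        return BalanceStatus("undetermined")
    delta: dict[str, Fraction] = {}
    charge = Fraction(0)
    for met, coeff in participants:
        assert met.formula is not None
        for element, count in met.formula.items():
            delta[element] = delta.get(element, Fraction(0)) + coeff * count
        if include_charge:
            assert met.charge is not None
            charge += coeff * met.charge
    delta = {el: v for el, v in delta.items() if v != 0}
    ok = not delta and (not include_charge or charge == 0)
    return BalanceStatus(
        "balanced" if ok else "unbalanced",
        per_element_delta={el: _as_number(v) for el, v in delta.items()},
        charge_delta=_as_number(charge) if include_charge else None,
    )


def _as_number(value: Fraction):
    return int(value) if value.denominator == 1 else value


def gene_disabled_reactions(model: ModelDefinition, knockout: Iterable[str]) -> set[str]:
    """Reactions disabled by knocking out ``knockout``.

    A reaction is disabled iff every catalyst unit loses a member, or a
    substrate loses all of its declared suppliers.  Reactions retaining an
    intact isozyme unit are not disabled.  Unknown gene ids warn.
    """
    knockout = frozenset(knockout)
    unknown = knockout - model.genes
    if unknown:
        warnings.warn(
            f"knockout genes not in any association: {sorted(unknown)}", stacklevel=2
        )
    return {
        rid
        for rid, assoc in model.associations.items()
        if assoc.disabled_by(knockout)
    }


def normalize_stoichiometry(reaction: Reaction) -> Reaction:
    """Rescale to minimum whole-integer stoichiometry (overall GCD 1).

    Returns a new reaction; the input is unmodified and direction is kept.
    """
    coeffs = list(reaction.stoichiometry.values())
    lcm = math.lcm(*(c.denominator for c in coeffs))
    scaled = [c * lcm for c in coeffs]
    gcd = math.gcd(*(abs(int(c)) for c in scaled))
    factor = Fraction(lcm, gcd)
    return reaction.with_stoichiometry(
        {k: v * factor for k, v in reaction.stoichiometry.items()}
    )
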