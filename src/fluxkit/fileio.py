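"""Readers and writers for the model TSV dialect, run files and SBML.

Model tables are three tab-separated files:

``metabolites.tsv``
    id, name, formula (Hill notation, empty = structure unknown), charge
    (empty = unknown), compartment, class (0/1), instances (``|``-joined).
``reactions.tsv``
    id, equation, direction flagging handled by the arrow
    (``->`` forward, ``<-`` reverse, ``<->`` reversible), relevant (0/1),
    flags (``|``-joined type flags), spontaneous (0/1).
    Equation grammar: ``"2 A[c] + B[p] -> C[c]"`` with ``[c]/[p]/[e]``
    compartment suffixes; coefficients may be integers, decimals or
    fractions (``3/2``).
``gpr.tsv``
    reaction_id, catalysts (`` or ``-separated `` and ``-joined gene
    lists), suppliers (``substrate:gene|gene;...``).

Run configuration files carry the declarative nutrient/secretion/biomass
sections of a flux run (YAML layout).  SBML export/import goes through
cobra, the community constraint-based modeling library.
"""

from __future__ import annotations

import re
from fractions import Fraction
from pathlib import Path

import yaml

from .build import FluxNetwork, direction_bounds
from .core import (
    IRREVERSIBLE_FORWARD,
    IRREVERSIBLE_REVERSE,
    REVERSIBLE,
    GeneProductAssociation,
    Metabolite,
    MetaboliteSet,
    ModelDefinition,
    Reaction,
    SetMember,
    format_formula,
    parse_formula,
)
from .engine import BiomassObjective, EngineConfig

__all__ = [
    "read_model",
    "write_model",
    "parse_equation",
    "format_equation",
    "read_run_config",
    "write_run_config",
    "RunConfig",
    "export_sbml",
    "import_sbml",
    "network_to_cobra",
]

_ARROWS = {"<->": REVERSIBLE, "->": IRREVERSIBLE_FORWARD, "<-": IRREVERSIBLE_REVERSE}
_TERM = re.compile(r"^(?:(\d+(?:\.\d+)?(?:/\d+)?)\s+)?(\S+)$")


def parse_equation(text: str) -> tuple[dict[str, Fraction], str]:
    """Parse ``"2 A[c] + B[p] -> C[c]"`` into (stoichiometry, direction)."""
    for arrow in ("<->", "->", "<-"):
        if arrow in text:
            left, right = text.split(arrow, 1)
            direction = _ARROWS[arrow]
            break
    else:
        raise ValueError(f"equation has no arrow: {text!r}")
    stoich: dict[str, Fraction] = {}

    def add_side(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            match = _TERM.match(term)
            if match is None:
                raise ValueError(f"cannot parse equation term {term!r}")
            coeff = Fraction(match.group(1)) if match.group(1) else Fraction(1)
            key = match.group(2)
            if not re.match(r"^.+\[[a-z]\]$", key):
                raise ValueError(f"metabolite {key!r} lacks a compartment suffix")
            stoich[key] = stoich.get(key, Fraction(0)) + sign * coeff
        return

    add_side(left, -1)
    add_side(right, +1)
    return {k: v for k, v in stoich.items() if v != 0}, direction


def format_equation(rxn: Reaction) -> str:
    arrow = {REVERSIBLE: "<->", IRREVERSIBLE_FORWARD: "->", IRREVERSIBLE_REVERSE: "<-"}[
        rxn.direction
    ]

    def side(items: dict[str, Fraction]) -> str:
        parts = []
        for key in sorted(items):
            coeff = items[key]
            parts.append(key if coeff == 1 else f"{coeff} {key}")
        return " + ".join(parts)

    return f"{side(rxn.substrates)} {arrow} {side(rxn.products)}"


def write_model(model: ModelDefinition, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "metabolites.tsv", "w") as fh:
        fh.write("id\tname\tformula\tcharge\tcompartment\tclass\tinstances\n")
        for key in sorted(model.metabolites):
            met = model.metabolites[key]
            fh.write(
                "\t".join(
                    [
                        met.id,
                        met.name,
                        format_formula(met.formula) if met.formula is not None else "",
                        "" if met.charge is None else str(met.charge),
                        met.compartment,
                        "1" if met.is_class else "0",
                        "|".join(met.instance_ids),
                    ]
                )
                + "\n"
            )
    with open(directory / "reactions.tsv", "w") as fh:
        fh.write("id\tequation\trelevant\tflags\tspontaneous\n")
        for rid in sorted(model.reactions):
            rxn = model.reactions[rid]
            fh.write(
                "\t".join(
                    [
                        rxn.id,
                        format_equation(rxn),
                        "1" if rxn.physiologically_relevant else "0",
                        "|".join(sorted(rxn.type_flags)),
                        "1" if rxn.spontaneous else "0",
                    ]
                )
                + "\n"
            )
    with open(directory / "gpr.tsv", "w") as fh:
        fh.write("reaction_id\tcatalysts\tsuppliers\n")
        for rid in sorted(model.associations):
            assoc = model.associations[rid]
            units = " or ".join(
                " and ".join(sorted(unit)) for unit in sorted(assoc.catalysts, key=sorted)
            )
            suppliers = ";".join(
                f"{sub}:{'|'.join(sorted(genes))}"
                for sub, genes in sorted(assoc.substrate_suppliers.items())
            )
            fh.write(f"{rid}\t{units}\t{suppliers}\n")


def _read_tsv(path: Path) -> list[dict[str, str]]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    out = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) > len(header):
            raise ValueError(f"{path}:{lineno}: too many columns")
        cells += [""] * (len(header) - len(cells))
        out.append(dict(zip(header, cells)))
    return out


def read_model(directory: str | Path) -> ModelDefinition:
    """Read the three-table model dialect; round-trips :func:`write_model`."""
    directory = Path(directory)
    model = ModelDefinition()
    for row in _read_tsv(directory / "metabolites.tsv"):
        model.add_metabolite(
            Metabolite(
                row["id"],
                name=row["name"],
                formula=parse_formula(row["formula"]) if row["formula"] else None,
                charge=int(row["charge"]) if row["charge"] else None,
                compartment=row["compartment"],
                is_class=row["class"] == "1",
                instance_ids=tuple(x for x in row["instances"].split("|") if x),
            )
        )
    for row in _read_tsv(directory / "reactions.tsv"):
        try:
            stoich, direction = parse_equation(row["equation"])
        except ValueError as exc:
            raise ValueError(f"reaction {row['id']}: {exc}") from exc
        model.add_reaction(
            Reaction(
                row["id"],
                stoich,
                direction=direction,
                physiologically_relevant=row.get("relevant", "1") != "0",
                type_flags=frozenset(x for x in row.get("flags", "").split("|") if x),
                spontaneous=row.get("spontaneous", "0") == "1",
            )
        )
    gpr_path = directory / "gpr.tsv"
    if gpr_path.exists():
        for row in _read_tsv(gpr_path):
            catalysts = frozenset(
                frozenset(g.strip() for g in unit.split(" and "))
                for unit in row["catalysts"].split(" or ")
                if unit.strip()
            )
            suppliers = {}
            for chunk in row.get("suppliers", "").split(";"):
                if ":" in chunk:
                    sub, genes = chunk.split(":", 1)
                    suppliers[sub] = frozenset(g for g in genes.split("|") if g)
            model.associations[row["reaction_id"]] = GeneProductAssociation(
                row["reaction_id"], catalysts=catalysts, substrate_suppliers=suppliers
            )
    return model


# ---------------------------------------------------------------------------
# run configuration


class RunConfig:
    """Declarative flux run: model path, sets, engine options, seed."""

    def __init__(
        self,
        model_dir: str,
        nutrients: MetaboliteSet,
        secretions: MetaboliteSet,
        biomass: BiomassObjective | None = None,
        objective: str = "BIOMASS",
        minimize_fluxes: bool = True,
        epsilon: float = 1e-6,
        cap: int = 10000,
        seed: int = 0,
    ):
        self.model_dir = model_dir
        self.nutrients = nutrients
        self.secretions = secretions
        self.biomass = biomass
        self.objective = objective
        self.minimize_fluxes = minimize_fluxes
        self.epsilon = epsilon
        self.cap = cap
        self.seed = seed

    def engine_config(self) -> EngineConfig:
        return EngineConfig(epsilon=self.epsilon, minimize_fluxes=self.minimize_fluxes)


def _members_to_yaml(mset: MetaboliteSet) -> list:
    out = []
    for m in mset.members:
        entry: dict = {"id": m.key}
        if m.coefficient is not None:
            entry["bound"] = m.coefficient
        if m.role:
            entry["role"] = m.role
        out.append(entry)
    return out


def write_run_config(config: RunConfig, path: str | Path) -> None:
    doc = {
        "model": config.model_dir,
        "objective": config.objective,
        "options": {
            "minimize-fluxes": "yes" if config.minimize_fluxes else "no",
            "epsilon": config.epsilon,
            "permutation-cap": config.cap,
            "seed": config.seed,
        },
        "nutrients": _members_to_yaml(config.nutrients),
        "secretions": _members_to_yaml(config.secretions),
    }
    if config.biomass is not None:
        doc["biomass"] = {
            "variant": config.biomass.variant,
            "gam": config.biomass.gam,
            "ngam": config.biomass.ngam,
            "members": [
                {"id": k, "coefficient": v} for k, v in sorted(config.biomass.members.items())
            ],
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _yaml_to_set(name: str, entries: list | None) -> MetaboliteSet:
    members = tuple(
        SetMember(e["id"], coefficient=e.get("bound"), role=e.get("role"))
        for e in (entries or [])
    )
    return MetaboliteSet(name, members)


def read_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    options = doc.get("options", {})
    biomass = None
    if "biomass" in doc:
        b = doc["biomass"]
        biomass = BiomassObjective(
            {e["id"]: float(e["coefficient"]) for e in b.get("members", [])},
            variant=b.get("variant", "core"),
            gam=float(b.get("gam", 0.0)),
            ngam=float(b.get("ngam", 0.0)),
        )
    return RunConfig(
        model_dir=doc["model"],
        nutrients=_yaml_to_set("nutrients", doc.get("nutrients")),
        secretions=_yaml_to_set("secretions", doc.get("secretions")),
        biomass=biomass,
        objective=doc.get("objective", "BIOMASS"),
        minimize_fluxes=options.get("minimize-fluxes", "yes") == "yes",
        epsilon=float(options.get("epsilon", 1e-6)),
        cap=int(options.get("permutation-cap", 10000)),
        seed=int(options.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# SBML via cobra


def network_to_cobra(network: FluxNetwork, model_id: str = "fluxkit"):
    """Convert a flux network to a cobra model (same S matrix and bounds)."""
    import cobra

    model = cobra.Model(model_id)
    mets = {}
    for key in sorted(network.metabolites):
        met = network.metabolites[key]
        cm = cobra.Metabolite(
            key,
            formula=format_formula(met.formula) if met.formula else None,
            charge=met.charge,
            compartment=met.compartment,
        )
        mets[key] = cm
    model.add_metabolites(list(mets.values()))
    reactions = []
    for rid in network.reaction_order():
        rxn = network.reactions[rid]
        lb, ub = network.bounds[rid]
        cr = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        cr.add_metabolites({mets[k]: float(v) for k, v in rxn.stoichiometry.items()})
        reactions.append(cr)
    model.add_reactions(reactions)
    if network.objective_id:
        model.objective = model.reactions.get_by_id(network.objective_id)
    return model


def export_sbml(network: FluxNetwork, path: str | Path) -> None:
    """Write the network as SBML: one species per compartmentalized
    metabolite, one reaction per network reaction with its bounds,
    exchanges included as boundary reactions."""
    import cobra.io

    cobra.io.write_sbml_model(network_to_cobra(network), str(path))


def import_sbml(path: str | Path) -> FluxNetwork:
    """Read an SBML file back into a flux network (S matrix and bounds)."""
    import cobra.io

    cmodel = cobra.io.read_sbml_model(str(path))
    net = FluxNetwork()
    for met in cmodel.metabolites:
        base, comp = _split_key(met.id)
        net.metabolites[met.id] = Metabolite(
            base,
            formula=parse_formula(met.formula) if met.formula else None,
            charge=met.charge,
            compartment=comp,
        )
    for rxn in cmodel.reactions:
        stoich = {m.id: Fraction(str(coeff)) for m, coeff in rxn.metabolites.items()}
        direction = (
            REVERSIBLE
            if rxn.lower_bound < 0 < rxn.upper_bound
            else (IRREVERSIBLE_REVERSE if rxn.upper_bound <= 0 else IRREVERSIBLE_FORWARD)
        )
        net.add_reaction(
            Reaction(rxn.id, stoich, direction=direction, spontaneous=True),
            bounds=(rxn.lower_bound, rxn.upper_bound),
        )
    return net


def _split_key(key: str) -> tuple[str, str]:
    if key.endswith("]") and "[" in key:
        base, comp = key[:-1].rsplit("[", 1)
        return base, comp
    return key, "c"
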