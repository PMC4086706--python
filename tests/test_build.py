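"""Network construction: filter cascade, instantiation, exchanges."""

import itertools
import warnings
from fractions import Fraction

import pytest

from fluxkit.build import (
    apply_filters,
    attach_exchanges,
    build_network,
    instantiate_classes,
)
from fluxkit.build import _Rejected  # noqa: F401  (rejection categories surface via apply_filters)
from fluxkit.core import (
    Metabolite,
    MetaboliteSet,
    ModelDefinition,
    Reaction,
    SetMember,
    check_mass_balance,
    parse_formula,
)


def _simple_model() -> ModelDefinition:
    m = ModelDefinition()
    for base, formula in [("A", "C2H4O2"), ("B", "C2H4O2"), ("C", "C2H4O2")]:
        m.add_metabolite(Metabolite(base, formula=parse_formula(formula), charge=0))
    return m


class TestFilters:
    def test_balanced_connected_reaction_is_retained(self):
        m = _simple_model()
        m.add_reaction(Reaction("R1", {"A[c]": -1, "B[c]": 1}))
        m.add_reaction(Reaction("R2", {"B[c]": -1, "C[c]": 1}))
        retained, report = apply_filters(m)
        assert report.retained == ["R1", "R2"]
        assert report.exclusions == []

    def test_polymerization_flag_excluded_with_category(self):
        # a balanced but polymerization-flagged reaction (the folate
        # polyglutamylation pattern) is excluded under its own category
        m = _simple_model()
        m.add_reaction(Reaction("KEEP", {"A[c]": -1, "B[c]": 1}))
        m.add_reaction(
            Reaction(
                "POLYGLU",
                {"A[c]": -1, "B[c]": 1},
                type_flags=frozenset({"polymerization"}),
            )
        )
        _, report = apply_filters(m, exchange_metabolites={"A[c]", "B[c]"})
        assert ("POLYGLU", "polymerization") in report.exclusions

    @pytest.mark.parametrize(
        "kwargs,category",
        [
            (dict(physiologically_relevant=False), "irrelevant"),
            (dict(type_flags=frozenset({"protein-modification"})), "protein-modification"),
            (dict(type_flags=frozenset({"polymer-segment"})), "polymer-segment"),
            (dict(type_flags=frozenset({"variable-stoichiometry"})), "variable-stoichiometry"),
        ],
    )
    def test_flag_filters(self, kwargs, category):
        m = _simple_model()
        m.add_reaction(Reaction("R", {"A[c]": -1, "B[c]": 1}, **kwargs))
        _, report = apply_filters(m, exchange_metabolites={"A[c]", "B[c]"})
        assert report.exclusions == [("R", category)]

    def test_unbalanced_and_undetermined_categories(self):
        m = _simple_model()
        m.add_metabolite(Metabolite("GHOSTLY", formula=None, charge=None))
        m.add_reaction(Reaction("BAD", {"A[c]": -1, "B[c]": 2}))
        m.add_reaction(Reaction("UNK", {"A[c]": -1, "GHOSTLY[c]": 1}))
        _, report = apply_filters(m, exchange_metabolites={"A[c]"})
        assert ("BAD", "unbalanced") in report.exclusions
        assert ("UNK", "undetermined") in report.exclusions

    def test_one_sided_and_string_substrate(self):
        m = _simple_model()
        m.add_reaction(Reaction("SINK", {"A[c]": -1}))
        m.add_reaction(Reaction("STRINGY", {"A[c]": -1, "an unknown peptide[c]": 1}))
        _, report = apply_filters(m, exchange_metabolites={"A[c]"})
        assert ("SINK", "one-sided") in report.exclusions
        assert ("STRINGY", "string-substrate") in report.exclusions

    def test_orphan_reaction_excluded_as_disconnected(self):
        # 5-reaction toy with one reaction sharing no metabolites; a
        # brute-force pairwise-sharing oracle fixes the expectation
        m = _simple_model()
        for base in ["D", "E", "X", "Y"]:
            m.add_metabolite(Metabolite(base, formula=parse_formula("C2H4O2"), charge=0))
        reactions = {
            "R1": {"A[c]": -1, "B[c]": 1},
            "R2": {"B[c]": -1, "C[c]": 1},
            "R3": {"C[c]": -1, "D[c]": 1},
            "R4": {"D[c]": -1, "E[c]": 1},
            "ORPHAN": {"X[c]": -1, "Y[c]": 1},
        }
        for rid, stoich in reactions.items():
            m.add_reaction(Reaction(rid, stoich))
        # oracle: pairwise metabolite sharing against the anchor set {A}
        anchor = {"A[c]"}
        orphan_ids = {
            rid
            for rid, st in reactions.items()
            if not (set(st) & anchor)
            and not any(
                set(st) & set(other) for oid, other in reactions.items() if oid != rid
            )
        }
        assert orphan_ids == {"ORPHAN"}
        retained, report = apply_filters(m, exchange_metabolites=anchor)
        assert len(retained) == 4
        assert report.exclusions == [("ORPHAN", "disconnected")]

    def test_disconnection_cascades_to_fixed_point(self):
        # removing an unbalanced bridge strands the far side of a chain
        m = _simple_model()
        m.add_metabolite(Metabolite("D", formula=parse_formula("C2H4O2"), charge=0))
        m.add_reaction(Reaction("GOOD", {"A[c]": -1, "B[c]": 1}))
        m.add_reaction(Reaction("BRIDGE", {"B[c]": -1, "C[c]": 2}))  # unbalanced
        m.add_reaction(Reaction("FAR", {"C[c]": -1, "D[c]": 1}))
        _, report = apply_filters(m, exchange_metabolites={"A[c]"})
        assert ("BRIDGE", "unbalanced") in report.exclusions
        assert ("FAR", "disconnected") in report.exclusions
        assert report.retained == ["GOOD"]

    def test_exclusion_log_partitions_source_reactions(self, fermentation_model):
        retained, report = apply_filters(
            fermentation_model, exchange_metabolites={"GLC[p]"}
        )
        seen = set(report.retained) | report.excluded_ids()
        assert seen == set(fermentation_model.reactions)
        assert len(report.retained) + len(report.exclusions) == len(
            fermentation_model.reactions
        )

    def test_filter_cascade_is_idempotent(self, fermentation_model):
        retained, report = apply_filters(
            fermentation_model, exchange_metabolites={"GLC[p]"}
        )
        second = ModelDefinition()
        second.metabolites = dict(fermentation_model.metabolites)
        for rxn in retained:
            second.add_reaction(rxn)
        retained2, report2 = apply_filters(second, exchange_metabolites={"GLC[p]"})
        assert report2.exclusions == []
        assert [r.id for r in retained2] == [r.id for r in retained]


class TestInstantiation:
    def _class_model(self):
        m = ModelDefinition()
        m.add_metabolite(Metabolite("ETOH", formula=parse_formula("C2H6O"), charge=0))
        m.add_metabolite(Metabolite("PROH", formula=parse_formula("C3H8O"), charge=0))
        m.add_metabolite(Metabolite("ACALD", formula=parse_formula("C2H4O"), charge=0))
        m.add_metabolite(Metabolite("PROAL", formula=parse_formula("C3H6O"), charge=0))
        m.add_metabolite(Metabolite("NAD", formula=parse_formula("C21H26N7O14P2"), charge=-1))
        m.add_metabolite(Metabolite("NADH", formula=parse_formula("C21H27N7O14P2"), charge=-2))
        m.add_metabolite(Metabolite("PROTON", formula=parse_formula("H"), charge=1))
        m.add_metabolite(
            Metabolite("ALCOHOL", is_class=True, instance_ids=("ETOH", "PROH"))
        )
        m.add_metabolite(
            Metabolite("ALDEHYDE", is_class=True, instance_ids=("ACALD", "PROAL"))
        )
        return m

    def test_class_oxidation_keeps_only_balanced_bindings(self):
        # 2x2 = 4 permutations; an exhaustive element-count oracle says
        # exactly the like-for-like pairings balance
        m = self._class_model()
        rxn = Reaction(
            "CLASS-OX",
            {
                "ALCOHOL[c]": -1,
                "NAD[c]": -1,
                "ALDEHYDE[c]": 1,
                "NADH[c]": 1,
                "PROTON[c]": 1,
            },
        )
        expected_balanced = 0
        for alc, ald in itertools.product(("ETOH", "PROH"), ("ACALD", "PROAL")):
            trial = Reaction(
                "T",
                {
                    f"{alc}[c]": -1,
                    "NAD[c]": -1,
                    f"{ald}[c]": 1,
                    "NADH[c]": 1,
                    "PROTON[c]": 1,
                },
            )
            if check_mass_balance(trial, m.metabolites).balanced:
                expected_balanced += 1
        assert expected_balanced == 2
        instances = instantiate_classes(rxn, m.metabolites)
        assert len(instances) == 2
        for inst in instances:
            assert check_mass_balance(inst, m.metabolites).balanced

    def test_reaction_without_classes_is_identity(self):
        m = self._class_model()
        rxn = Reaction("PLAIN", {"ETOH[c]": -1, "ACALD[c]": 1})
        assert instantiate_classes(rxn, m.metabolites) == [rxn]

    def test_permutation_cap_rejects(self):
        m = self._class_model()
        rxn = Reaction(
            "CLASS-OX",
            {"ALCOHOL[c]": -1, "NAD[c]": -1, "ALDEHYDE[c]": 1, "NADH[c]": 1,
             "PROTON[c]": 1},
        )
        model = ModelDefinition()
        model.metabolites = m.metabolites
        model.add_reaction(rxn)
        _, report = apply_filters(model, cap=3)
        assert report.exclusions == [("CLASS-OX", "permutation-cap")]

    def test_empty_instance_list_is_ambiguous(self):
        m = self._class_model()
        m.add_metabolite(Metabolite("EMPTYCLASS", is_class=True, instance_ids=()))
        model = ModelDefinition()
        model.metabolites = m.metabolites
        model.add_reaction(Reaction("R", {"EMPTYCLASS[c]": -1, "ETOH[c]": 1}))
        _, report = apply_filters(model)
        assert report.exclusions == [("R", "ambiguous-instantiation")]

    def test_no_balanced_binding_is_ambiguous(self):
        m = self._class_model()
        model = ModelDefinition()
        model.metabolites = m.metabolites
        # alcohol -> aldehyde without redox partner never balances
        model.add_reaction(Reaction("R", {"ALCOHOL[c]": -1, "ACALD[c]": 1}))
        _, report = apply_filters(model)
        assert report.exclusions == [("R", "ambiguous-instantiation")]

    def test_instances_carry_provenance(self):
        m = self._class_model()
        model = ModelDefinition()
        model.metabolites = m.metabolites
        model.add_reaction(
            Reaction(
                "CLASS-OX",
                {"ALCOHOL[c]": -1, "NAD[c]": -1, "ALDEHYDE[c]": 1, "NADH[c]": 1,
                 "PROTON[c]": 1},
            )
        )
        net = build_network(
            model,
            MetaboliteSet("n", (SetMember("ETOH[c]", coefficient=5.0),
                                SetMember("PROH[c]", coefficient=5.0))),
            MetaboliteSet("s", (SetMember("ACALD[c]"), SetMember("PROAL[c]"))),
        )
        sources = {net.provenance[rid][0] for rid in net.reactions if rid.startswith("CLASS-OX")}
        assert sources == {"CLASS-OX"}


class TestExchanges:
    def _net(self):
        m = _simple_model()
        m.add_metabolite(Metabolite("NH4", formula=parse_formula("H4N"), charge=1))
        m.add_metabolite(Metabolite("GLC", formula=parse_formula("C6H12O6"), charge=0,
                                    compartment="p"))
        m.add_reaction(Reaction("R1", {"A[c]": -1, "B[c]": 1}))
        return build_network(m)

    def test_cytosolic_nutrient_exchanges_into_cytosol(self, fermentation_aerobic):
        # ammonium is declared in the cytosol, so its uptake exchange
        # produces the cytosolic species directly (no periplasmic step)
        rxn = fermentation_aerobic.reactions["EX-NH4[c]"]
        assert rxn.stoichiometry == {"NH4[c]": Fraction(1)}
        assert fermentation_aerobic.exchanges["EX-NH4[c]"] == "nutrient"

    def test_nutrient_coefficient_sets_uptake_bound(self, core_problem):
        assert core_problem.bounds["EX-GLC[p]"] == (0.0, 10.0)
        # unconstrained nutrient gets the large default bound
        assert core_problem.bounds["EX-OXYGEN[p]"][1] == core_problem.default_bound

    def test_empty_secretion_set_creates_no_effluxes(self):
        net = self._net()
        out = attach_exchanges(
            net, MetaboliteSet("n", (SetMember("A[c]", coefficient=1.0),)),
            MetaboliteSet("s", ()),
        )
        assert not [r for r in out.reactions if r.startswith("SEC-")]

    def test_unknown_nutrient_warns_and_is_skipped(self):
        net = self._net()
        with pytest.warns(UserWarning, match="absent from network"):
            out = attach_exchanges(
                net,
                MetaboliteSet("n", (SetMember("UNOBTAINIUM[p]", coefficient=1.0),)),
                MetaboliteSet("s", ()),
            )
        assert "EX-UNOBTAINIUM[p]" not in out.reactions
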