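"""Two-stage FBA: biomass assembly, taxicab stage, protocols, scans."""

import numpy as np
import pytest

import fluxkit as fk
from fluxkit import fixtures as fx
from fluxkit.build import FluxNetwork
from fluxkit.core import Metabolite, MetaboliteSet, Reaction, SetMember, parse_formula
from fluxkit.engine import (
    BIOMASS_ID,
    BiomassObjective,
    CofactorIds,
    EngineConfig,
    assemble_biomass,
    chemostat_run,
    flux_sweep,
    reachability_scan,
    solve,
    steady_state_residual,
    sweep_table,
)


class TestBiomassAssembly:
    def test_maintenance_terms_enter_as_documented(self, fermentation_aerobic):
        bm = fx.fermentation_biomass(gam=53.95, ngam=3.15)
        net = assemble_biomass(fermentation_aerobic, bm)
        biomass = net.reactions[BIOMASS_ID]
        assert float(biomass.stoichiometry["ATP[c]"]) == pytest.approx(-53.95)
        assert float(biomass.stoichiometry["ADP[c]"]) == pytest.approx(53.95)
        assert net.bounds["ATPM"][0] == pytest.approx(3.15)

    def test_zero_gam_leaves_only_members(self, fermentation_aerobic):
        bm = BiomassObjective({"PYR[c]": 2.0}, gam=0.0, ngam=0.0)
        net = assemble_biomass(fermentation_aerobic, bm)
        assert set(net.reactions[BIOMASS_ID].stoichiometry) == {"PYR[c]"}

    def test_missing_member_is_hard_error(self, fermentation_aerobic):
        bm = BiomassObjective({"UNOBTAINIUM[c]": 1.0}, gam=0.0, ngam=0.0)
        with pytest.raises(KeyError, match="UNOBTAINIUM"):
            assemble_biomass(fermentation_aerobic, bm)

    def test_biomass_flux_drains_members_linearly(self):
        # two-member toy: at growth 0.5 with coefficients {X:2, Y:4} the
        # exchange fluxes must be 1.0 and 2.0 (linearity oracle)
        net = FluxNetwork()
        for base in ("X", "Y"):
            net.metabolites[f"{base}[c]"] = Metabolite(
                base, formula=parse_formula("CH2O"), charge=0
            )
        net.add_reaction(Reaction("EX-X[c]", {"X[c]": 1}), bounds=(0, 10), kind="nutrient")
        net.add_reaction(Reaction("EX-Y[c]", {"Y[c]": 1}), bounds=(0, 10), kind="nutrient")
        net = assemble_biomass(net, BiomassObjective({"X[c]": 2.0, "Y[c]": 4.0},
                                                     gam=0.0, ngam=0.0))
        net.set_bounds(BIOMASS_ID, 0.5, 0.5)
        sol = solve(net)
        assert sol.flux("EX-X[c]") == pytest.approx(2.0 * 0.5)
        assert sol.flux("EX-Y[c]") == pytest.approx(4.0 * 0.5)


class TestTwoStageSolve:
    def test_closed_network_has_zero_objective(self, core_problem):
        net = core_problem.copy()
        for rid, kind in net.exchanges.items():
            if kind == "nutrient":
                net.set_bounds(rid, 0.0, 0.0)
        sol = solve(net)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
        assert not sol.growth

    def test_taxicab_selects_shorter_route_at_equal_objective(self):
        # enumeration oracle: both routes move 10 units; route lengths 2
        # and 3 give taxicab norms 20 vs 30 (plus exchanges)
        net = fx.diamond_problem()
        sol = solve(net)
        assert sol.objective_value == pytest.approx(10.0)
        assert sol.flux("R1-A-TO-B") == pytest.approx(10.0)
        assert sol.flux("R3-A-TO-C") == pytest.approx(0.0)
        short = 2 * 10 + 2 * 10  # route + both exchanges
        assert float(sol.fluxes.abs().sum()) == pytest.approx(short)

    def test_taxicab_never_degrades_objective_or_increases_norm(self, core_problem):
        stage1 = solve(core_problem, EngineConfig(minimize_fluxes=False))
        stage2 = solve(core_problem, EngineConfig(minimize_fluxes=True))
        assert stage2.objective_value == pytest.approx(stage1.objective_value, rel=1e-8)
        assert stage2.fluxes.abs().sum() <= stage1.fluxes.abs().sum() + 1e-6

    def test_rescaling_changes_taxicab_vector_but_not_optimum(self):
        # scaling one route's stoichiometry makes it "cheaper" in flux
        # units: the stage-1 optimum is invariant, the flux vector is not
        model = fx.build_diamond_toy()
        scaled = {}
        for rid, rxn in model.reactions.items():
            if rid in ("R3-A-TO-C", "R4-C-TO-D", "R5-D-TO-T"):
                scaled[rid] = Reaction(rid, {k: 4 * v for k, v in rxn.stoichiometry.items()})
            else:
                scaled[rid] = rxn
        model.reactions = scaled
        from fluxkit.build import build_network

        net = build_network(
            model,
            MetaboliteSet("n", (SetMember("A[c]", coefficient=10.0),)),
            MetaboliteSet("s", (SetMember("T[c]"),)),
        )
        net.objective_id = "SEC-T[c]"
        sol = solve(net)
        assert sol.objective_value == pytest.approx(10.0)
        assert sol.flux("R3-A-TO-C") == pytest.approx(2.5)  # 4x stoichiometry
        assert sol.flux("R1-A-TO-B") == pytest.approx(0.0)

    def test_infeasible_status_is_propagated(self, fermentation_aerobic):
        net = assemble_biomass(fermentation_aerobic, fx.fermentation_biomass())
        net.set_bounds("EX-GLC[p]", 0.0, 0.0)  # NGAM floor with no carbon
        sol = solve(net, EngineConfig(minimize_fluxes=False))
        assert sol.status == "infeasible"

    def test_unbounded_status_is_propagated(self):
        net = FluxNetwork()
        net.metabolites["A[c]"] = Metabolite("A", formula=parse_formula("C"), charge=0)
        net.add_reaction(Reaction("IN", {"A[c]": 1}), bounds=(0, np.inf))
        net.add_reaction(Reaction("OUT", {"A[c]": -1}), bounds=(0, np.inf))
        net.objective_id = "OUT"
        sol = solve(net, EngineConfig(minimize_fluxes=False))
        assert sol.status == "unbounded"

    def test_every_optimum_satisfies_steady_state(self, core_problem, fermentation_anaerobic):
        for net in (core_problem, fermentation_anaerobic):
            sol = solve(net)
            assert steady_state_residual(net, sol) <= 1e-6

    def test_half_and_whole_oxygen_conventions_agree_on_exchanges(self):
        # converting the oxidase between half- and whole-O2 forms leaves
        # all exchange fluxes identical and only rescales that reaction
        whole = fx.core_energy_problem(fx.ECOCYC_CONVENTION)
        half = fx.core_energy_problem(
            fx.FixtureSpec("half", nadh_h_per_2e=4, oxidase_o2="half")
        )
        s_whole, s_half = solve(whole), solve(half)
        assert s_half.objective_value == pytest.approx(s_whole.objective_value)
        for rid, kind in whole.exchanges.items():
            assert s_half.flux(rid) == pytest.approx(s_whole.flux(rid), abs=1e-6)
        assert s_half.flux("CYTOCHROME-BO-OXIDASE-RXN") == pytest.approx(
            2 * s_whole.flux("CYTOCHROME-BO-OXIDASE-RXN")
        )

    def test_cobra_reproduces_stage1_optimum(self, core_problem):
        # independent oracle: the same LP through cobra's solver stack
        cobra_model = fk.fileio.network_to_cobra(core_problem)
        value = cobra_model.optimize().objective_value
        ours = solve(core_problem, EngineConfig(minimize_fluxes=False)).objective_value
        assert value == pytest.approx(ours, rel=1e-6)
        assert ours == pytest.approx(216.0)


class TestProtocols:
    def test_chemostat_fixes_uptake_and_maximizes_biomass(self, growth_network):
        sol = chemostat_run(growth_network, "EX-GLC[p]", 3.008)
        assert sol.status == "optimal"
        assert sol.flux("EX-GLC[p]") == pytest.approx(3.008)
        assert sol.mu is not None and sol.mu > 0

    def test_chemostat_without_carbon_gives_zero_growth(self, fermentation_aerobic):
        bm = fx.fermentation_biomass(ngam=0.0)
        net = assemble_biomass(fermentation_aerobic, bm)
        sol = chemostat_run(net, "EX-GLC[p]", 0.0)
        assert sol.mu == pytest.approx(0.0, abs=1e-9)

    def test_chemostat_growth_is_homogeneous_in_uptake(self, fermentation_aerobic):
        # LP homogeneity: with no other active bound and zero NGAM,
        # doubling the substrate supply doubles the growth rate
        bm = fx.fermentation_biomass(ngam=0.0)
        net = assemble_biomass(fermentation_aerobic, bm)
        mu1 = chemostat_run(net, "EX-GLC[p]", 5.0).mu
        mu2 = chemostat_run(net, "EX-GLC[p]", 10.0).mu
        assert mu2 == pytest.approx(2 * mu1, rel=1e-6)

    def test_unknown_substrate_is_error(self, growth_network):
        with pytest.raises(KeyError):
            chemostat_run(growth_network, "EX-NOPE[p]", 1.0)

    def test_single_point_sweep_equals_plain_solve(self, fermentation_anaerobic):
        [swept] = flux_sweep(fermentation_anaerobic, "EX-OXYGEN[p]", [0.0])
        plain = solve(fermentation_anaerobic)
        assert swept.objective_value == pytest.approx(plain.objective_value)
        assert np.allclose(swept.fluxes.to_numpy(), plain.fluxes.to_numpy(), atol=1e-6)

    def test_sweep_over_unused_exchange_keeps_objective_constant(self, core_problem):
        # re-solve sensitivity oracle: water uptake is never binding
        sols = flux_sweep(core_problem, "EX-WATER[p]", [0.0, 5.0, 10.0])
        values = {round(s.objective_value, 6) for s in sols}
        assert values == {216.0}

    def test_sweep_emits_tidy_table(self, fermentation_anaerobic):
        bounds = [0.0, 5.0]
        sols = flux_sweep(fermentation_anaerobic, "EX-OXYGEN[p]", bounds)
        table = sweep_table(bounds, sols, ["SEC-ETOH[p]", "SEC-ACET[p]"])
        assert list(table.columns) == ["bound", "reaction", "flux"]
        assert len(table) == 4

    def test_non_monotone_sweep_rejected(self, core_problem):
        with pytest.raises(ValueError):
            flux_sweep(core_problem, "EX-OXYGEN[p]", [0.0, 10.0, 5.0])


class TestReachability:
    def test_blocked_member_detected_and_flips_with_balance(self):
        from fluxkit.build import build_network

        nutrients = MetaboliteSet("n", (SetMember("N[c]", coefficient=10.0),))
        secretions = MetaboliteSet("s", (SetMember("A[c]"), SetMember("B[c]"),
                                         SetMember("H2X[c]")))
        bm = BiomassObjective({"A[c]": 1.0, "B[c]": 1.0}, gam=0.0, ngam=0.0)
        blocked_net = build_network(fx.build_blocked_biomass_toy(False), nutrients, secretions)
        report = reachability_scan(blocked_net, bm)
        by_member = report.set_index("member")["producible"]
        assert bool(by_member["A[c]"]) is True
        assert bool(by_member["B[c]"]) is False
        fixed_net = build_network(fx.build_blocked_biomass_toy(True), nutrients, secretions)
        report2 = reachability_scan(fixed_net, bm)
        assert bool(report2.set_index("member")["producible"]["B[c]"]) is True

    def test_all_fixture_members_producible_on_glucose(self, fermentation_aerobic, biomass):
        report = reachability_scan(fermentation_aerobic, biomass)
        assert report["producible"].all()

    def test_scan_does_not_mutate_network(self, fermentation_aerobic, biomass):
        before = dict(fermentation_aerobic.bounds)
        reachability_scan(fermentation_aerobic, biomass)
        assert fermentation_aerobic.bounds == before
        assert "DRAIN-PROBE" not in fermentation_aerobic.reactions
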