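"""Aerobic ATP yield on the core energy network, two conventions.

Builds the glucose -> ATP benchmark network, maximizes the ATP hydrolysis
reaction at a glucose uptake of 10 mmol/gCDW/hr, and prints the taxicab-
minimized fluxes through the electron transport chain under the two
NADH-dehydrogenase proton conventions (4 vs 3 H+ translocated per 2 e-).
The objective value is the maximal ATP turnover in mmol/gCDW/hr; with the
4 H+/2e- convention the network yields 21.6 ATP per glucose, with the
3 H+/2e- convention 23.5.
"""

from fluxkit import fixtures as fx
from fluxkit.engine import solve

for spec in (fx.ECOCYC_CONVENTION, fx.IJO_CONVENTION):
    network = fx.core_energy_problem(spec, glucose_bound=10.0)
    solution = solve(network)
    print(f"--- {spec.name} ({spec.nadh_h_per_2e} H+/2e-, {spec.oxidase_o2}-O2 oxidase)")
    print(f"max ATP turnover: {solution.objective_value:.1f} mmol/gCDW/hr")
    for rid in (
        "NADH-DEHYDROG-A-RXN",
        "ATP-SYNTHASE-RXN",
        "CYTOCHROME-BO-OXIDASE-RXN",
        "EX-OXYGEN[p]",
        "SEC-CO2[p]",
    ):
        print(f"  {rid:<28s} {solution.flux(rid):7.1f}")

derived = fx.derive_proton_stoichiometry()
print(
    "\nderived proton coefficients: oxidase"
    f" {derived.oxidase_h_per_o2} H+/O2, synthase {derived.synthase_h_per_atp}"
)
print("(the unique integral solution of the periplasmic proton balance)")
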