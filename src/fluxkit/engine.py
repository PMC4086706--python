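"""Two-stage flux balance analysis.

Stage 1 maximizes the objective reaction flux subject to the steady-state
constraint ``S v = 0`` and flux bounds.  Stage 2 (the taxicab stage,
parsimonious FBA) fixes the objective at its optimum and minimizes the sum
of absolute fluxes via the standard positive/negative flux splitting,
which removes degenerate alternate optima and thermodynamically absurd
loops from the reported flux vector.

Units follow the field's convention throughout: fluxes in mmol/gCDW/hr,
biomass coefficients in mmol/gCDW, so a biomass flux of 1.0 is a specific
growth rate of 1.0 per hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .build import FluxNetwork
from .core import MetaboliteSet, Reaction

__all__ = [
    "BiomassObjective",
    "EngineConfig",
    "FluxSolution",
    "CofactorIds",
    "assemble_biomass",
    "solve",
    "chemostat_run",
    "flux_sweep",
    "sweep_table",
    "reachability_scan",
    "BIOMASS_ID",
]

BIOMASS_ID = "BIOMASS"


@dataclass(frozen=True)
class CofactorIds:
    """Metabolite keys used for maintenance-ATP bookkeeping."""

    atp: str = "ATP[c]"
    adp: str = "ADP[c]"
    pi: str = "Pi[c]"
    water: str = "WATER[c]"
    proton: str = "PROTON[c]"


@dataclass(frozen=True)
class BiomassObjective:
    """Biomass demand: precursor coefficients plus maintenance ATP.

    ``gam`` (growth-associated maintenance, mmol ATP/gCDW) enters the
    biomass reaction as an ATP hydrolysis term scaled by growth; ``ngam``
    (mmol ATP/gCDW/hr) is a fixed flux floor on the ATP hydrolysis
    reaction.  Defaults are the standard E. coli values.
    """

    members: dict[str, float] = field(default_factory=dict)
    variant: str = "core"
    gam: float = 53.95
    ngam: float = 3.15

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.members.values()):
            raise ValueError("biomass coefficients must be positive")
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("maintenance terms must be non-negative")

    def without(self, keys: Iterable[str]) -> "BiomassObjective":
        drop = set(keys)
        return BiomassObjective(
            {k: v for k, v in self.members.items() if k not in drop},
            variant=self.variant,
            gam=self.gam,
            ngam=self.ngam,
        )


@dataclass(frozen=True)
class EngineConfig:
    epsilon: float = 1e-6  # growth threshold on the objective flux
    minimize_fluxes: bool = True
    tolerance: float = 1e-9
    objective_fix_rtol: float = 1e-8  # stage-2 objective fixing, relative

    def __post_init__(self) -> None:
        if self.epsilon <= self.tolerance:
            raise ValueError("growth threshold must exceed solver tolerance")


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: pd.Series
    growth: bool
    mu: float | None = None
    objective_id: str | None = None

    def flux(self, reaction_id: str) -> float:
        return float(self.fluxes.get(reaction_id, 0.0))

    def nonzero(self, tol: float = 1e-9) -> pd.Series:
        nz = self.fluxes[self.fluxes.abs() > tol]
        return nz.reindex(nz.abs().sort_values(ascending=False).index)


def assemble_biomass(
    network: FluxNetwork,
    objective: BiomassObjective,
    cofactors: CofactorIds = CofactorIds(),
    atpm_id: str = "ATPM",
) -> FluxNetwork:
    """Attach the biomass reaction and maintenance constraints.

    The biomass reaction drains each member at its coefficient and, when
    ``gam > 0``, hydrolyzes ``gam`` ATP per unit growth.  ``ngam`` becomes
    the lower flux bound of the ATP hydrolysis reaction ``atpm_id``.
    Missing members are a hard error (the reachability scan is the tool for
    diagnosing them, not silent dropping).
    """
    missing = [k for k in objective.members if k not in network.metabolites]
    if missing:
        raise KeyError(f"biomass members absent from network: {sorted(missing)}")
    net = network.copy()
    stoich: dict[str, Fraction] = {
        k: -Fraction(v).limit_denominator(10**9) for k, v in objective.members.items()
    }
    if objective.gam > 0:
        gam = Fraction(objective.gam).limit_denominator(10**9)
        for key, sign in (
            (cofactors.atp, -1),
            (cofactors.water, -1),
            (cofactors.adp, +1),
            (cofactors.pi, +1),
            (cofactors.proton, +1),
        ):
            if key not in net.metabolites:
                raise KeyError(f"maintenance cofactor {key} absent from network")
            stoich[key] = stoich.get(key, Fraction(0)) + sign * gam
    rxn = Reaction(BIOMASS_ID, stoich, spontaneous=True)
    if BIOMASS_ID in net.reactions:
        del net.reactions[BIOMASS_ID]
        del net.bounds[BIOMASS_ID]
        net.provenance.pop(BIOMASS_ID, None)
    net.add_reaction(rxn, bounds=(0.0, net.default_bound), kind="biomass")
    net.objective_id = BIOMASS_ID
    if objective.ngam > 0:
        if atpm_id not in net.reactions:
            raise KeyError(f"NGAM requires ATP hydrolysis reaction {atpm_id!r} in network")
        _, ub = net.bounds[atpm_id]
        net.set_bounds(atpm_id, objective.ngam, ub)
    return net


# ---------------------------------------------------------------------------
# LP assembly


_STATUS = {0: "optimal", 1: "iteration-limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _linprog(c, A_ub, b_ub, A_eq, b_eq, bounds):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    return res


def solve(
    network: FluxNetwork,
    config: EngineConfig = EngineConfig(),
    objective_id: str | None = None,
) -> FluxSolution:
    """Two-stage FBA solve of a network.

    Stage 1 maximizes the objective reaction flux; when
    ``config.minimize_fluxes`` is set, stage 2 fixes that optimum (within a
    relative tolerance) and minimizes the taxicab norm of the flux vector.
    The reported objective value is always the stage-1 optimum.  Infeasible
    and unbounded statuses are propagated, never coerced to no-growth.
    """
    obj = objective_id or network.objective_id
    if obj is None or obj not in network.reactions:
        raise KeyError(f"objective reaction {obj!r} not in network")
    S, met_ids, rxn_ids = network.stoichiometric_matrix()
    n = len(rxn_ids)
    j_obj = rxn_ids.index(obj)
    lb = np.array([network.bounds[r][0] for r in rxn_ids])
    ub = np.array([network.bounds[r][1] for r in rxn_ids])

    c = np.zeros(n)
    c[j_obj] = -1.0
    res = _linprog(c, None, None, S, np.zeros(S.shape[0]), list(zip(lb, ub)))
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        # -inf objective from an unbounded maximization
        empty = pd.Series(0.0, index=rxn_ids)
        return FluxSolution(status, float("nan"), empty, False, objective_id=obj)
    z_star = -res.fun
    fluxes = np.asarray(res.x)

    if config.minimize_fluxes:
        fluxes = _taxicab_stage(S, lb, ub, j_obj, z_star, config)
        if fluxes is None:  # numerically brittle corner: keep stage-1 vector
            fluxes = np.asarray(res.x)

    series = pd.Series(fluxes, index=rxn_ids)
    series[series.abs() < config.tolerance] = 0.0
    growth = z_star > config.epsilon
    mu = z_star if obj == BIOMASS_ID else None
    return FluxSolution("optimal", z_star, series, growth, mu=mu, objective_id=obj)


def _taxicab_stage(S, lb, ub, j_obj, z_star, config: EngineConfig):
    """Minimize sum |v| with the objective fixed near its stage-1 optimum."""
    n = S.shape[1]
    # v = p - q with p, q >= 0; preserve any strictly positive lower bounds
    p_lb = np.maximum(lb, 0.0)
    p_ub = np.maximum(ub, 0.0)
    q_lb = np.maximum(-ub, 0.0)
    q_ub = np.maximum(-lb, 0.0)
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(S.shape[0])
    row = np.zeros(2 * n)
    row[j_obj] = 1.0
    row[n + j_obj] = -1.0
    c = np.ones(2 * n)
    bounds = list(zip(np.concatenate([p_lb, q_lb]), np.concatenate([p_ub, q_ub])))
    # fix the objective exactly at its stage-1 optimum; if that proves
    # numerically infeasible, relax to >= z*(1 - rtol)
    res = _linprog(
        c, None, None, np.vstack([A_eq, row]), np.append(b_eq, z_star), bounds
    )
    if res.status != 0:
        slack = max(config.tolerance, config.objective_fix_rtol * abs(z_star))
        res = _linprog(
            c, -row[None, :], np.array([-(z_star - slack)]), A_eq, b_eq, bounds
        )
    if res.status != 0:
        return None
    x = np.asarray(res.x)
    return x[:n] - x[n:]


# ---------------------------------------------------------------------------
# protocols


def chemostat_run(
    network: FluxNetwork,
    substrate_exchange: str,
    uptake: float,
    config: EngineConfig = EngineConfig(),
) -> FluxSolution:
    """Substrate-limited chemostat protocol.

    The measured substrate supply rate is the only fixed constraint (an
    equality on its uptake exchange); all other exchanges keep their
    defaults, and biomass is maximized.  The solution's ``mu`` is the
    specific growth rate.
    """
    net = network.copy()
    if substrate_exchange not in net.reactions:
        raise KeyError(f"substrate exchange {substrate_exchange!r} not in network")
    if net.exchanges.get(substrate_exchange) != "nutrient":
        raise KeyError(f"{substrate_exchange!r} is not a nutrient exchange")
    net.set_bounds(substrate_exchange, uptake, uptake)
    return solve(net, config, objective_id=BIOMASS_ID)


def exchange_fluxes(network: FluxNetwork, solution: FluxSolution) -> pd.DataFrame:
    """Extracellular flux summary in the chemostat-table layout."""
    rows = []
    for rid, kind in sorted(network.exchanges.items()):
        if kind == "biomass":
            continue
        rows.append(
            {
                "exchange": rid,
                "kind": kind,
                "flux": solution.flux(rid),
            }
        )
    return pd.DataFrame(rows)


def flux_sweep(
    network: FluxNetwork,
    exchange_id: str,
    bounds: Sequence[float],
    config: EngineConfig = EngineConfig(),
    objective_id: str | None = None,
) -> list[FluxSolution]:
    """Solve once per upper bound of one exchange, all else constant.

    Per-point solver failures are recorded in the returned solutions (their
    status) without aborting the sweep.
    """
    if list(bounds) != sorted(bounds) and list(bounds) != sorted(bounds, reverse=True):
        raise ValueError("sweep bounds must be monotone")
    out = []
    for b in bounds:
        net = network.copy()
        net.set_bounds(exchange_id, 0.0, float(b))
        out.append(solve(net, config, objective_id=objective_id))
    return out


def sweep_table(
    bounds: Sequence[float], solutions: Sequence[FluxSolution], reactions: Sequence[str]
) -> pd.DataFrame:
    """Tidy long-format (bound, reaction, flux) table for plotting."""
    rows = []
    for b, sol in zip(bounds, solutions):
        for rid in reactions:
            rows.append({"bound": float(b), "reaction": rid, "flux": sol.flux(rid)})
    return pd.DataFrame(rows)


def reachability_scan(
    network: FluxNetwork,
    biomass: BiomassObjective,
    config: EngineConfig = EngineConfig(minimize_fluxes=False),
) -> pd.DataFrame:
    """Per-member producibility: maximize a temporary drain of each member.

    Mirrors the validation step of setting the production of each biomass
    metabolite in turn as the optimization goal.  The input network is
    never mutated.
    """
    rows = []
    for key in sorted(biomass.members):
        if key not in network.metabolites:
            rows.append({"member": key, "producible": False, "max_drain": 0.0, "note": "absent"})
            continue
        net = network.copy()
        drain_id = "DRAIN-PROBE"
        net.add_reaction(
            Reaction(drain_id, {key: Fraction(-1)}, spontaneous=True),
            bounds=(0.0, net.default_bound),
        )
        sol = solve(net, config, objective_id=drain_id)
        producible = sol.status == "optimal" and sol.objective_value > config.epsilon
        rows.append(
            {
                "member": key,
                "producible": bool(producible),
                "max_drain": sol.objective_value if sol.status == "optimal" else 0.0,
                "note": "" if sol.status == "optimal" else sol.status,
            }
        )
    return pd.DataFrame(rows)


def steady_state_residual(network: FluxNetwork, solution: FluxSolution) -> float:
    """Max |S v| over metabolites; every optimum should satisfy <= 1e-6."""
    S, _, rxn_ids = network.stoichiometric_matrix()
    v = solution.fluxes.reindex(rxn_ids).to_numpy()
    return float(np.max(np.abs(S @ v))) if len(rxn_ids) else 0.0
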