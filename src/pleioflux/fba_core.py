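"""Linear-programming core: FBA, parsimonious FBA, and wildtype flux caps.

Flux caps implement the wildtype-constraint rule: every flux is confined
between zero and its wildtype value,

    0 <= v_i <= v_i_WT   for v_i_WT >= 0
    0 >= v_i >= v_i_WT   for v_i_WT <  0

so that no reaction may run harder (or in the opposite direction) than it
does in the unperturbed optimum. Caps are always *intersected* with the
model's native bounds, never widened; a native lower bound such as a
maintenance-ATPase floor survives the intersection.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional

import cobra
import cobra.flux_analysis
import pandas as pd

from pleioflux.model_io import MetabolicModel, reactions_constrained_by_gene

__all__ = [
    "FluxCaps",
    "InfeasibleProblem",
    "UnboundedProblem",
    "fba",
    "pfba",
    "wildtype_caps",
    "restrict_gene",
    "set_caps",
]

#: reaction id -> (lower cap, upper cap), intersected with native bounds at solve time
FluxCaps = dict[str, tuple[float, float]]

ZERO_FLUX_TOL = 1e-9
PFBA_FIX_RTOL = 1e-9


class InfeasibleProblem(Exception):
    """The LP has an empty feasible region under the given caps."""


class UnboundedProblem(Exception):
    """The LP objective is unbounded in the requested direction."""


def set_caps(model: cobra.Model, caps: Optional[FluxCaps]) -> bool:
    """Intersect caps with native bounds in place (use inside a model context).

    Returns ``False`` when some intersection is empty, in which case the
    problem is infeasible without needing a solver call.
    """
    if not caps:
        return True
    feasible = True
    for rxn_id, (cap_lb, cap_ub) in caps.items():
        rxn = model.reactions.get_by_id(rxn_id)
        lb = max(rxn.lower_bound, cap_lb)
        ub = min(rxn.upper_bound, cap_ub)
        if lb > ub:
            feasible = False
            break
        rxn.bounds = (lb, ub)
    return feasible


def fba(
    mm: MetabolicModel,
    objective: str | None = None,
    direction: str = "max",
    caps: Optional[FluxCaps] = None,
) -> tuple[float, pd.Series]:
    """Solve max/min c.v subject to S.v = 0 and bounds intersected with caps.

    Returns the optimal objective value and the full flux vector.
    """
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    obj_id = objective or mm.biomass_reaction_id
    with mm.cobra_model as model:
        if not set_caps(model, caps):
            raise InfeasibleProblem(f"empty feasible region (objective {obj_id})")
        model.objective = obj_id
        model.objective_direction = direction
        try:
            solution = model.optimize()
        except cobra.exceptions.OptimizationError as exc:
            if "unbounded" in str(exc).lower():
                raise UnboundedProblem(
                    f"unbounded LP (objective {obj_id})"
                ) from exc
            raise InfeasibleProblem(
                f"no optimal solution (objective {obj_id}): {exc}"
            ) from exc
        if solution.status == "infeasible":
            raise InfeasibleProblem(f"infeasible LP (objective {obj_id})")
        if solution.status != "optimal":
            raise UnboundedProblem(
                f"solver status {solution.status!r} (objective {obj_id})"
            )
        return float(solution.objective_value), solution.fluxes


def pfba(mm: MetabolicModel, objective: str | None = None) -> pd.Series:
    """Parsimonious FBA: maximize the objective, then minimize total flux.

    Stage 1 maximizes the objective (biomass by default); stage 2 fixes it
    at the optimum (within a relative tolerance band) and minimizes the sum
    of absolute fluxes via nonnegative forward/reverse splitting. The
    returned flux vector attains the stage-1 optimum.
    """
    obj_id = objective or mm.biomass_reaction_id
    with mm.cobra_model as model:
        model.objective = obj_id
        model.objective_direction = "max"
        stage1 = model.slim_optimize(error_value=None)
        solution = cobra.flux_analysis.pfba(model, objective=obj_id)
    achieved = float(solution.fluxes[obj_id])
    if not math.isclose(achieved, stage1, rel_tol=1e-6, abs_tol=1e-6):
        raise InfeasibleProblem(
            f"pFBA stage 2 lost the stage-1 optimum for {obj_id}: "
            f"{achieved} vs {stage1}"
        )
    return solution.fluxes


def wildtype_caps(wt: Mapping[str, float], zero_tol: float = ZERO_FLUX_TOL) -> FluxCaps:
    """Sign-respecting caps from a wildtype flux vector.

    Fluxes within ``zero_tol`` of zero are capped to exactly zero so that
    numerically silent reactions stay off.
    """
    caps: FluxCaps = {}
    for rxn_id, v in wt.items():
        v = float(v)
        if v >= zero_tol:
            caps[rxn_id] = (0.0, v)
        elif v <= -zero_tol:
            caps[rxn_id] = (v, 0.0)
        else:
            caps[rxn_id] = (0.0, 0.0)
    return caps


def restrict_gene(
    caps: FluxCaps,
    mm: MetabolicModel,
    gene_id: str,
    fraction: float,
    wt: Mapping[str, float],
) -> FluxCaps:
    """Cap all reactions the gene constrains at ``fraction`` of wildtype flux.

    Models a partial-loss-of-function allele: for each reaction whose GPR is
    boolean-essential on the gene, the magnitude cap becomes
    ``fraction * |v_WT|`` with the wildtype sign. Other caps are untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    constrained = reactions_constrained_by_gene(mm, gene_id)
    new_caps = dict(caps)
    for rxn_id in constrained:
        v = float(wt.get(rxn_id, 0.0))
        if abs(v) < ZERO_FLUX_TOL:
            new_caps[rxn_id] = (0.0, 0.0)
        elif v > 0:
            new_caps[rxn_id] = (0.0, fraction * v)
        else:
            new_caps[rxn_id] = (fraction * v, 0.0)
    return new_caps
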