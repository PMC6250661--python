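"""Brute-force LP oracle used for cross-checks and synthetic ground truth.

Everything here is deliberately independent of the production code path:
linear programs are built as dense matrices and solved with
:func:`scipy.optimize.linprog` (HiGHS), GPR rules are evaluated by walking
the parsed boolean expression with the :mod:`ast` module, and every
component maximum rebuilds its LP from scratch with no shared incremental
state. It is only meant for small networks.
"""

from __future__ import annotations

import ast
import math
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from pleioflux.model_io import MetabolicModel

__all__ = [
    "oracle_fba",
    "oracle_pfba",
    "oracle_component_maxima",
    "oracle_allele_pleiotropy",
    "oracle_sweep_counts",
    "oracle_essentiality_count",
    "gpr_blocked",
    "genes_constraining",
]

_THRESHOLD = 1e-4
_FLOOR = 1e-9


# ---------------------------------------------------------------------------
# GPR truth-table evaluation (independent of cobra's GPR machinery)
# ---------------------------------------------------------------------------

def _eval_bool(node: ast.expr, assignment: Mapping[str, bool]) -> bool:
    if isinstance(node, ast.BoolOp):
        vals = (_eval_bool(v, assignment) for v in node.values)
        return all(vals) if isinstance(node.op, ast.And) else any(vals)
    if isinstance(node, ast.Name):
        return assignment[node.id]
    raise ValueError(f"unsupported GPR syntax node: {ast.dump(node)}")


def eval_gpr(rule: str, assignment: Mapping[str, bool]) -> bool:
    """Evaluate a GPR string under an explicit truth assignment."""
    tree = ast.parse(rule, mode="eval")
    return _eval_bool(tree.body, assignment)


def gpr_blocked(rule: str, gene: str) -> bool:
    """Gene off, everything else on: does the GPR fail?"""
    if not rule.strip():
        return False
    names = {
        n.id for n in ast.walk(ast.parse(rule, mode="eval"))
        if isinstance(n, ast.Name)
    }
    assignment = {name: name != gene for name in names}
    return not eval_gpr(rule, assignment)


def genes_constraining(mm: MetabolicModel, rxn_id: str) -> set[str]:
    rule = mm.reactions.get_by_id(rxn_id).gene_reaction_rule
    if not rule.strip():
        return set()
    names = {
        n.id for n in ast.walk(ast.parse(rule, mode="eval"))
        if isinstance(n, ast.Name)
    }
    return {g for g in names if gpr_blocked(rule, g)}


# ---------------------------------------------------------------------------
# Dense LP construction
# ---------------------------------------------------------------------------

def _dense_problem(mm: MetabolicModel):
    model = mm.cobra_model
    met_index = {met.id: i for i, met in enumerate(model.metabolites)}
    rxn_ids = [rxn.id for rxn in model.reactions]
    S = np.zeros((len(met_index), len(rxn_ids)))
    lb = np.zeros(len(rxn_ids))
    ub = np.zeros(len(rxn_ids))
    for j, rxn in enumerate(model.reactions):
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        for met, coeff in rxn.metabolites.items():
            S[met_index[met.id], j] = coeff
    return S, rxn_ids, met_index, lb, ub


def _apply_caps(
    rxn_ids: Sequence[str], lb: np.ndarray, ub: np.ndarray,
    caps: Optional[Mapping[str, tuple[float, float]]],
) -> bool:
    if not caps:
        return True
    index = {r: j for j, r in enumerate(rxn_ids)}
    for rxn_id, (clb, cub) in caps.items():
        j = index[rxn_id]
        lb[j] = max(lb[j], clb)
        ub[j] = min(ub[j], cub)
        if lb[j] > ub[j]:
            return False
    return True


def _solve_max(S, lb, ub, obj_col) -> Optional[float]:
    """Maximize one variable; None if infeasible."""
    c = np.zeros(S.shape[1])
    c[obj_col] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    if not res.success:
        return None
    return float(-res.fun)


def oracle_fba(
    mm: MetabolicModel,
    objective: Optional[str] = None,
    caps: Optional[Mapping[str, tuple[float, float]]] = None,
) -> Optional[float]:
    """Max objective flux; None when infeasible."""
    S, rxn_ids, _, lb, ub = _dense_problem(mm)
    if not _apply_caps(rxn_ids, lb, ub, caps):
        return None
    return _solve_max(S, lb, ub, rxn_ids.index(objective or mm.biomass_reaction_id))


def oracle_pfba(mm: MetabolicModel, objective: Optional[str] = None) -> dict[str, float]:
    """Two-stage parsimonious FBA via forward/reverse flux splitting."""
    S, rxn_ids, _, lb, ub = _dense_problem(mm)
    obj_col = rxn_ids.index(objective or mm.biomass_reaction_id)
    opt = _solve_max(S, lb, ub, obj_col)
    if opt is None:
        raise RuntimeError("oracle pFBA: stage 1 infeasible")
    lb2, ub2 = lb.copy(), ub.copy()
    lb2[obj_col] = ub2[obj_col] = opt
    n = len(rxn_ids)
    # v = f - r with f, r >= 0
    A_eq = np.hstack([S, -S])
    f_bounds = [(max(l, 0.0), max(u, 0.0)) for l, u in zip(lb2, ub2)]
    r_bounds = [(max(-u, 0.0), max(-l, 0.0)) for l, u in zip(lb2, ub2)]
    c = np.ones(2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(S.shape[0]),
                  bounds=f_bounds + r_bounds, method="highs")
    if not res.success:
        raise RuntimeError("oracle pFBA: stage 2 infeasible")
    v = res.x[:n] - res.x[n:]
    return {r: float(v[j]) for j, r in enumerate(rxn_ids)}


def _wildtype_caps(wt: Mapping[str, float]) -> dict[str, tuple[float, float]]:
    caps = {}
    for rxn_id, v in wt.items():
        if v >= _FLOOR:
            caps[rxn_id] = (0.0, float(v))
        elif v <= -_FLOOR:
            caps[rxn_id] = (float(v), 0.0)
        else:
            caps[rxn_id] = (0.0, 0.0)
    return caps


def _restricted_caps(
    mm: MetabolicModel,
    base: Mapping[str, tuple[float, float]],
    gene: str,
    fraction: float,
    wt: Mapping[str, float],
) -> dict[str, tuple[float, float]]:
    caps = dict(base)
    for rxn in mm.reactions:
        if gpr_blocked(rxn.gene_reaction_rule, gene):
            v = float(wt.get(rxn.id, 0.0))
            if abs(v) < _FLOOR:
                caps[rxn.id] = (0.0, 0.0)
            elif v > 0:
                caps[rxn.id] = (0.0, fraction * v)
            else:
                caps[rxn.id] = (fraction * v, 0.0)
    return caps


def oracle_component_maxima(
    mm: MetabolicModel,
    components: Sequence[str],
    caps: Optional[Mapping[str, tuple[float, float]]] = None,
) -> dict[str, float]:
    """Per-component production maxima, one scratch-built LP each.

    Every LP carries one fresh secretion column per biomass component
    (flux >= 0, unbounded), so non-focal components are freely excretable.
    An infeasible problem scores as zero production.
    """
    maxima: dict[str, float] = {}
    for focal in components:
        S, rxn_ids, met_index, lb, ub = _dense_problem(mm)
        if not _apply_caps(rxn_ids, lb, ub, caps):
            maxima[focal] = 0.0
            continue
        n_extra = len(components)
        S_ext = np.hstack([S, np.zeros((S.shape[0], n_extra))])
        lb_ext = np.concatenate([lb, np.zeros(n_extra)])
        ub_ext = np.concatenate([ub, np.full(n_extra, np.inf)])
        for j, comp in enumerate(components):
            S_ext[met_index[comp], S.shape[1] + j] = -1.0
        col = S.shape[1] + list(components).index(focal)
        value = _solve_max(S_ext, lb_ext, ub_ext, col)
        maxima[focal] = 0.0 if value is None else value
    return maxima


def _count_reduced(
    baseline: Mapping[str, float], mutant: Mapping[str, float],
    threshold: float = _THRESHOLD,
) -> int:
    count = 0
    for comp, base in baseline.items():
        if base <= _FLOOR:
            continue
        if (base - mutant[comp]) > max(threshold * base, _FLOOR):
            count += 1
    return count


def oracle_allele_pleiotropy(
    mm: MetabolicModel,
    components: Sequence[str],
    gene: str,
    fraction: float,
    wt: Optional[Mapping[str, float]] = None,
    threshold: float = _THRESHOLD,
) -> int:
    """Pleiotropy of one allele under wildtype caps, fully recomputed."""
    wt = wt if wt is not None else oracle_pfba(mm)
    base_caps = _wildtype_caps(wt)
    baseline = oracle_component_maxima(mm, components, base_caps)
    caps = _restricted_caps(mm, base_caps, gene, fraction, wt)
    mutant = oracle_component_maxima(mm, components, caps)
    return _count_reduced(baseline, mutant, threshold)


def oracle_sweep_counts(
    mm: MetabolicModel,
    components: Sequence[str],
    gene: str,
    fractions: Sequence[float],
    wt: Optional[Mapping[str, float]] = None,
) -> tuple[np.ndarray, int]:
    """Allele pleiotropy at each fraction plus the strict-increase step count."""
    wt = wt if wt is not None else oracle_pfba(mm)
    counts = np.array(
        [oracle_allele_pleiotropy(mm, components, gene, float(f), wt)
         for f in fractions],
        dtype=int,
    )
    steps = int(np.sum(np.diff(counts) > 0))
    return counts, steps


def oracle_essentiality_count(
    mm: MetabolicModel,
    components: Sequence[str],
    gene: str,
    fraction: float,
    wt: Optional[Mapping[str, float]] = None,
    threshold: float = _THRESHOLD,
) -> int:
    """Essentiality count: free flux redistribution, gene capacity capped.

    Baseline is the fraction-1.0 allele (native bounds, gene at 100% of its
    wildtype capacity), mirroring the production counting rule.
    """
    wt = wt if wt is not None else oracle_pfba(mm)
    base_caps = _restricted_caps(mm, {}, gene, 1.0, wt)
    baseline = oracle_component_maxima(mm, components, base_caps)
    if fraction >= 1.0:
        return 0
    caps = _restricted_caps(mm, {}, gene, fraction, wt)
    mutant = oracle_component_maxima(mm, components, caps)
    return _count_reduced(baseline, mutant, threshold)
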