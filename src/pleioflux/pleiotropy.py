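"""The core pleiotropy procedure.

Pipeline per model:

1. Estimate the wildtype flux distribution with parsimonious FBA and derive
   sign-respecting flux caps from it.
2. Add one secretion (demand) exchange per biomass component, and record the
   maximal production rate of each component under the wildtype caps, with
   free excretion of all other components.
3. Simulate alleles of a gene by capping flux through all reactions the gene
   constrains at a fraction of wildtype flux (1.00 down to 0.00), and count
   the biomass components whose maximal production drops by at least 0.01%
   relative to the wildtype maximum. That count is the allele's pleiotropy.

Essentiality is the analogous count when fluxes may redistribute freely
(native bounds instead of wildtype caps); it reflects what remains
impossible after the mutant has adapted its expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import cobra
import numpy as np
import pandas as pd

from pleioflux.fba_core import (
    FluxCaps,
    pfba,
    restrict_gene,
    set_caps,
    wildtype_caps,
)
from pleioflux.model_io import MetabolicModel, reactions_constrained_by_gene

__all__ = [
    "REDUCTION_THRESHOLD",
    "PRODUCTION_FLOOR",
    "default_fraction_grid",
    "WildtypeReference",
    "PleiotropyProfile",
    "EssentialityProfile",
    "build_reference",
    "allele_pleiotropy",
    "sweep_gene",
    "essentiality_count",
    "essentiality_profile",
    "reaction_pleiotropy",
    "type2_share",
    "aggregate_type2",
    "classify_genes",
]

#: relative production drop that counts as "affected" (0.01%)
REDUCTION_THRESHOLD = 1e-4
#: absolute floor below which a production maximum is treated as zero
PRODUCTION_FLOOR = 1e-9


def default_fraction_grid(step: float = 0.005) -> np.ndarray:
    """Capacity fractions from 100% down to 0% in steps of ``step``."""
    n = round(1.0 / step)
    if not math.isclose(n * step, 1.0, rel_tol=1e-9):
        raise ValueError(f"grid step {step} does not divide 1 evenly")
    return np.round(np.linspace(1.0, 0.0, n + 1), 12)


@dataclass
class WildtypeReference:
    """Wildtype flux distribution, caps, and per-component production maxima.

    ``model`` carries one added demand exchange per biomass component
    (``demand_ids``), each with bounds [0, inf) so every other component may
    be excreted freely while one is maximized.
    """

    model: MetabolicModel
    components: dict[str, float]
    wt_fluxes: pd.Series
    caps: FluxCaps
    component_max: dict[str, float]
    biomass_max: float
    demand_ids: dict[str, str]
    threshold: float = REDUCTION_THRESHOLD
    floor: float = PRODUCTION_FLOOR
    _essentiality_baselines: dict[str, dict[str, float]] = field(
        default_factory=dict, repr=False
    )

    def producible_components(self) -> list[str]:
        """Components with a nonzero wildtype production maximum.

        A component whose wildtype maximum is already zero can never
        register a reduction and is recorded but never counted.
        """
        return [c for c, v in self.component_max.items() if v > self.floor]


@dataclass
class PleiotropyProfile:
    """Per-gene pleiotropy along the capacity-fraction grid."""

    gene: str
    fractions: np.ndarray
    counts: np.ndarray
    affected: list[frozenset[str]]
    steps: int
    knockout_pleiotropy: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene,
                "fraction": self.fractions,
                "count": self.counts,
                "components": [";".join(sorted(s)) for s in self.affected],
            }
        )


@dataclass
class EssentialityProfile:
    """Per-gene essentiality counts along the capacity-fraction grid."""

    gene: str
    fractions: np.ndarray
    counts: np.ndarray


def _count_steps(counts: Sequence[int]) -> int:
    """Strict increases between adjacent grid points, high to low fraction."""
    counts = np.asarray(counts)
    return int(np.sum(np.diff(counts) > 0))


def _component_maxima(
    ref: WildtypeReference,
    caps: Optional[FluxCaps],
    components: Optional[Iterable[str]] = None,
) -> dict[str, float]:
    """Maximal production of each component under the given caps.

    One LP per component, all inside a single model context. An infeasible
    problem (e.g. a maintenance floor conflicting with a knockout cap) is
    scored as zero production.
    """
    comps = list(components) if components is not None else list(ref.components)
    model = ref.model.cobra_model
    with model:
        if not set_caps(model, caps):
            return {c: 0.0 for c in comps}
        maxima: dict[str, float] = {}
        for comp in comps:
            model.objective = ref.demand_ids[comp]
            model.objective_direction = "max"
            value = model.slim_optimize(error_value=float("nan"))
            maxima[comp] = 0.0 if math.isnan(value) else float(value)
    return maxima


def build_reference(
    mm: MetabolicModel,
    components: Mapping[str, float],
    threshold: float = REDUCTION_THRESHOLD,
) -> WildtypeReference:
    """Wildtype pFBA, flux caps, and capped per-component production maxima.

    The input model is copied; the copy gains one demand exchange per
    component (flux >= 0, unbounded above). Caps cover only the original
    reactions, so excretion of non-focal components stays free.
    """
    wt = pfba(mm)
    caps = wildtype_caps(wt)
    biomass_max = float(wt[mm.biomass_reaction_id])

    work = mm.copy()
    model = work.cobra_model
    demand_ids: dict[str, str] = {}
    new_reactions = []
    for comp in components:
        met = model.metabolites.get_by_id(comp)
        rxn_id = f"DM_{comp}"
        while rxn_id in model.reactions:
            rxn_id += "_"
        rxn = cobra.Reaction(rxn_id, lower_bound=0.0, upper_bound=float("inf"))
        rxn.add_metabolites({met: -1.0})
        new_reactions.append(rxn)
        demand_ids[comp] = rxn_id
    model.add_reactions(new_reactions)

    ref = WildtypeReference(
        model=work,
        components=dict(components),
        wt_fluxes=wt,
        caps=caps,
        component_max={},
        biomass_max=biomass_max,
        demand_ids=demand_ids,
        threshold=threshold,
    )
    ref.component_max = _component_maxima(ref, caps)
    return ref


def _reduced(ref: WildtypeReference, baseline: float, mutant: float) -> bool:
    """The 0.01% rule: mutant production fell below (1 - threshold) * baseline."""
    if baseline <= ref.floor:
        return False
    return (baseline - mutant) > max(ref.threshold * baseline, ref.floor)


def _affected_under_caps(
    ref: WildtypeReference, caps: FluxCaps
) -> frozenset[str]:
    comps = ref.producible_components()
    maxima = _component_maxima(ref, caps, comps)
    return frozenset(
        c for c in comps if _reduced(ref, ref.component_max[c], maxima[c])
    )


def allele_pleiotropy(
    ref: WildtypeReference, gene_id: str, fraction: float
) -> tuple[int, frozenset[str]]:
    """Pleiotropy of one allele: count and identity of affected components.

    A component counts as affected when its maximal production under the
    gene-restricted wildtype caps falls at least 0.01% below its wildtype
    maximum. Components with wildtype maximum zero never count.
    """
    constrained = reactions_constrained_by_gene(ref.model, gene_id)
    if fraction >= 1.0 or not any(
        abs(float(ref.wt_fluxes.get(r, 0.0))) > ref.floor for r in constrained
    ):
        # caps cannot change: either the allele is wildtype or the gene's
        # reactions carry no wildtype flux
        return 0, frozenset()
    caps = restrict_gene(ref.caps, ref.model, gene_id, fraction, ref.wt_fluxes)
    affected = _affected_under_caps(ref, caps)
    return len(affected), affected


def sweep_gene(
    ref: WildtypeReference,
    gene_id: str,
    grid: Optional[np.ndarray] = None,
) -> PleiotropyProfile:
    """Evaluate allele pleiotropy over the full capacity-fraction grid.

    The step count is the number of grid transitions where pleiotropy
    strictly increases while the fraction decreases; plateaus contribute
    nothing. Each grid point is an independent set of LPs.
    """
    fractions = default_fraction_grid() if grid is None else np.asarray(grid, float)
    counts = np.zeros(len(fractions), dtype=int)
    affected: list[frozenset[str]] = []
    for i, f in enumerate(fractions):
        n, comps = allele_pleiotropy(ref, gene_id, float(f))
        counts[i] = n
        affected.append(comps)
    return PleiotropyProfile(
        gene=gene_id,
        fractions=fractions,
        counts=counts,
        affected=affected,
        steps=_count_steps(counts),
        knockout_pleiotropy=int(counts[-1]),
    )


def _essentiality_baseline(ref: WildtypeReference, gene_id: str) -> dict[str, float]:
    """Per-component maxima with native bounds and the gene at 100% capacity.

    The baseline for essentiality is the fraction-1.0 member of the same
    allele family: fluxes redistribute freely, but the gene's reactions stay
    within their wildtype capacity. This makes the unmutated allele compare
    equal to its own baseline by construction.
    """
    if gene_id not in ref._essentiality_baselines:
        caps = restrict_gene({}, ref.model, gene_id, 1.0, ref.wt_fluxes)
        ref._essentiality_baselines[gene_id] = _component_maxima(ref, caps)
    return ref._essentiality_baselines[gene_id]


def essentiality_count(
    ref: WildtypeReference, gene_id: str, fraction: float
) -> int:
    """Components whose *unconstrained* maximal production the allele reduces.

    Unlike pleiotropy, all other fluxes may redistribute freely (native
    bounds); only the gene's reactions are capped at ``fraction`` of their
    wildtype capacity. Uses the same 0.01% counting rule.
    """
    baseline = _essentiality_baseline(ref, gene_id)
    if fraction >= 1.0:
        return 0
    caps = restrict_gene({}, ref.model, gene_id, fraction, ref.wt_fluxes)
    comps = [c for c in ref.components if baseline[c] > ref.floor]
    maxima = _component_maxima(ref, caps, comps)
    return sum(1 for c in comps if _reduced(ref, baseline[c], maxima[c]))


def essentiality_profile(
    ref: WildtypeReference,
    gene_id: str,
    grid: Optional[np.ndarray] = None,
) -> EssentialityProfile:
    fractions = default_fraction_grid() if grid is None else np.asarray(grid, float)
    counts = np.array(
        [essentiality_count(ref, gene_id, float(f)) for f in fractions], dtype=int
    )
    return EssentialityProfile(gene=gene_id, fractions=fractions, counts=counts)


def reaction_pleiotropy(ref: WildtypeReference, reaction_id: str) -> int:
    """Pleiotropy of blocking one reaction, all others at wildtype caps."""
    if reaction_id not in ref.model.reactions:
        raise KeyError(f"reaction {reaction_id!r} not in model")
    caps = dict(ref.caps)
    caps[reaction_id] = (0.0, 0.0)
    return len(_affected_under_caps(ref, caps))


def type2_share(ref: WildtypeReference, gene_id: str) -> Optional[float]:
    """Fraction of a gene's knockout pleiotropy reproduced by its worst single reaction.

    Defined for genes constraining at least two reactions with nonzero
    knockout pleiotropy; returns ``None`` otherwise. A value near 1 means
    the gene's pleiotropy stems from one molecular function's network
    consequences (type II) rather than from multiple functions (type I).
    """
    constrained = sorted(reactions_constrained_by_gene(ref.model, gene_id))
    if len(constrained) < 2:
        return None
    gene_p, _ = allele_pleiotropy(ref, gene_id, 0.0)
    if gene_p == 0:
        return None
    best = max(reaction_pleiotropy(ref, r) for r in constrained)
    return best / gene_p


def aggregate_type2(
    ref: WildtypeReference, genes: Optional[Iterable[str]] = None
) -> tuple[Optional[float], Optional[float], dict[str, float]]:
    """Mean-of-ratios and ratio-of-sums over qualifying multi-reaction genes."""
    gene_ids = list(genes) if genes is not None else [g.id for g in ref.model.genes]
    ratios: dict[str, float] = {}
    best_sum = 0.0
    gene_sum = 0.0
    for g in gene_ids:
        constrained = sorted(reactions_constrained_by_gene(ref.model, g))
        if len(constrained) < 2:
            continue
        gene_p, _ = allele_pleiotropy(ref, g, 0.0)
        if gene_p == 0:
            continue
        best = max(reaction_pleiotropy(ref, r) for r in constrained)
        ratios[g] = best / gene_p
        best_sum += best
        gene_sum += gene_p
    if not ratios:
        return None, None, {}
    mean_of_ratios = float(np.mean(list(ratios.values())))
    ratio_of_sums = best_sum / gene_sum
    return mean_of_ratios, ratio_of_sums, ratios


def classify_genes(
    ref: WildtypeReference, genes: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Partition genes by fitness contribution and knockout pleiotropy class.

    A gene contributes to fitness iff its full knockout under wildtype caps
    reduces the maximal biomass production by at least 0.01%. Within those,
    classes follow the knockout pleiotropy: 0 components (biomass reduced
    through no single component, e.g. certain transporters), exactly 1,
    2 or more, or all components.
    """
    gene_ids = list(genes) if genes is not None else sorted(g.id for g in ref.model.genes)
    n_components = len(ref.components)
    model = ref.model.cobra_model
    rows = []
    for g in gene_ids:
        caps = restrict_gene(ref.caps, ref.model, g, 0.0, ref.wt_fluxes)
        with model:
            if set_caps(model, caps):
                model.objective = ref.model.biomass_reaction_id
                model.objective_direction = "max"
                value = model.slim_optimize(error_value=float("nan"))
                ko_biomass = 0.0 if math.isnan(value) else float(value)
            else:
                ko_biomass = 0.0
        contributes = _reduced(ref, ref.biomass_max, ko_biomass)
        if not contributes:
            rows.append((g, False, 0, "no-effect"))
            continue
        count, _ = allele_pleiotropy(ref, g, 0.0)
        if count == 0:
            label = "biomass-only"
        elif count == 1:
            label = "one-component"
        elif count == n_components:
            label = "all-components"
        else:
            label = "multi-component"
        rows.append((g, True, count, label))
    return pd.DataFrame(
        rows, columns=["gene", "fitness_contributing", "ko_pleiotropy", "class"]
    ).set_index("gene")
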