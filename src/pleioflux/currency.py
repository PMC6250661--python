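"""Currency-metabolite analysis.

Currency metabolites (ATP, NAD(P)H, FADH2, acyl-CoA, ...) couple otherwise
unrelated pathways by supplying energy, redox equivalents or activated
groups. To quantify how much pleiotropy they mediate, a cofactor is made
freely available by adding a balanced, reversible, unbounded reaction that
interconverts its charged and discharged forms, e.g.

    NADPH <=> NADP+ + H+ + 2 e-

where the electrons are carried by a boundary pseudo-species with its own
free exchange. The whole pleiotropy pipeline is then rerun from scratch on
the modified model and compared gene by gene against the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import cobra
import yaml

from pleioflux.model_io import MetabolicModel
from pleioflux.pleiotropy import (
    REDUCTION_THRESHOLD,
    WildtypeReference,
    allele_pleiotropy,
    build_reference,
    essentiality_count,
)

__all__ = [
    "CurrencyMetabolite",
    "load_currency_list",
    "add_free_cofactor",
    "add_free_cofactors",
    "count_currency_reactions",
    "ReductionResult",
    "reduction_analysis",
]

_UNBOUNDED = float("inf")


@dataclass(frozen=True)
class CurrencyMetabolite:
    """One cofactor pair plus the species that balance its interconversion.

    ``charged``/``discharged`` are species ids, either exact model ids or
    base ids to which compartment suffixes (``_c`` style) are appended.
    ``balancing`` lists (species id, stoichiometry) produced on the
    discharged side; entries in ``pseudo`` do not exist in the model and are
    created as freely exchangeable bookkeeping species (protons donated to
    an external pool, electron carriers, transferred phosphoryl or acyl
    groups).
    """

    name: str
    charged: str
    discharged: str
    balancing: tuple[tuple[str, float], ...] = ()
    pseudo: tuple[str, ...] = ()

    @property
    def species_ids(self) -> tuple[str, str]:
        return (self.charged, self.discharged)


def load_currency_list(path: str | Path) -> list[CurrencyMetabolite]:
    """Read a currency-metabolite list from YAML.

    Expected structure per entry: ``name``, ``charged``, ``discharged``,
    optional ``balancing`` mapping species id -> stoichiometry, optional
    ``pseudo`` list of the balancing ids that are bookkeeping species.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    entries = []
    for item in raw:
        balancing = tuple(sorted((item.get("balancing") or {}).items()))
        entries.append(
            CurrencyMetabolite(
                name=item["name"],
                charged=item["charged"],
                discharged=item["discharged"],
                balancing=balancing,
                pseudo=tuple(item.get("pseudo") or ()),
            )
        )
    return entries


def _resolve_pairs(
    model: cobra.Model, cm: CurrencyMetabolite
) -> list[tuple[str, str, str]]:
    """(charged id, discharged id, compartment) in every compartment with both."""
    mets = model.metabolites
    pairs = []
    if cm.charged in mets and cm.discharged in mets:
        comp = mets.get_by_id(cm.charged).compartment or ""
        pairs.append((cm.charged, cm.discharged, comp))
        return pairs
    tried = []
    for comp in sorted(model.compartments):
        cid, did = f"{cm.charged}_{comp}", f"{cm.discharged}_{comp}"
        tried.append(cid)
        if cid in mets and did in mets:
            pairs.append((cid, did, comp))
    if not pairs:
        raise KeyError(
            f"currency metabolite {cm.name!r}: no compartment holds both "
            f"{cm.charged!r} and {cm.discharged!r} (tried {tried})"
        )
    return pairs


def add_free_cofactor(mm: MetabolicModel, cm: CurrencyMetabolite) -> MetabolicModel:
    """Return a copy of the model in which the cofactor is freely available.

    One reversible, unbounded interconversion reaction is added per
    compartment where both species exist. Balancing pseudo-species are
    created once, with a free boundary exchange each, so the displayed
    half-reaction stays balanced without touching real metabolite pools.
    """
    work = mm.copy()
    model = work.cobra_model
    pairs = _resolve_pairs(model, cm)

    new_rxns: list[cobra.Reaction] = []
    pseudo_mets: dict[str, cobra.Metabolite] = {}
    for pseudo_id in cm.pseudo:
        if pseudo_id in model.metabolites:
            pseudo_mets[pseudo_id] = model.metabolites.get_by_id(pseudo_id)
            continue
        met = cobra.Metabolite(pseudo_id, name=pseudo_id, compartment="pool")
        pseudo_mets[pseudo_id] = met
        ex = cobra.Reaction(
            f"EX_{pseudo_id}", lower_bound=-_UNBOUNDED, upper_bound=_UNBOUNDED
        )
        ex.add_metabolites({met: -1.0})
        new_rxns.append(ex)

    mets = model.metabolites
    for charged_id, discharged_id, comp in pairs:
        rxn = cobra.Reaction(
            f"FREE_{cm.name}_{comp}" if comp else f"FREE_{cm.name}",
            lower_bound=-_UNBOUNDED,
            upper_bound=_UNBOUNDED,
        )
        stoich: dict[cobra.Metabolite, float] = {
            mets.get_by_id(charged_id): -1.0,
            mets.get_by_id(discharged_id): 1.0,
        }
        for species_id, coeff in cm.balancing:
            if species_id in pseudo_mets:
                target = pseudo_mets[species_id]
            elif species_id in mets:
                target = mets.get_by_id(species_id)
            elif f"{species_id}_{comp}" in mets:
                target = mets.get_by_id(f"{species_id}_{comp}")
            else:
                raise KeyError(
                    f"currency metabolite {cm.name!r}: balancing species "
                    f"{species_id!r} not found (compartment {comp!r})"
                )
            stoich[target] = stoich.get(target, 0.0) + coeff
        rxn.add_metabolites(stoich)
        new_rxns.append(rxn)
    model.add_reactions(new_rxns)
    return work


def add_free_cofactors(
    mm: MetabolicModel, cms: Iterable[CurrencyMetabolite]
) -> MetabolicModel:
    """All listed cofactors freed at once."""
    work = mm
    for cm in cms:
        work = add_free_cofactor(work, cm)
    return work


def count_currency_reactions(
    mm: MetabolicModel, cms: Sequence[CurrencyMetabolite]
) -> int:
    """Non-exchange reactions whose stoichiometry touches a listed currency species."""
    targets: set[str] = set()
    for cm in cms:
        for base in cm.species_ids:
            if base in mm.cobra_model.metabolites:
                targets.add(base)
            for comp in mm.cobra_model.compartments:
                cid = f"{base}_{comp}"
                if cid in mm.cobra_model.metabolites:
                    targets.add(cid)
    count = 0
    for rxn in mm.cobra_model.reactions:
        if rxn.boundary:
            continue
        if any(met.id in targets for met in rxn.metabolites):
            count += 1
    return count


@dataclass
class ReductionResult:
    """Effect of freeing currency metabolites on previously pleiotropic genes.

    Fractions are over genes with baseline full-knockout count >= 2
    (``pleiotropic_genes``); a gene counts as reduced under a metabolite
    when its full-knockout count strictly decreases after that metabolite
    is made freely available and the whole reference is rebuilt.
    """

    mode: str
    baseline_counts: dict[str, int]
    pleiotropic_genes: tuple[str, ...]
    per_metabolite: dict[str, float]
    reduced_by: dict[str, tuple[str, ...]]
    any_fraction: float
    all_free_fraction: float


def _knockout_counts(
    ref: WildtypeReference, genes: Sequence[str], mode: str
) -> dict[str, int]:
    if mode == "pleiotropy":
        return {g: allele_pleiotropy(ref, g, 0.0)[0] for g in genes}
    if mode == "essentiality":
        return {g: essentiality_count(ref, g, 0.0) for g in genes}
    raise ValueError(f"unknown mode {mode!r}")


def reduction_analysis(
    mm: MetabolicModel,
    components: Mapping[str, float],
    cms: Sequence[CurrencyMetabolite],
    mode: str = "pleiotropy",
    genes: Optional[Sequence[str]] = None,
    threshold: float = REDUCTION_THRESHOLD,
) -> ReductionResult:
    """Per-metabolite and any-metabolite fractions of genes with reduced counts.

    Every model variant gets its own wildtype reference (pFBA included):
    "freely available" applies to the baseline of the variant as well, so no
    caps leak between variants.
    """
    gene_ids = list(genes) if genes is not None else sorted(
        g.id for g in mm.cobra_model.genes
    )
    base_ref = build_reference(mm, components, threshold=threshold)
    baseline = _knockout_counts(base_ref, gene_ids, mode)
    pleiotropic = tuple(g for g in gene_ids if baseline[g] >= 2)

    per_metabolite: dict[str, float] = {}
    reduced_by: dict[str, tuple[str, ...]] = {}
    reduced_any: set[str] = set()
    for cm in cms:
        variant = add_free_cofactor(mm, cm)
        ref = build_reference(variant, components, threshold=threshold)
        counts = _knockout_counts(ref, list(pleiotropic), mode)
        reduced = tuple(g for g in pleiotropic if counts[g] < baseline[g])
        reduced_by[cm.name] = reduced
        reduced_any.update(reduced)
        per_metabolite[cm.name] = (
            len(reduced) / len(pleiotropic) if pleiotropic else float("nan")
        )

    if cms:
        all_variant = add_free_cofactors(mm, cms)
        all_ref = build_reference(all_variant, components, threshold=threshold)
        all_counts = _knockout_counts(all_ref, list(pleiotropic), mode)
        n_all = sum(1 for g in pleiotropic if all_counts[g] < baseline[g])
    else:
        n_all = 0

    n = len(pleiotropic)
    return ReductionResult(
        mode=mode,
        baseline_counts=baseline,
        pleiotropic_genes=pleiotropic,
        per_metabolite=per_metabolite,
        reduced_by=reduced_by,
        any_fraction=len(reduced_any) / n if n else float("nan"),
        all_free_fraction=n_all / n if n else float("nan"),
    )
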