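"""Loading metabolic models and resolving which reactions a gene controls.

Models are SBML (Level 3 + fbc preferred; legacy COBRA notes accepted via
COBRApy's reader). A :class:`MetabolicModel` is a thin wrapper around a
:class:`cobra.Model` plus the designated biomass reaction, so downstream
code never has to guess which reaction encodes growth.

Gene-to-reaction control follows boolean gene-protein-reaction (GPR)
semantics: a gene constrains a reaction iff the GPR evaluates to false when
that gene alone is switched off, i.e. the gene is essential for catalysis.
A gene appearing only as one isoenzyme in an OR clause therefore does not
constrain the reaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import cobra
import cobra.io

__all__ = [
    "ModelConfig",
    "MetabolicModel",
    "load_model",
    "write_model",
    "extract_biomass_components",
    "reactions_constrained_by_gene",
    "gene_blocks_reaction",
]


@dataclass
class ModelConfig:
    """How to interpret a model file.

    Parameters
    ----------
    biomass_reaction_id
        Reaction encoding growth. When ``None``, the reaction carrying the
        model's objective coefficient is used.
    excluded_species
        Species ids never counted as biomass components (inorganic ions,
        water, protons and similar bookkeeping species).
    medium
        Optional overrides of exchange-reaction uptake bounds, as
        ``{exchange_id: max_uptake}`` in mmol/gDW/h.
    """

    biomass_reaction_id: str | None = None
    excluded_species: tuple[str, ...] = ()
    medium: Mapping[str, float] | None = None


@dataclass
class MetabolicModel:
    """A cobra model with a designated biomass reaction."""

    cobra_model: cobra.Model
    biomass_reaction_id: str

    def __post_init__(self) -> None:
        if self.biomass_reaction_id not in self.cobra_model.reactions:
            raise KeyError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model "
                f"{self.cobra_model.id!r}"
            )
        for rxn in self.cobra_model.reactions:
            if rxn.lower_bound > rxn.upper_bound:
                raise ValueError(f"reaction {rxn.id}: lower bound exceeds upper bound")

    # -- convenience passthroughs -------------------------------------------------
    @property
    def reactions(self):
        return self.cobra_model.reactions

    @property
    def metabolites(self):
        return self.cobra_model.metabolites

    @property
    def genes(self):
        return self.cobra_model.genes

    @property
    def biomass_reaction(self) -> cobra.Reaction:
        return self.cobra_model.reactions.get_by_id(self.biomass_reaction_id)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(self.cobra_model.copy(), self.biomass_reaction_id)


def _objective_reaction_id(model: cobra.Model) -> str:
    from cobra.util.solver import linear_reaction_coefficients

    coeffs = linear_reaction_coefficients(model)
    if not coeffs:
        raise ValueError(
            "model declares no objective reaction and no biomass reaction id "
            "was configured"
        )
    # deterministic pick: largest coefficient, then lexicographic id
    best = sorted(coeffs.items(), key=lambda kv: (-abs(kv[1]), kv[0].id))[0][0]
    return best.id


def load_model(
    path: str | Path,
    config: ModelConfig | None = None,
    solver: str = "glpk",
) -> MetabolicModel:
    """Read an SBML model and designate its biomass reaction.

    The model is used exactly as published: no bound edits, no gap filling.
    Raises :class:`KeyError` when the configured biomass reaction is absent
    and :class:`ValueError` when a GPR string failed to parse (COBRApy
    reports the offending reaction).
    """
    config = config or ModelConfig()
    model = cobra.io.read_sbml_model(str(path))
    model.solver = solver

    biomass_id = config.biomass_reaction_id or _objective_reaction_id(model)
    if biomass_id not in model.reactions:
        raise KeyError(f"biomass reaction {biomass_id!r} not found in {path}")

    # a non-empty rule that produced no gene associations means the GPR
    # string could not be parsed
    for rxn in model.reactions:
        if rxn.gene_reaction_rule.strip() and not rxn.genes:
            raise ValueError(f"unparsable GPR on reaction {rxn.id!r}: "
                             f"{rxn.gene_reaction_rule!r}")

    if config.medium:
        medium = dict(model.medium)
        medium.update(config.medium)
        model.medium = medium

    return MetabolicModel(model, biomass_id)


def write_model(mm: MetabolicModel, path: str | Path) -> None:
    """Serialize back to SBML (Level 3 + fbc)."""
    mm.cobra_model.objective = mm.biomass_reaction_id
    cobra.io.write_sbml_model(mm.cobra_model, str(path))


def extract_biomass_components(
    mm: MetabolicModel, excluded: Iterable[str] = ()
) -> dict[str, float]:
    """Substrates of the biomass reaction, minus excluded species.

    Returns ``{metabolite_id: coefficient}`` with coefficients as positive
    consumption values (mmol per gDW of biomass). Each component is treated
    downstream as one phenotypic trait. Raises :class:`ValueError` when
    nothing remains — there would be no traits to score.
    """
    excluded_set = set(excluded)
    biomass = mm.biomass_reaction
    components = {
        met.id: -coeff
        for met, coeff in biomass.metabolites.items()
        if coeff < 0 and met.id not in excluded_set
    }
    if not components:
        raise ValueError(
            f"biomass reaction {mm.biomass_reaction_id!r} has no substrate "
            "metabolites left after exclusions"
        )
    return components


def gene_blocks_reaction(rxn: cobra.Reaction, gene_id: str) -> bool:
    """True iff switching off ``gene_id`` alone makes the GPR false.

    Reactions without a GPR are never blocked by any gene.
    """
    if not rxn.gene_reaction_rule.strip():
        return False
    return not rxn.gpr.eval({gene_id})


def reactions_constrained_by_gene(mm: MetabolicModel, gene_id: str) -> set[str]:
    """Reactions for which the gene is boolean-essential.

    The gene must appear alone or only inside AND clauses on every path of
    the GPR; if the GPR stays satisfiable with the gene off (an isoenzyme
    or alternative transporter exists), the reaction is not constrained.
    """
    if gene_id not in mm.cobra_model.genes:
        raise KeyError(f"gene {gene_id!r} not in model; known genes: "
                       f"{sorted(g.id for g in mm.cobra_model.genes)[:20]} ...")
    gene = mm.cobra_model.genes.get_by_id(gene_id)
    return {rxn.id for rxn in gene.reactions if gene_blocks_reaction(rxn, gene_id)}
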