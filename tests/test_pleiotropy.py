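"""Wildtype reference, allele sweeps, essentiality, reaction decomposition."""

import cobra
import numpy as np
import pytest

from pleioflux import (
    SyntheticNetworkSpec,
    allele_pleiotropy,
    build_reference,
    classify_genes,
    essentiality_count,
    essentiality_profile,
    extract_biomass_components,
    make_random_network,
    make_toy1,
    reaction_pleiotropy,
    sweep_gene,
    type2_share,
)
from pleioflux.pleiotropy import default_fraction_grid


def test_reference_component_maxima(toy1_ref, toy2_ref):
    assert toy1_ref.component_max == pytest.approx({"B1": 5.0, "B2": 5.0})
    assert toy1_ref.biomass_max == pytest.approx(5.0)
    # TOY2: R1/R2 capped at their wildtype flux of 3
    assert toy2_ref.component_max == pytest.approx({"B1": 3.0, "B2": 3.0})


def test_component_off_all_active_pathways_has_zero_maximum():
    mm = make_toy1()
    model = mm.cobra_model
    B3 = cobra.Metabolite("B3", compartment="c")
    r3 = cobra.Reaction("R3", lower_bound=0, upper_bound=1000)
    r3.add_metabolites({model.metabolites.get_by_id("A"): -1, B3: 1})
    r3.gene_reaction_rule = "g3"
    model.add_reactions([r3])
    # B3 is not in the biomass reaction, so R3 carries no wildtype flux
    ref = build_reference(mm, {"B1": 1.0, "B2": 1.0, "B3": 1.0})
    assert ref.component_max["B3"] == pytest.approx(0.0, abs=1e-9)
    # and it can never register as affected
    count, affected = allele_pleiotropy(ref, "g3", 0.0)
    assert count == 0 and affected == frozenset()


def test_allele_pleiotropy_examples(toy1_ref, toy2_ref):
    assert allele_pleiotropy(toy1_ref, "g1", 0.5) == (1, frozenset({"B1"}))
    assert allele_pleiotropy(toy2_ref, "gE", 0.75) == (0, frozenset())
    count, affected = allele_pleiotropy(toy2_ref, "gE", 0.25)
    assert count == 2 and affected == frozenset({"B1", "B2"})


def test_sweep_toy1_g1(toy1_ref):
    profile = sweep_gene(toy1_ref, "g1")
    assert len(profile.fractions) == 201
    assert profile.counts[0] == 0  # fraction 1.0
    assert (profile.counts[1:] == 1).all()  # any restriction hits B1
    assert profile.steps == 1
    assert profile.knockout_pleiotropy == 1


def test_sweep_toy2_gE_threshold_at_half_capacity(toy2_ref):
    """Cofactor generation must fall below the total demand (6f < 3+3 is
    never the binding constraint; each component needs 3, supplied 6f)."""
    profile = sweep_gene(toy2_ref, "gE")
    above = profile.counts[profile.fractions >= 0.5]
    below = profile.counts[profile.fractions < 0.5]
    assert (above == 0).all()
    assert (below == 2).all()
    assert profile.steps == 1
    assert profile.knockout_pleiotropy == 2


def test_gene_without_wildtype_flux_sweeps_to_zero():
    mm = make_toy1()
    model = mm.cobra_model
    A = model.metabolites.get_by_id("A")
    B1 = model.metabolites.get_by_id("B1")
    idle = cobra.Reaction("R_IDLE", lower_bound=0, upper_bound=1000)
    idle.add_metabolites({A: -2, B1: 1})  # wasteful duplicate, unused by pFBA
    idle.gene_reaction_rule = "g9"
    model.add_reactions([idle])
    ref = build_reference(mm, extract_biomass_components(mm))
    profile = sweep_gene(ref, "g9")
    assert (profile.counts == 0).all()
    assert profile.steps == 0


def test_essentiality_counts(toy1_ref):
    assert essentiality_count(toy1_ref, "g1", 0.0) == 1
    assert essentiality_count(toy1_ref, "g1", 1.0) == 0
    assert essentiality_count(toy1_ref, "g2", 1.0) == 0


def test_essentiality_zero_with_isoenzyme_detour():
    """With an alternative route, knocking out g1 leaves the free-flux
    maximum of B1 intact even though pleiotropy (wildtype caps) still sees
    the loss."""
    mm = make_toy1()
    model = mm.cobra_model
    r1b = cobra.Reaction("R1b", lower_bound=0, upper_bound=1000)
    r1b.add_metabolites({
        model.metabolites.get_by_id("A"): -1,
        model.metabolites.get_by_id("B1"): 1,
    })
    r1b.gene_reaction_rule = "g4"
    model.add_reactions([r1b])
    ref = build_reference(mm, extract_biomass_components(mm))
    assert essentiality_count(ref, "g1", 0.0) == 0
    count, _ = allele_pleiotropy(ref, "g1", 0.0)
    assert count in (0, 1)  # depends on which route pFBA chose
    profile = essentiality_profile(ref, "g1", np.linspace(1, 0, 5))
    assert (profile.counts == 0).all()


def test_reaction_pleiotropy(toy1_ref):
    assert reaction_pleiotropy(toy1_ref, "R1") == 1  # same as g1 knockout
    with pytest.raises(KeyError):
        reaction_pleiotropy(toy1_ref, "R_MISSING")


def test_reaction_pleiotropy_zero_for_fluxless_reaction():
    mm = make_toy1()
    model = mm.cobra_model
    A = model.metabolites.get_by_id("A")
    B1 = model.metabolites.get_by_id("B1")
    idle = cobra.Reaction("R_IDLE", lower_bound=0, upper_bound=1000)
    idle.add_metabolites({A: -2, B1: 1})
    model.add_reactions([idle])
    ref = build_reference(mm, extract_biomass_components(mm))
    assert reaction_pleiotropy(ref, "R_IDLE") == 0


def test_type2_share_bounds_and_preconditions(toy1_ref):
    # single-reaction gene: undefined
    assert type2_share(toy1_ref, "g1") is None

    # serial two-reaction gene: either block reproduces the knockout
    mm = make_toy1()
    model = mm.cobra_model
    M = cobra.Metabolite("M", compartment="c")
    r1 = model.reactions.get_by_id("R1")
    r1.subtract_metabolites({model.metabolites.get_by_id("B1"): 1})
    r1.add_metabolites({M: 1})
    r1c = cobra.Reaction("R1c", lower_bound=0, upper_bound=1000)
    r1c.add_metabolites({M: -1, model.metabolites.get_by_id("B1"): 1})
    r1c.gene_reaction_rule = "g1"
    model.add_reactions([r1c])
    ref = build_reference(mm, extract_biomass_components(mm))
    assert type2_share(ref, "g1") == pytest.approx(1.0)


def test_classification_toy1(toy1_ref):
    table = classify_genes(toy1_ref)
    assert table.loc["g1", "fitness_contributing"]
    assert table.loc["g2", "fitness_contributing"]
    assert (table["ko_pleiotropy"] == 1).all()
    assert (table["class"] == "one-component").all()


def test_classification_toy2(toy2_ref):
    table = classify_genes(toy2_ref)
    assert table["fitness_contributing"].all()
    assert table.loc["gE", "ko_pleiotropy"] == 2
    assert table.loc["gE", "class"] == "all-components"
    assert table.loc["g1", "class"] == "one-component"


def test_affected_sets_nested_along_grid(toy2_ref):
    """Caps shrink monotonically with the fraction, so affected-component
    sets must be weakly growing toward full knockout."""
    grid = default_fraction_grid(0.05)
    for gene in ("gE", "g1", "g2"):
        previous = frozenset()
        for f in grid:
            _, affected = allele_pleiotropy(toy2_ref, gene, float(f))
            assert previous <= affected
            previous = affected


def test_step_count_bounded_by_knockout_pleiotropy():
    mm, _ = make_random_network(
        SyntheticNetworkSpec(topology="branched", n_components=3, seed=11)
    )
    ref = build_reference(mm, extract_biomass_components(mm))
    grid = default_fraction_grid(0.05)
    for gene in sorted(g.id for g in mm.genes):
        profile = sweep_gene(ref, gene, grid)
        assert profile.steps <= profile.knockout_pleiotropy
        assert profile.counts[0] == 0
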