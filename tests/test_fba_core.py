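"""LP core: FBA, parsimonious FBA, wildtype caps, gene restriction."""

import itertools

import cobra
import numpy as np
import pytest

from pleioflux import (
    InfeasibleProblem,
    UnboundedProblem,
    fba,
    make_toy1,
    make_toy2,
    pfba,
    restrict_gene,
    wildtype_caps,
)
from pleioflux.oracle import _dense_problem, oracle_fba


def test_fba_optimum_toy1(toy1):
    value, fluxes = fba(toy1)
    assert value == pytest.approx(5.0)
    assert fluxes["EX_A"] == pytest.approx(10.0)


def test_fba_optimum_toy2(toy2):
    value, _ = fba(toy2)
    assert value == pytest.approx(3.0)


def test_no_carbon_source_no_growth(toy1):
    value, _ = fba(toy1, caps={"EX_A": (0.0, 0.0)})
    assert value == pytest.approx(0.0, abs=1e-9)


def test_infeasible_and_unbounded_are_distinct():
    mm = make_toy1()
    mm.reactions.get_by_id("BIOMASS").lower_bound = 1.0
    with pytest.raises(InfeasibleProblem):
        fba(mm, caps={"EX_A": (0.0, 0.0)})

    loose = make_toy1()
    loose.reactions.get_by_id("R1").upper_bound = float("inf")
    back = cobra.Reaction("R1_REV", lower_bound=0, upper_bound=float("inf"))
    back.add_metabolites({
        loose.metabolites.get_by_id("B1"): -1,
        loose.metabolites.get_by_id("A"): 1,
    })
    loose.cobra_model.add_reactions([back])
    with pytest.raises(UnboundedProblem):
        fba(loose, objective="R1")


def test_pfba_unique_optimum_toy1(toy1):
    fluxes = pfba(toy1)
    expected = {"EX_A": 10.0, "R1": 5.0, "R2": 5.0, "BIOMASS": 5.0}
    for rxn, v in expected.items():
        assert fluxes[rxn] == pytest.approx(v)


def test_pfba_unique_optimum_toy2(toy2):
    fluxes = pfba(toy2)
    expected = {"EX_A": 12.0, "RGEN": 6.0, "R1": 3.0, "R2": 3.0, "BIOMASS": 3.0}
    for rxn, v in expected.items():
        assert fluxes[rxn] == pytest.approx(v)


def test_pfba_silences_futile_cycle():
    mm = make_toy1()
    model = mm.cobra_model
    A = model.metabolites.get_by_id("A")
    C = cobra.Metabolite("C", compartment="c")
    fwd = cobra.Reaction("CYC_F", lower_bound=0, upper_bound=1000)
    fwd.add_metabolites({A: -1, C: 1})
    rev = cobra.Reaction("CYC_R", lower_bound=0, upper_bound=1000)
    rev.add_metabolites({C: -1, A: 1})
    model.add_reactions([fwd, rev])
    fluxes = pfba(mm)
    assert fluxes["CYC_F"] == pytest.approx(0.0, abs=1e-9)
    assert fluxes["CYC_R"] == pytest.approx(0.0, abs=1e-9)
    assert fluxes["BIOMASS"] == pytest.approx(5.0)


@pytest.mark.parametrize(
    "wt_flux, expected",
    [(5.0, (0.0, 5.0)), (-3.0, (-3.0, 0.0)), (0.0, (0.0, 0.0))],
)
def test_wildtype_caps_sign_branches(wt_flux, expected):
    assert wildtype_caps({"R": wt_flux})["R"] == expected


def test_restrict_gene_scales_constrained_reactions(toy1):
    wt = pfba(toy1)
    caps = wildtype_caps(wt)
    half = restrict_gene(caps, toy1, "g1", 0.5, wt)
    assert half["R1"] == (0.0, 2.5)
    assert half["R2"] == caps["R2"]
    assert restrict_gene(caps, toy1, "g1", 1.0, wt) == caps
    assert restrict_gene(caps, toy1, "g1", 0.0, wt)["R1"] == (0.0, 0.0)
    with pytest.raises(KeyError):
        restrict_gene(caps, toy1, "nope", 0.5, wt)
    with pytest.raises(ValueError):
        restrict_gene(caps, toy1, "g1", 1.5, wt)


def test_objective_monotone_under_cap_intersection(toy2):
    """Shrinking the feasible set can never raise the optimum."""
    rng = np.random.default_rng(42)
    rxn_ids = [r.id for r in toy2.reactions]
    for _ in range(10):
        caps_a = {r: (0.0, float(rng.uniform(1.0, 12.0))) for r in rxn_ids}
        caps_b = {r: (0.0, float(rng.uniform(1.0, 12.0))) for r in rxn_ids}
        both = {
            r: (max(caps_a[r][0], caps_b[r][0]), min(caps_a[r][1], caps_b[r][1]))
            for r in rxn_ids
        }
        va, _ = fba(toy2, caps=caps_a)
        vab, _ = fba(toy2, caps=both)
        assert vab <= va + 1e-9


# -- independent oracles ------------------------------------------------------

def _vertex_enumeration_max(mm, objective):
    """Enumerate basic feasible solutions of S.v=0 with box bounds and return
    the best objective value. Exponential; only for tiny networks."""
    S, rxn_ids, _, lb, ub = _dense_problem(mm)
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    c = np.zeros(n)
    c[rxn_ids.index(objective)] = 1.0
    best = -np.inf
    n_fixed = n - rank
    for fixed in itertools.combinations(range(n), n_fixed):
        free = [i for i in range(n) if i not in fixed]
        for choice in itertools.product((0, 1), repeat=n_fixed):
            v = np.zeros(n)
            for i, ch in zip(fixed, choice):
                v[i] = lb[i] if ch == 0 else ub[i]
            rhs = -S[:, fixed] @ v[list(fixed)]
            sol, *_ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
            v[free] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            best = max(best, float(c @ v))
    return best


@pytest.mark.parametrize("factory, expected", [(make_toy1, 5.0), (make_toy2, 3.0)])
def test_fba_agrees_with_vertex_enumeration(factory, expected):
    mm = factory()
    value, _ = fba(mm)
    assert value == pytest.approx(expected)
    assert _vertex_enumeration_max(mm, mm.biomass_reaction_id) == pytest.approx(expected)


@pytest.mark.parametrize("factory", [make_toy1, make_toy2])
def test_two_solver_backends_agree(factory):
    """GLPK (production path) and HiGHS via the dense oracle give the same
    optimum on the fixtures."""
    mm = factory()
    value, _ = fba(mm)
    assert oracle_fba(mm) == pytest.approx(value, abs=1e-8)
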