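"""Small synthetic metabolic networks with known ground truth.

These generators emulate the structural features the pleiotropy analysis
relies on — a biomass reaction over several components, linear and branched
pathways off a shared precursor, isoenzyme (OR) and complex (AND) GPR
rules, and a currency-metabolite cycle coupling otherwise independent
pathways — at a scale where every number can be verified by hand or by the
brute-force LP oracle.

Two fixed fixtures:

TOY1   EX_A: -> A (<= 10);  R1: A -> B1 [g1];  R2: A -> B2 [g2];
       BIOMASS: B1 + B2 ->.  Biomass optimum 5, uptake split 5/5.

TOY2   EX_A: -> A (<= 12);  RGEN: A + X -> W + Xstar [gE];
       R1: A + Xstar -> B1 + X [g1];  R2: A + Xstar -> B2 + X [g2];
       EX_W: W ->;  BIOMASS: B1 + B2 ->.  Each biomass unit costs 4 A
       (2 directly, 2 through cofactor charging), so the optimum is 3 with
       RGEN = 6 and R1 = R2 = 3. (Xstar, X) is the toy currency pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import cobra
import numpy as np
import pandas as pd

from pleioflux.currency import CurrencyMetabolite
from pleioflux.model_io import MetabolicModel
from pleioflux.oracle import (
    oracle_allele_pleiotropy,
    oracle_essentiality_count,
    oracle_fba,
    oracle_pfba,
)

__all__ = [
    "SyntheticNetworkSpec",
    "make_toy1",
    "make_toy2",
    "toy2_currency_pair",
    "make_random_network",
    "write_ground_truth",
]

_UB = 1000.0


def _reaction(
    rxn_id: str,
    stoich: dict[cobra.Metabolite, float],
    gpr: str = "",
    lb: float = 0.0,
    ub: float = _UB,
) -> cobra.Reaction:
    rxn = cobra.Reaction(rxn_id, lower_bound=lb, upper_bound=ub)
    rxn.add_metabolites(stoich)
    if gpr:
        rxn.gene_reaction_rule = gpr
    return rxn


def _finish(model: cobra.Model, biomass_id: str) -> MetabolicModel:
    model.objective = biomass_id
    model.solver = "glpk"
    return MetabolicModel(model, biomass_id)


def make_toy1() -> MetabolicModel:
    """Two independent single-gene pathways feeding a two-component biomass."""
    model = cobra.Model("TOY1")
    A, B1, B2 = (cobra.Metabolite(m, compartment="c") for m in ("A", "B1", "B2"))
    model.add_reactions([
        _reaction("EX_A", {A: 1.0}, ub=10.0),
        _reaction("R1", {A: -1.0, B1: 1.0}, gpr="g1"),
        _reaction("R2", {A: -1.0, B2: 1.0}, gpr="g2"),
        _reaction("BIOMASS", {B1: -1.0, B2: -1.0}),
    ])
    return _finish(model, "BIOMASS")


def make_toy2() -> MetabolicModel:
    """Currency-coupled fixture: both pathways draw on one cofactor cycle."""
    model = cobra.Model("TOY2")
    A, X, Xstar, W, B1, B2 = (
        cobra.Metabolite(m, compartment="c")
        for m in ("A", "X", "Xstar", "W", "B1", "B2")
    )
    model.add_reactions([
        _reaction("EX_A", {A: 1.0}, ub=12.0),
        _reaction("RGEN", {A: -1.0, X: -1.0, W: 1.0, Xstar: 1.0}, gpr="gE"),
        _reaction("R1", {A: -1.0, Xstar: -1.0, B1: 1.0, X: 1.0}, gpr="g1"),
        _reaction("R2", {A: -1.0, Xstar: -1.0, B2: 1.0, X: 1.0}, gpr="g2"),
        _reaction("EX_W", {W: -1.0}),
        _reaction("BIOMASS", {B1: -1.0, B2: -1.0}),
    ])
    return _finish(model, "BIOMASS")


def toy2_currency_pair() -> CurrencyMetabolite:
    """The (charged, discharged) cofactor pair of TOY2."""
    return CurrencyMetabolite(name="Xpair", charged="Xstar", discharged="X")


@dataclass
class SyntheticNetworkSpec:
    """Recipe for a seeded random toy network.

    ``topology`` is one of ``linear`` (independent chains from the uptake
    metabolite to each biomass component, with genes drawn from a shared
    pool so some genes serve several chains), ``branched`` (all chains hang
    off a common precursor pathway whose genes affect every component) or
    ``currency`` (every chain consumes a charged cofactor regenerated by a
    single generator reaction, as in TOY2).
    """

    n_components: int = 4
    topology: str = "linear"
    isoenzymes: bool = False
    complexes: bool = False
    uptake_budget: float = 10.0
    cofactor_cost: int = 1
    max_chain_len: int = 3
    gene_pool_factor: float = 0.7
    seed: int = 0
    max_retries: int = 5


def _decorate_gpr(gene: str, rng: np.random.Generator,
                  spec: SyntheticNetworkSpec, counter: list[int]) -> str:
    """Optionally wrap a gene into an OR (isoenzyme) or AND (complex) rule."""
    roll = rng.random()
    if spec.isoenzymes and roll < 0.25:
        counter[0] += 1
        return f"{gene} or gIso{counter[0]}"
    if spec.complexes and roll > 0.75:
        counter[0] += 1
        return f"{gene} and gCx{counter[0]}"
    return gene


def _build_network(spec: SyntheticNetworkSpec, seed: int) -> MetabolicModel:
    rng = np.random.default_rng(seed)
    model = cobra.Model(f"SYN_{spec.topology}_{seed}")
    mets: dict[str, cobra.Metabolite] = {}

    def met(mid: str) -> cobra.Metabolite:
        if mid not in mets:
            mets[mid] = cobra.Metabolite(mid, compartment="c")
        return mets[mid]

    reactions: list[cobra.Reaction] = [
        _reaction("EX_A", {met("A"): 1.0}, ub=spec.uptake_budget)
    ]
    chains: list[list[tuple[str, str]]] = []  # (from, to) metabolite steps
    comps = [f"B{i + 1}" for i in range(spec.n_components)]

    if spec.topology == "branched":
        shared_len = int(rng.integers(1, 3))
        prev = "A"
        for s in range(shared_len):
            nxt = f"P{s + 1}" if s < shared_len - 1 else "P"
            chains.append([(prev, nxt)])
            prev = nxt
        root = "P"
    else:
        root = "A"

    if spec.topology == "currency":
        reactions.append(
            _reaction(
                "RGEN",
                {met("A"): -1.0, met("X"): -1.0, met("W"): 1.0, met("Xstar"): 1.0},
                gpr="gE",
            )
        )
        reactions.append(_reaction("EX_W", {met("W"): -1.0}))

    for i, comp in enumerate(comps):
        length = int(rng.integers(1, spec.max_chain_len + 1))
        prev = root
        steps = []
        for s in range(length):
            nxt = comp if s == length - 1 else f"M{i + 1}_{s + 1}"
            steps.append((prev, nxt))
            prev = nxt
        chains.append(steps)

    # flatten chain steps into reactions with genes drawn from a shared pool
    all_steps = [step for chain in chains for step in chain]
    n_genes = max(2, int(np.ceil(spec.gene_pool_factor * len(all_steps))))
    pool = [f"g{j + 1}" for j in range(n_genes)]
    decorate_counter = [0]
    for idx, (src, dst) in enumerate(all_steps):
        gene = pool[int(rng.integers(n_genes))]
        gpr = _decorate_gpr(gene, rng, spec, decorate_counter)
        stoich = {met(src): -1.0, met(dst): 1.0}
        if spec.topology == "currency" and dst in comps:
            c = float(spec.cofactor_cost)
            stoich[met("Xstar")] = -c
            stoich[met("X")] = c
        reactions.append(_reaction(f"R{idx + 1}", stoich, gpr=gpr))

    # heterogeneous small-integer biomass coefficients: chains then carry
    # different wildtype fluxes, so a shared gene hits its components at
    # different capacity thresholds (stepwise pleiotropy)
    coeffs = rng.integers(1, 4, size=len(comps))
    biomass = _reaction(
        "BIOMASS", {met(c): -float(k) for c, k in zip(comps, coeffs)}
    )
    reactions.append(biomass)
    model.add_reactions(reactions)
    return _finish(model, "BIOMASS")


def make_random_network(
    spec: SyntheticNetworkSpec,
) -> tuple[MetabolicModel, pd.DataFrame]:
    """Seeded random network plus oracle-computed ground truth.

    The returned frame has one row per gene with its full-knockout
    pleiotropy and essentiality counts, both computed by the brute-force
    oracle (fresh LP per component). Draws whose biomass optimum is zero
    are resampled a bounded number of times.
    """
    if spec.topology not in ("linear", "branched", "currency"):
        raise ValueError(f"unknown topology {spec.topology!r}")
    for attempt in range(spec.max_retries):
        mm = _build_network(spec, spec.seed + 1_000_003 * attempt)
        opt = oracle_fba(mm)
        if opt is not None and opt > 1e-6:
            break
    else:
        raise RuntimeError(
            f"could not draw a feasible network for spec {spec} "
            f"in {spec.max_retries} attempts"
        )
    components = [
        m.id for m, c in mm.biomass_reaction.metabolites.items() if c < 0
    ]
    wt = oracle_pfba(mm)
    rows = []
    for gene in sorted(g.id for g in mm.genes):
        rows.append(
            (
                gene,
                oracle_allele_pleiotropy(mm, components, gene, 0.0, wt),
                oracle_essentiality_count(mm, components, gene, 0.0, wt),
            )
        )
    truth = pd.DataFrame(
        rows, columns=["gene", "ko_pleiotropy", "essentiality"]
    ).set_index("gene")
    return mm, truth


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t")
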