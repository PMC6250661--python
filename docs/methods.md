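# Methods

## Model and scope

The pipeline treats a metabolic network as a linear steady-state system:
fluxes **v** (mmol/gDW/h; biomass in 1/h) satisfy S·v = 0 within reaction
bounds, and growth is the flux of a designated biomass pseudo-reaction.
Phenotypic traits are the substrates of that reaction — amino acids,
nucleotides, lipids and other organic precursors — after removing water,
protons and inorganic ions, which are bookkeeping species rather than
synthesized components. Published models are used exactly as read from
SBML: no bound edits, no compartment merging, no gap filling; a native
constraint such as a maintenance-ATPase lower bound is carried through
unchanged.

## Wildtype reference and the flux-cap rule

The wildtype state is the parsimonious-FBA optimum: biomass is maximized,
then the sum of absolute fluxes is minimized at that optimum via
forward/reverse flux splitting (the objective is held fixed by COBRApy's
constraint with a 10⁻⁹-scale tolerance band; stage 2 is verified to retain
the stage-1 value to 10⁻⁶ relative). The wildtype fluxes then cap every
reaction between zero and its wildtype value, sign-respecting; fluxes
within 10⁻⁹ of zero are capped to exactly zero. Caps are always
intersected with native bounds, never widened.

Parsimonious optima need not be unique. The fixtures and the synthetic
generator are constructed so the optimum *is* unique (chains are forced to
run at the biomass-stoichiometry rate), and on those the GLPK production
path and the independent HiGHS oracle agree flux by flux. On degenerate
models, wildtype-dependent quantities are solver-conditional; no tertiary
tie-break is imposed, and the tests quantify the consequence only where the
optimum is unique.

## Counting rule

A trait counts as affected when its maximal production falls below
(1 − 10⁻⁴) of its baseline, i.e. a relative drop of at least 0.01%, with an
absolute floor of 10⁻⁹ guarding near-zero maxima; traits whose baseline
maximum is already ≤ 10⁻⁹ can never register a reduction and are recorded
but not counted. An allele whose capped problem becomes infeasible (a
knockout cap colliding with a native lower bound such as a maintenance
floor) scores zero production for every trait: the allele cannot sustain
any steady state, so all producible traits count as affected.

## Alleles, sweeps and steps

A gene constrains a reaction iff the GPR evaluates false with that gene off
and every other gene on (boolean essentiality). This generalizes "alone or
only in an AND relationship" to arbitrarily nested expressions: in
`(g1 and g2) or (g1 and g3)`, g1 constrains the reaction, g2 and g3 do not.
An allele at capacity fraction f caps each constrained reaction's magnitude
at f·|v^WT| with the wildtype sign. The default sweep grid runs from 100%
to 0% in 0.5% steps (201 points); each grid point is an independent set of
LPs, one per trait, inside a single solver context. The step count is the
number of strict increases between adjacent grid points — plateaus
contribute nothing — and is bounded above by the full-knockout pleiotropy
since affected sets are nested (caps shrink monotonically with f).

## Essentiality

Essentiality replaces the wildtype caps by native bounds (free flux
redistribution) while still capping the gene's reactions at f·|v^WT|. The
baseline for the comparison is the fraction-1.0 member of the same allele
family — native bounds with the gene at 100% of wildtype capacity — rather
than the fully unconstrained model. The two baselines coincide whenever the
free optimum does not push the gene's reactions beyond their wildtype flux;
where they differ, the capacity-capped baseline answers the sharper
question "what does *reducing* this gene's activity below wildtype make
impossible?", keeps the unmutated allele identically at zero, and makes the
per-fraction profile continuous in f. At full knockout (the headline
statistic) the two definitions disagree only for genes whose capacity is
entirely non-binding for a trait, where counting the trait as affected
would be spurious.

## Currency metabolites

A cofactor is made freely available by adding one reversible, unbounded
reaction per compartment interconverting its charged and discharged forms.
Balancing species that do not exist in the model (electrons, protons
donated to an external sink, transferred phosphoryl/acetyl/amino groups)
are created as pool species with their own free exchange, so the
half-reaction balances without touching real metabolite pools. The shipped
`data/currency_bigg.yml` covers the canonical 14 cofactors in the BiGG
namespace (ATP/ADP, CTP/CDP, GTP/GDP, UTP/UDP, ITP/IDP, NADH/NAD,
NADPH/NADP, FADH2/FAD, FMNH2/FMN, Q8H2/Q8, MQL8/MQN8, DMMQL8/DMMQ8,
acetyl-CoA/CoA, glutamate/2-oxoglutarate); models in other namespaces need
their own file. Every freed-cofactor variant gets a full fresh pipeline —
pFBA reference included — because "freely available" must also hold for
the variant's own baseline; a state-isolation test asserts that no caps
leak between variants. A gene counts as reduced when its full-knockout
count strictly decreases; fractions are reported per metabolite, for the
union over metabolites, and for an all-cofactors-free run.

## Modularity

The gene–trait network links each gene to the traits its full knockout
affects (genes with empty sets are dropped). Barber's bipartite modularity
Q = (1/m) Σ_{same module} (A_gt − k_g d_t/m) is optimized with LP&BRIM:
label propagation seeds modules, BRIM alternately reassigns gene-side and
trait-side labels by argmax (Q never decreases), and one spare empty module
lets nodes split off. Because label propagation tends to coalesce small
connected graphs into a single module that BRIM cannot split, each restart
also refines a few random k-module assignments (k = 2…4); the best of 20
restarts is kept for observed networks, 5 for nulls (a tractability
concession at 10,000 nulls; on enumerable networks single restarts already
find the global optimum ≥ 95% of the time). The all-in-one partition
(Q ≡ 0, an analytic identity) is always a candidate, so reported Q ≥ 0.
Nulls are degree-preserving double-edge swaps: 10·m proposed swaps, each
applied only when it creates no duplicate edge — networks with no legal
swap (complete bipartite) return unchanged. Scaled modularity is
z = (Q_obs − mean Q_null)/sd Q_null, reported as undefined when the null
variance is zero, and the empirical p uses the (1 + count)/(1 + N)
convention to avoid zero.

## Step randomization test

The null hypothesis is that, apart from the upper bound, step counts carry
no information about knockout pleiotropy: each gene's step count is drawn
uniformly on the integers {0, …, maxP} (steps are counts, so the discrete
uniform is the only sensible reading). The test draws n_rand such datasets
(10⁶ by default), computes Spearman's ρ (average ranks for ties) for each
in vectorized chunks, and reports p = (1 + #{ρ_null ≥ ρ_obs})/(1 + n_rand).
Genes with maxP = 0 are excluded by default — they force ties at zero in
both variables — with an opt-in to include them. An undefined observed ρ
(zero variance) propagates as NaN rather than a spurious p. Null draws
with all-tied steps have undefined ρ and are scored 0, which cannot
inflate p for any positive observed correlation.

## Synthetic data

The generator emulates the structural features the analysis depends on:
a multi-component biomass reaction with heterogeneous small-integer
coefficients (so chains carry different wildtype fluxes and a shared gene
hits its traits at different capacity thresholds — the origin of stepwise
pleiotropy), linear chains with genes drawn from a shared pool (size 0.7 ×
the number of reactions, so some genes serve several pathways), branched
topologies with a common precursor pathway, a TOY2-style currency cycle
whose generator couples otherwise independent chains, and optional
isoenzyme (OR) and complex (AND) GPR decorations (25% of reactions each
when enabled). Coefficients stay small integers so every fixture remains
hand-verifiable, and uptake budgets default to 10–12 mmol/gDW/h as in the
fixed toys. What the generator does **not** emulate: genome-scale size,
realistic biochemistry or elemental balancing, alternative optimal flux
distributions, compartments, or a realistic medium. Passing tests
therefore certify the *machinery* — LP construction, caps, counting,
network statistics — not the biological numbers of any real model, which
require the published SBML files.

Ground truth for every generated network comes from the brute-force oracle:
dense LPs built from scratch per trait and solved with scipy's HiGHS,
GPR evaluation by walking the parsed expression tree — no code shared with
the production path.

## Problem sizes and numerical choices

Solver: GLPK via optlang (feasibility/optimality at solver defaults near
10⁻⁹); infeasibility detected both at bound-intersection time (lb > ub)
and from solver status. Tests compare the engine against the oracle on the
two fixed fixtures over the full 201-point grid and on 50 seeded networks
per topology class at full knockout, with sweep-profile equivalence on a
subset along an 11-point grid; the acceptance script uses 10 networks per
topology, 200 rewired nulls and 10⁵ randomization draws. These sizes are
the package's own desk-scale defaults; genome-scale runs use the same code
paths with the full 10⁴-null and 10⁶-draw settings from `RunConfig`.

## Known limitations

- Degenerate parsimonious optima make wildtype-dependent quantities
  solver-conditional on real models; published active-network sizes should
  be treated accordingly.
- The currency list and ion-exclusion defaults ship for the BiGG namespace
  only; model-specific supplementary component lists are authoritative for
  reproducing published component counts.
- The per-fraction essentiality profile extends the full-knockout notion of
  essentiality; see the baseline discussion above for the convention chosen.
- LP&BRIM is a heuristic; on large networks the reported Q is a lower bound
  on the true optimum (mitigated by restarts and random reseeding).
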