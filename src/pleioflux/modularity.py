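"""Bipartite gene--trait network modularity.

The full-knockout results define a bipartite graph linking genes to the
biomass components they affect. Modularity is Barber's bipartite Q,

    Q = (1/m) * sum over gene-trait pairs (g, t) in the same module of
        (A_gt - k_g * d_t / m)

with A the biadjacency matrix, k and d the gene and trait degrees and m the
edge count. Modules may mix genes and traits. Partitions are found with
LP&BRIM: label propagation seeds modules, then BRIM alternately reassigns
gene-side and trait-side labels to the adjacent module that maximizes Q
until Q stops improving; the best of several random restarts is kept.

Significance comes from a degree-preserving null: double-edge swaps rewire
the network while keeping both degree sequences, and the observed Q is
compared against the null Q distribution via a z-score ("scaled
modularity") and an empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GeneTraitNetwork",
    "ModularityResult",
    "barber_q",
    "lp_brim",
    "rewire_null",
    "scaled_modularity",
]


@dataclass(frozen=True)
class GeneTraitNetwork:
    """Bipartite incidence of genes vs. affected biomass components."""

    genes: tuple[str, ...]
    traits: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.edges:
            raise ValueError("gene-trait network has no edges")
        gene_set, trait_set = set(self.genes), set(self.traits)
        if gene_set & trait_set:
            raise ValueError("gene and trait node ids must be disjoint")
        for g, t in self.edges:
            if g not in gene_set or t not in trait_set:
                raise ValueError(f"edge ({g}, {t}) references unknown nodes")

    @classmethod
    def from_affected_sets(
        cls, affected: Mapping[str, frozenset[str] | set[str]]
    ) -> "GeneTraitNetwork":
        """Build from per-gene affected-component sets at full knockout.

        Genes with empty sets would be isolated nodes and are dropped.
        """
        edges = frozenset(
            (g, t) for g, comps in affected.items() for t in comps
        )
        genes = tuple(sorted({g for g, _ in edges}))
        traits = tuple(sorted({t for _, t in edges}))
        return cls(genes=genes, traits=traits, edges=edges)

    @property
    def m(self) -> int:
        return len(self.edges)

    def biadjacency(self) -> np.ndarray:
        gi = {g: i for i, g in enumerate(self.genes)}
        ti = {t: j for j, t in enumerate(self.traits)}
        A = np.zeros((len(self.genes), len(self.traits)))
        for g, t in self.edges:
            A[gi[g], ti[t]] = 1.0
        return A

    def degrees(self) -> tuple[dict[str, int], dict[str, int]]:
        k = {g: 0 for g in self.genes}
        d = {t: 0 for t in self.traits}
        for g, t in self.edges:
            k[g] += 1
            d[t] += 1
        return k, d


@dataclass
class ModularityResult:
    """Observed partition and Q with its degree-preserving null distribution."""

    partition: dict[str, int]
    q: float
    null_q: np.ndarray
    z: Optional[float]
    p: float

    @property
    def n_null(self) -> int:
        return len(self.null_q)


def _modularity_matrix(A: np.ndarray) -> tuple[np.ndarray, float]:
    m = A.sum()
    k = A.sum(axis=1)
    d = A.sum(axis=0)
    return A - np.outer(k, d) / m, m


def barber_q(net: GeneTraitNetwork, partition: Mapping[str, int]) -> float:
    """Barber's bipartite modularity of a (possibly mixed) partition."""
    A = net.biadjacency()
    Bt, m = _modularity_matrix(A)
    gl = np.array([partition[g] for g in net.genes])
    tl = np.array([partition[t] for t in net.traits])
    same = gl[:, None] == tl[None, :]
    return float((Bt * same).sum() / m)


def _brim(Bt: np.ndarray, m: float, gl: np.ndarray, tl: np.ndarray,
          max_iter: int = 200) -> tuple[np.ndarray, np.ndarray, float]:
    """BRIM refinement: alternate argmax assignments; Q never decreases.

    One spare empty module column is kept so a node whose best existing
    module contributes negatively can split off on its own.
    """
    c = int(max(gl.max(), tl.max())) + 2
    q_prev = -np.inf
    for _ in range(max_iter):
        T = np.zeros((len(tl), c))
        T[np.arange(len(tl)), tl] = 1.0
        gene_scores = Bt @ T                      # genes x modules
        gl = np.argmax(gene_scores, axis=1)
        R = np.zeros((len(gl), c))
        R[np.arange(len(gl)), gl] = 1.0
        trait_scores = Bt.T @ R
        tl = np.argmax(trait_scores, axis=1)
        q = float(trait_scores[np.arange(len(tl)), tl].sum() / m)
        if q <= q_prev + 1e-12:
            break
        q_prev = q
    return gl, tl, q_prev if q_prev > -np.inf else 0.0


def _label_propagation(net: GeneTraitNetwork, rng: np.random.Generator,
                       max_sweeps: int = 30) -> dict[str, int]:
    """Seed modules: each node repeatedly adopts its neighbors' majority label."""
    nodes = list(net.genes) + list(net.traits)
    labels = {node: i for i, node in enumerate(nodes)}
    neighbors: dict[str, list[str]] = {node: [] for node in nodes}
    for g, t in net.edges:
        neighbors[g].append(t)
        neighbors[t].append(g)
    order = np.array(nodes, dtype=object)
    for _ in range(max_sweeps):
        changed = False
        rng.shuffle(order)
        for node in order:
            neigh = neighbors[node]
            if not neigh:
                continue
            counts: dict[int, int] = {}
            for nb in neigh:
                counts[labels[nb]] = counts.get(labels[nb], 0) + 1
            best = max(counts.values())
            candidates = sorted(lab for lab, c in counts.items() if c == best)
            new = candidates[int(rng.integers(len(candidates)))]
            if new != labels[node]:
                labels[node] = new
                changed = True
        if not changed:
            break
    return labels


def lp_brim(
    net: GeneTraitNetwork, seed: int = 0, n_restarts: int = 20
) -> tuple[dict[str, int], float]:
    """Best partition over seeded LP&BRIM restarts (never below Q = 0).

    Each restart refines several initial label assignments with BRIM: the
    label-propagation seed plus a few random k-module assignments (label
    propagation alone tends to coalesce small connected graphs into one
    module, which BRIM's alternating argmax cannot split). The all-in-one
    partition (Q = 0 identically) is always a candidate, so the returned Q
    is nonnegative.
    """
    A = net.biadjacency()
    Bt, m = _modularity_matrix(A)
    rng = np.random.default_rng(seed)
    n_g, n_t = len(net.genes), len(net.traits)
    n_nodes = n_g + n_t

    best_q = 0.0
    best_partition = {node: 0 for node in net.genes + net.traits}
    for _ in range(max(1, n_restarts)):
        inits: list[tuple[np.ndarray, np.ndarray]] = []
        labels = _label_propagation(net, rng)
        uniq = {lab: i for i, lab in enumerate(sorted(set(labels.values())))}
        inits.append((
            np.array([uniq[labels[g]] for g in net.genes]),
            np.array([uniq[labels[t]] for t in net.traits]),
        ))
        for k in (2, 3, 4):
            if k > n_nodes:
                break
            inits.append((
                rng.integers(0, k, size=n_g),
                rng.integers(0, k, size=n_t),
            ))
        for gl0, tl0 in inits:
            gl, tl, q = _brim(Bt, m, gl0, tl0)
            if q > best_q:
                best_q = q
                best_partition = {
                    **{g: int(gl[i]) for i, g in enumerate(net.genes)},
                    **{t: int(tl[j]) for j, t in enumerate(net.traits)},
                }
    return best_partition, best_q


def rewire_null(
    net: GeneTraitNetwork, seed: int | np.random.Generator = 0
) -> GeneTraitNetwork:
    """Degree-preserving rewiring by bipartite double-edge swaps.

    Proposes 10*m swaps of the gene endpoints of two random edges, applying
    each only when it creates no duplicate edge. Both degree sequences are
    invariant. Networks admitting no legal swap (e.g. complete bipartite)
    come back unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = sorted(net.edges)
    m = len(edges)
    if m < 2:
        return net
    edge_set = set(edges)
    n_trials = 10 * m
    pick = rng.integers(0, m, size=(n_trials, 2))
    for a, b in pick:
        if a == b:
            continue
        g1, t1 = edges[a]
        g2, t2 = edges[b]
        if g1 == g2 or t1 == t2:
            continue
        e1, e2 = (g1, t2), (g2, t1)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard((g1, t1))
        edge_set.discard((g2, t2))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[a], edges[b] = e1, e2
    return GeneTraitNetwork(
        genes=net.genes, traits=net.traits, edges=frozenset(edge_set)
    )


def scaled_modularity(
    net: GeneTraitNetwork,
    n_null: int = 10_000,
    seed: int = 0,
    n_restarts: int = 20,
    null_restarts: int = 5,
) -> ModularityResult:
    """Observed Q, its z-score against rewired nulls, and the empirical p.

    z = (Q_obs - mean(Q_null)) / sd(Q_null); undefined (None) when the null
    variance is zero. p = (1 + #{Q_null >= Q_obs}) / (1 + n_null).
    """
    if n_null < 2:
        raise ValueError("n_null must be at least 2")
    rng = np.random.default_rng(seed)
    partition, q_obs = lp_brim(net, seed=int(rng.integers(2**31)),
                               n_restarts=n_restarts)
    null_q = np.empty(n_null)
    for i in range(n_null):
        null_net = rewire_null(net, rng)
        _, null_q[i] = lp_brim(null_net, seed=int(rng.integers(2**31)),
                               n_restarts=null_restarts)
    sd = float(null_q.std(ddof=1))
    z = (q_obs - float(null_q.mean())) / sd if sd > 0 else None
    p = (1 + int(np.sum(null_q >= q_obs))) / (1 + n_null)
    return ModularityResult(partition=partition, q=q_obs, null_q=null_q, z=z, p=p)
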