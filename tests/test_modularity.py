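"""Barber bipartite modularity, LP&BRIM, degree-preserving nulls."""

import itertools

import numpy as np
import pytest

from pleioflux import (
    GeneTraitNetwork,
    barber_q,
    lp_brim,
    rewire_null,
    scaled_modularity,
)


def _net(edges):
    genes = tuple(sorted({g for g, _ in edges}))
    traits = tuple(sorted({t for _, t in edges}))
    return GeneTraitNetwork(genes=genes, traits=traits, edges=frozenset(edges))


TWO_EDGES = _net([("ga", "t1"), ("gb", "t2")])
COMPLETE_22 = _net([("ga", "t1"), ("ga", "t2"), ("gb", "t1"), ("gb", "t2")])
TWO_STARS = _net(
    [("ga", "t1"), ("ga", "t2"), ("gb", "t3"), ("gb", "t4"), ("gc", "t3")]
)


def _all_partitions(nodes):
    """Every set partition of the node list (Bell-number many)."""
    if not nodes:
        yield {}
        return
    first, rest = nodes[0], nodes[1:]
    for sub in _all_partitions(rest):
        n_modules = max(sub.values(), default=-1) + 1
        for label in range(n_modules + 1):
            yield {first: label, **sub}


def _exhaustive_best_q(net):
    nodes = list(net.genes) + list(net.traits)
    return max(barber_q(net, p) for p in _all_partitions(nodes))


def test_network_construction_and_invariants():
    net = GeneTraitNetwork.from_affected_sets(
        {"gE": {"B1", "B2"}, "g1": {"B1"}, "g2": {"B2"}, "g0": set()}
    )
    assert net.genes == ("g1", "g2", "gE")  # empty gene dropped
    assert net.m == 4
    k, d = net.degrees()
    assert sum(k.values()) == sum(d.values()) == net.m
    with pytest.raises(ValueError):
        GeneTraitNetwork.from_affected_sets({"g": set()})


def test_gene_affecting_all_traits_has_full_degree():
    net = GeneTraitNetwork.from_affected_sets(
        {"gE": {"B1", "B2", "B3"}, "g1": {"B1"}}
    )
    k, _ = net.degrees()
    assert k["gE"] == len(net.traits)


def test_two_disjoint_edges_q_half():
    partition = {"ga": 0, "t1": 0, "gb": 1, "t2": 1}
    assert barber_q(TWO_EDGES, partition) == pytest.approx(0.5)


@pytest.mark.parametrize("net", [TWO_EDGES, COMPLETE_22, TWO_STARS])
def test_all_in_one_partition_has_zero_q(net):
    """Row and column degree sums cancel exactly in the single-module case."""
    partition = {node: 0 for node in net.genes + net.traits}
    assert barber_q(net, partition) == pytest.approx(0.0, abs=1e-12)


def test_complete_bipartite_q_never_positive():
    nodes = list(COMPLETE_22.genes) + list(COMPLETE_22.traits)
    qs = [barber_q(COMPLETE_22, p) for p in _all_partitions(nodes)]
    assert max(qs) == pytest.approx(0.0, abs=1e-12)


def test_lp_brim_recovers_two_stars():
    partition, q = lp_brim(TWO_STARS, seed=0)
    assert q == pytest.approx(_exhaustive_best_q(TWO_STARS))
    assert partition["ga"] == partition["t1"] == partition["t2"]
    assert partition["gb"] == partition["t3"] == partition["t4"]
    assert partition["ga"] != partition["gb"]


def test_lp_brim_complete_bipartite_single_module():
    _, q = lp_brim(COMPLETE_22, seed=0)
    assert q == pytest.approx(0.0, abs=1e-12)


def test_lp_brim_matches_exhaustive_enumeration_on_small_networks():
    """Single-restart LP&BRIM finds the global optimum in at least 95% of
    seeded runs on networks small enough to enumerate."""
    networks = [TWO_EDGES, TWO_STARS,
                _net([("ga", "t1"), ("gb", "t1"), ("gb", "t2"),
                      ("gc", "t3"), ("gd", "t3"), ("gd", "t2")])]
    hits = trials = 0
    for net in networks:
        best = _exhaustive_best_q(net)
        for seed in range(40):
            _, q = lp_brim(net, seed=seed, n_restarts=1)
            assert q <= best + 1e-9
            trials += 1
            hits += q >= best - 1e-9
    assert hits / trials >= 0.95


def test_lp_brim_never_below_all_in_one():
    rng = np.random.default_rng(5)
    for _ in range(10):
        edges = {(f"g{rng.integers(5)}", f"t{rng.integers(5)}") for _ in range(8)}
        net = _net(sorted(edges))
        _, q = lp_brim(net, seed=1, n_restarts=3)
        assert q >= 0.0


def test_rewire_preserves_degree_sequences():
    rng = np.random.default_rng(7)
    edges = {(f"g{rng.integers(8)}", f"t{rng.integers(6)}") for _ in range(20)}
    net = _net(sorted(edges))
    for seed in range(5):
        null = rewire_null(net, seed)
        assert null.degrees() == net.degrees()
        assert null.m == net.m


def test_rewire_complete_bipartite_is_identity():
    null = rewire_null(COMPLETE_22, 3)
    assert null.edges == COMPLETE_22.edges


def test_scaled_modularity_near_zero_under_the_null():
    """An observed network drawn from the same ensemble as the nulls should
    sit within a few standard deviations of the null mean."""
    rng = np.random.default_rng(21)
    edges = set()
    while len(edges) < 18:
        edges.add((f"g{rng.integers(9)}", f"t{rng.integers(7)}"))
    net = _net(sorted(edges))
    observed = rewire_null(net, 123)  # a typical draw from the ensemble
    result = scaled_modularity(observed, n_null=80, seed=2,
                               n_restarts=5, null_restarts=5)
    assert result.z is not None
    assert abs(result.z) < 3.0
    assert 0 < result.p <= 1


def test_scaled_modularity_detects_planted_structure():
    """Two disjoint stars are far more modular than their rewired nulls."""
    edges = [(f"g{i}", f"t{j}") for i in range(3) for j in range(3)]
    edges += [(f"h{i}", f"u{j}") for i in range(3) for j in range(3)]
    net = _net(edges)
    result = scaled_modularity(net, n_null=60, seed=4,
                               n_restarts=5, null_restarts=5)
    assert result.q == pytest.approx(0.5)
    assert result.z is not None and result.z > 3.0
    assert result.p < 0.05
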