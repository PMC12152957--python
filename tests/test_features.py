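"""The five structural descriptors: worked examples, oracles, invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bnpah.bn_isomers import BNIsomer, enumerate_bn_isomers
from bnpah.features import (
    FeatureVector,
    classify_inner_outer,
    compute_n_DR,
    compute_n_LL,
    compute_n_SP,
    featurize,
)
from bnpah.molgraph import automorphism_group, build_molecular_graph
from bnpah.scaffolds import DualistTree, enumerate_scaffolds


def _linear_tree(n):
    return DualistTree(
        cells=tuple((i, 0) for i in range(n)),
        edges=tuple((i, i + 1) for i in range(n - 1)),
    )


def _angular_tree():
    return DualistTree(cells=((0, 0), (1, 0), (1, 1)), edges=((0, 1), (1, 2)))


def _bfs_distance(bonds, n_atoms, start, goal):
    """Plain breadth-first search, independent of the implementation path."""
    adj = {i: [] for i in range(n_atoms)}
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    frontier, dist = [start], {start: 0}
    while frontier:
        nxt = []
        for v in frontier:
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    nxt.append(w)
        frontier = nxt
    return dist[goal]


def test_n_LL_worked_examples(naphthalene):
    tree, g = naphthalene
    assert compute_n_LL(g, tree) == 0  # fewer than 3 rings
    lin6 = _linear_tree(6)
    assert compute_n_LL(build_molecular_graph(lin6), lin6) == 4  # fully linear
    ang = _angular_tree()
    assert compute_n_LL(build_molecular_graph(ang), ang) == 0  # phenanthrene


def test_n_LL_bound_with_equality_only_for_linear(graphs6):
    for tree, g, _ in graphs6:
        n_ll = compute_n_LL(g, tree)
        assert 0 <= n_ll <= tree.n_rings - 2
        if n_ll == tree.n_rings - 2 and tree.n_rings > 2:
            # equality forces the single straight chain
            dirs = {
                min(d, (d + 3) % 6)
                for adj in tree.neighbor_directions()
                for d in adj
            }
            assert len(dirs) == 1


def test_inner_outer_classification(naphthalene):
    tree, g = naphthalene
    bridgeheads = [a.index for a in g.atoms if len(a.ring_membership) == 2]
    perimeter = [a.index for a in g.atoms if len(a.ring_membership) == 1]
    iso = BNIsomer("s", bridgeheads[0], perimeter[0], "k")
    assert classify_inner_outer(iso, g) == (1, 0)
    iso2 = BNIsomer("s", perimeter[0], perimeter[1], "k")
    assert classify_inner_outer(iso2, g) == (0, 0)
    # an inner B participates in three bonds to ring neighbors
    b = bridgeheads[0]
    degree = sum(1 for bond in g.bonds if b in bond)
    assert degree == 3


def test_n_SP_examples_and_bfs_oracle(graphs6):
    # bonded pair
    tree, g, group = graphs6[0]
    for iso in enumerate_bn_isomers(g, group):
        n_sp = compute_n_SP(iso, g)
        assert n_sp == _bfs_distance(g.bonds, g.n_atoms, iso.b_index, iso.n_index) - 1
        bonded = (min(iso.b_index, iso.n_index), max(iso.b_index, iso.n_index)) in g.bonds
        assert (n_sp == 0) == bonded


def test_n_SP_para_within_one_ring(benzene_graph):
    ring = benzene_graph.rings[0]
    iso = BNIsomer("s", ring[0], ring[3], "k")
    assert compute_n_SP(iso, benzene_graph) == 2


def test_n_DR_worked_examples():
    lin3 = _linear_tree(3)
    g = build_molecular_graph(lin3)
    # terminal rings: pick outer atoms exclusive to ring 0 and ring 2
    only0 = [a.index for a in g.atoms if a.ring_membership == frozenset({0})]
    only2 = [a.index for a in g.atoms if a.ring_membership == frozenset({2})]
    iso = BNIsomer("s", only0[0], only2[0], "k")
    assert compute_n_DR(iso, g, lin3) == 3  # path disrupts the middle ring
    iso_same = BNIsomer("s", only0[0], only0[1], "k")
    assert compute_n_DR(iso_same, g, lin3) == 1


def test_naphthalene_fused_bond_pair_vector(naphthalene):
    tree, g = naphthalene
    bridge = [a.index for a in g.atoms if len(a.ring_membership) == 2]
    iso = BNIsomer(tree.canonical_code, bridge[0], bridge[1], "k")
    vec = featurize(iso, g, tree)
    assert vec.as_tuple() == (2, 0, 1, 1, 0, 2)


def test_fully_linear_terminal_adjacent_vector():
    lin6 = _linear_tree(6)
    g = build_molecular_graph(lin6)
    term = [a.index for a in g.atoms if a.ring_membership == frozenset({0})]
    pair = next(
        (a, b)
        for a in term
        for b in term
        if a != b and (min(a, b), max(a, b)) in g.bonds
    )
    iso = BNIsomer("s", pair[0], pair[1], "k")
    assert featurize(iso, g, lin6).as_tuple() == (6, 4, 0, 0, 0, 1)


def test_featurize_is_pure(naphthalene):
    tree, g = naphthalene
    iso = enumerate_bn_isomers(g)[0]
    assert featurize(iso, g, tree) == featurize(iso, g, tree)


def test_full_space_invariants(features6):
    df = features6
    assert len(df) == 23894
    assert (df.n_LL <= df.n_rings - 2).all()
    assert df.b_inner.isin([0, 1]).all() and df.n_inner.isin([0, 1]).all()
    assert (df.n_SP >= 0).all()
    assert ((1 <= df.n_DR) & (df.n_DR <= df.n_rings)).all()


def test_n_SP_zero_iff_bonded_full_space(graphs6):
    for tree, g, group in graphs6:
        if tree.n_rings > 4:
            continue  # 2-4 ring space is exhaustive enough and fast
        for iso in enumerate_bn_isomers(g, group):
            bonded = (
                min(iso.b_index, iso.n_index),
                max(iso.b_index, iso.n_index),
            ) in g.bonds
            assert (compute_n_SP(iso, g) == 0) == bonded


@settings(derandomize=True, max_examples=40)
@given(
    scaffold_index=st.integers(min_value=0, max_value=19),
    isomer_index=st.integers(min_value=0, max_value=10**6),
    perm_index=st.integers(min_value=0, max_value=10**6),
)
def test_features_invariant_under_automorphic_relabeling(
    scaffold_index, isomer_index, perm_index
):
    """Replacing a (B, N) placement by any automorphic image leaves every
    descriptor unchanged."""
    tree = enumerate_scaffolds(5)[scaffold_index]
    g = build_molecular_graph(tree)
    group = automorphism_group(g)
    isomers = enumerate_bn_isomers(g, group)
    iso = isomers[isomer_index % len(isomers)]
    p = group[perm_index % len(group)]
    moved = BNIsomer(iso.scaffold_code, p[iso.b_index], p[iso.n_index], "moved")
    assert featurize(moved, g, tree) == featurize(iso, g, tree)


def test_feature_vector_validation():
    with pytest.raises(ValueError):
        FeatureVector(n_rings=3, n_LL=2, b_inner=0, n_inner=0, n_SP=1, n_DR=1)
    with pytest.raises(ValueError):
        FeatureVector(n_rings=3, n_LL=0, b_inner=0, n_inner=0, n_SP=1, n_DR=4)
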