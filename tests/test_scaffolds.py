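"""Scaffold enumeration: counts, canonical invariance, helicene detection."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bnpah.scaffolds import (
    AXIAL_DIRECTIONS,
    DualistTree,
    ScaffoldError,
    canonical_code,
    enumerate_scaffolds,
    is_helicenic,
    scaffold_counts,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle: grow every placement sequence, deduplicate
# by pairwise symmetry comparison on explicit (cells, edges) sets — no use of
# canonical_code.


def _rot(c):
    q, r = c
    return (-r, q + r)


def _ref(c):
    q, r = c
    return (q, -q - r)


def _symmetry_images(cells, edges):
    """All 12 symmetry images of (cells, cell-pair edges), each translated
    so its minimum cell sits at the origin."""
    images = []
    for use_ref in (False, True):
        tf = [(_ref(c) if use_ref else c) for c in cells]
        for _ in range(6):
            tf = [_rot(c) for c in tf]
            mapping = dict(zip(cells, tf))
            mn = min(tf)

            def norm(c):
                return (c[0] - mn[0], c[1] - mn[1])

            cset = frozenset(norm(c) for c in tf)
            eset = frozenset(
                frozenset((norm(mapping[a]), norm(mapping[b]))) for a, b in edges
            )
            images.append((cset, eset))
    return images


def _brute_force_scaffolds(n_rings):
    """Every (cells, edges) placement with n_rings cells, one class per
    free isomer.  The no-shared-atom rule is expressed geometrically: the
    new cell may not touch any ring already fused to its attachment ring."""
    start = (((0, 0), (1, 0)), (((0, 0), (1, 0)),))
    states = [start]
    for _ in range(n_rings - 2):
        nxt = []
        for cells, edges in states:
            neigh = {c: set() for c in cells}
            for a, b in edges:
                neigh[a].add(b)
                neigh[b].add(a)
            for parent in cells:
                for dq, dr in AXIAL_DIRECTIONS:
                    new = (parent[0] + dq, parent[1] + dr)
                    if new in cells:
                        continue
                    # new ring must not be adjacent to a ring fused to parent
                    if any(
                        max(abs(new[0] - o[0]), abs(new[1] - o[1]),
                            abs(new[0] + new[1] - o[0] - o[1])) == 1
                        for o in neigh[parent]
                    ):
                        continue
                    nxt.append((cells + (new,), edges + ((parent, new),)))
        states = nxt
    # two placements are the same free isomer iff their full sets of
    # normalized symmetry images coincide (the group is closed)
    classes = {frozenset(_symmetry_images(cells, edges)) for cells, edges in states}
    return classes


@pytest.mark.parametrize("n,expected", [(2, 1), (3, 2), (4, 5)])
def test_enumeration_matches_brute_force_oracle(n, expected):
    assert len(_brute_force_scaffolds(n)) == expected
    assert scaffold_counts(n)[n] == expected


def test_per_size_counts(scaffolds6):
    counts = {}
    for s in scaffolds6:
        counts[s.n_rings] = counts.get(s.n_rings, 0) + 1
    assert counts == {2: 1, 3: 2, 4: 5, 5: 12, 6: 37}
    assert len(scaffolds6) == 57


def test_enumeration_deterministic_and_sorted(scaffolds6):
    again = enumerate_scaffolds(6)
    assert [s.canonical_code for s in again] == [s.canonical_code for s in scaffolds6]
    for n in range(2, 7):
        codes = [s.canonical_code for s in scaffolds6 if s.n_rings == n]
        assert codes == sorted(codes)
        assert len(set(codes)) == len(codes)


def test_max_rings_validation():
    with pytest.raises(ValueError):
        enumerate_scaffolds(1)


def test_malformed_tree_rejected():
    # disconnected edge set
    bad = DualistTree(cells=((0, 0), (1, 0), (3, 0)), edges=((0, 1), (0, 1)))
    with pytest.raises(ScaffoldError):
        canonical_code(bad)
    # 60-degree annulation (three rings sharing an atom)
    shared = DualistTree(
        cells=((0, 0), (1, 0), (1, -1)), edges=((0, 1), (0, 2))
    )
    with pytest.raises(ScaffoldError):
        canonical_code(shared)


def _linear_tree(n):
    cells = tuple((i, 0) for i in range(n))
    return DualistTree(cells=cells, edges=tuple((i, i + 1) for i in range(n - 1)))


def _all_cis_tree(n):
    """Fibonacene path winding around the origin: cells are consecutive
    neighbors of (0,0)."""
    cells = tuple(AXIAL_DIRECTIONS[k % 6] for k in range(n))
    return DualistTree(cells=cells, edges=tuple((i, i + 1) for i in range(n - 1)))


def test_helicene_detection():
    assert not is_helicenic(_linear_tree(6))
    assert is_helicenic(_all_cis_tree(6))  # [6]helicene: ends touch
    assert not is_helicenic(_all_cis_tree(5))  # [5]-cis is a fjord, no clash


def test_single_helicene_among_six_ring_scaffolds(scaffolds6):
    helicenic = [s for s in scaffolds6 if s.helicenic]
    assert [s.n_rings for s in helicenic] == [6]
    assert helicenic[0].canonical_code == canonical_code(_all_cis_tree(6))


def test_three_ring_scaffolds_are_linear_and_angular(scaffolds6):
    three = [s for s in scaffolds6 if s.n_rings == 3]
    codes = {s.canonical_code for s in three}
    assert canonical_code(_linear_tree(3)) in codes
    assert canonical_code(_all_cis_tree(3)) in codes
    assert len(codes) == 2


@settings(derandomize=True, max_examples=60)
@given(
    index=st.integers(min_value=0, max_value=19),
    k=st.integers(min_value=0, max_value=5),
    reflect=st.booleans(),
    shift=st.tuples(st.integers(-3, 3), st.integers(-3, 3)),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_canonical_code_invariant_under_symmetry(index, k, reflect, shift, seed):
    """Rotating/reflecting/translating/relabeling a scaffold leaves its
    canonical code unchanged."""
    import random

    base = enumerate_scaffolds(5)[index]
    cells = list(base.cells)
    if reflect:
        cells = [_ref(c) for c in cells]
    for _ in range(k):
        cells = [_rot(c) for c in cells]
    cells = [(c[0] + shift[0], c[1] + shift[1]) for c in cells]
    order = list(range(len(cells)))
    random.Random(seed).shuffle(order)
    inv = {old: new for new, old in enumerate(order)}
    new_cells = tuple(cells[i] for i in order)
    new_edges = tuple((inv[i], inv[j]) for i, j in base.edges)
    assert canonical_code(DualistTree(new_cells, new_edges)) == base.canonical_code
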