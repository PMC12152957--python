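"""Exhaustive enumeration of cata-condensed benzenoid scaffolds.

A cata-condensed polybenzenoid hydrocarbon (cc-PBH) is fully described by
its *dualist tree*: one vertex per hexagonal ring, one edge per fused bond.
Because no carbon belongs to three rings, the dualist graph is a tree, and
each vertex can be pinned to a cell of the hexagonal lattice (axial
coordinates).  Two rings fused to the same ring may never sit on adjacent
lattice cells — that 60-degree annulation would force a carbon shared by
three rings — so edge directions at any vertex differ by at least 120
degrees.  Helicenes are retained: a scaffold whose embedding clashes
(two vertices on the same cell, or on adjacent cells without a fusion edge)
simply escapes the plane in three dimensions and is flagged ``helicenic``.

Scaffolds are counted as free constitutional isomers: representatives are
deduplicated under the 12 symmetries of the hexagonal lattice (6 rotations
x 2 reflections), which also identifies the two enantiomers of each
helicene.  Enumeration proceeds by breadth-first growth — attach one new
fused hexagon to every vertex of every smaller scaffold, canonicalize,
deduplicate — so actual representatives (not just counts) are produced.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

#: The six axial-coordinate steps between adjacent hexagon cells, in
#: counter-clockwise order (60 degrees apart).
AXIAL_DIRECTIONS: tuple[tuple[int, int], ...] = (
    (1, 0),
    (1, -1),
    (0, -1),
    (-1, 0),
    (-1, 1),
    (0, 1),
)

_DIRECTION_INDEX = {d: i for i, d in enumerate(AXIAL_DIRECTIONS)}

#: The dihedral symmetry group of the lattice as permutations of the six
#: directions: rotations d -> d + k and reflections d -> k - d (mod 6).
SYMMETRY_DIRECTION_MAPS: tuple[tuple[int, ...], ...] = tuple(
    [tuple((d + k) % 6 for d in range(6)) for k in range(6)]
    + [tuple((k - d) % 6 for d in range(6)) for k in range(6)]
)


class ScaffoldError(ValueError):
    """Raised when a dualist tree violates the cata-condensation invariants."""


@dataclass(frozen=True)
class DualistTree:
    """A cata-condensed scaffold as a tree of hexagon cells.

    Parameters
    ----------
    cells:
        Axial ``(q, r)`` coordinates, one per ring.  Coordinates may repeat
        for strongly winding helicenes (seven or more rings); vertices are
        identified by list position, never by coordinate.
    edges:
        Fusion bonds between rings, as index pairs into ``cells``.  Only
        tree edges define fusion; lattice adjacency alone does not.
    """

    cells: tuple[tuple[int, int], ...]
    edges: tuple[tuple[int, int], ...]
    helicenic: bool = field(default=False, compare=False)
    canonical_code: str = field(default="", compare=False)

    @property
    def n_rings(self) -> int:
        return len(self.cells)

    def neighbor_directions(self) -> list[dict[int, int]]:
        """Per-vertex map {direction index: neighbor vertex}."""
        adj: list[dict[int, int]] = [dict() for _ in self.cells]
        for i, j in self.edges:
            dq = self.cells[j][0] - self.cells[i][0]
            dr = self.cells[j][1] - self.cells[i][1]
            d = _DIRECTION_INDEX[(dq, dr)]
            adj[i][d] = j
            adj[j][(d + 3) % 6] = i
        return adj

    def validate(self) -> None:
        """Check the cata-condensation invariants, raising ScaffoldError."""
        n = len(self.cells)
        if n < 1:
            raise ScaffoldError("scaffold needs at least one ring")
        if len(self.edges) != n - 1:
            raise ScaffoldError(
                f"{len(self.edges)} edges for {n} cells: not a tree"
            )
        seen: set[tuple[int, int]] = set()
        for i, j in self.edges:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ScaffoldError(f"invalid edge ({i}, {j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ScaffoldError(f"duplicate edge ({i}, {j})")
            seen.add(key)
            dq = self.cells[j][0] - self.cells[i][0]
            dr = self.cells[j][1] - self.cells[i][1]
            if (dq, dr) not in _DIRECTION_INDEX:
                raise ScaffoldError(f"edge ({i}, {j}) joins non-adjacent cells")
        # connectivity: |edges| = n - 1 plus reachability <=> tree
        if n > 1:
            adj: list[list[int]] = [[] for _ in range(n)]
            for i, j in self.edges:
                adj[i].append(j)
                adj[j].append(i)
            stack, reached = [0], {0}
            while stack:
                v = stack.pop()
                for w in adj[v]:
                    if w not in reached:
                        reached.add(w)
                        stack.append(w)
            if len(reached) != n:
                raise ScaffoldError("edge set is disconnected")
        # no 60-degree annulation at any vertex
        for v, dirs in enumerate(self.neighbor_directions()):
            ds = sorted(dirs)
            for a, b in itertools.combinations(ds, 2):
                gap = (b - a) % 6
                if min(gap, 6 - gap) < 2:
                    raise ScaffoldError(
                        f"rings fused at 60 degrees around vertex {v}"
                    )


def _encode_from(
    root: int,
    adj: Sequence[dict[int, int]],
    sigma: tuple[int, ...],
) -> str:
    """Serialize the tree rooted at `root` with directions mapped by sigma.

    Children are emitted in increasing mapped-direction order, which makes
    the string unique for a fixed (root, sigma).
    """

    def rec(v: int, parent: int) -> str:
        parts = []
        for d in sorted(adj[v], key=lambda d: sigma[d]):
            w = adj[v][d]
            if w == parent:
                continue
            parts.append(f"{sigma[d]}{rec(w, v)}")
        return "(" + "".join(parts) + ")"

    return rec(root, -1)


def canonical_code(tree: DualistTree) -> str:
    """Canonical string for a scaffold, invariant under the 12 lattice
    symmetries (and hence under mirror) and under translation.

    The code is the lexicographic minimum, over every choice of root vertex
    and every dihedral direction map, of a rooted serialization of the
    dualist tree with edge-direction labels.  Equal codes iff the scaffolds
    are the same free constitutional isomer.
    """
    tree.validate()
    adj = tree.neighbor_directions()
    return min(
        _encode_from(root, adj, sigma)
        for root in range(len(tree.cells))
        for sigma in SYMMETRY_DIRECTION_MAPS
    )


def is_helicenic(tree: DualistTree) -> bool:
    """True iff the scaffold cannot be drawn flat without ring clash.

    Two distinct vertices on the same lattice cell, or on adjacent cells
    without a fusion edge between them, place carbon atoms on top of each
    other in the planar embedding; the physical molecule winds out of
    plane (helicene).
    """
    tree.validate()
    edge_set = {(min(i, j), max(i, j)) for i, j in tree.edges}
    for i, j in itertools.combinations(range(len(tree.cells)), 2):
        if tree.cells[i] == tree.cells[j]:
            return True
        dq = tree.cells[j][0] - tree.cells[i][0]
        dr = tree.cells[j][1] - tree.cells[i][1]
        if (dq, dr) in _DIRECTION_INDEX and (i, j) not in edge_set:
            return True
    return False


def _finalize(cells: tuple, edges: tuple) -> DualistTree:
    raw = DualistTree(cells=cells, edges=edges)
    return DualistTree(
        cells=cells,
        edges=edges,
        helicenic=is_helicenic(raw),
        canonical_code=canonical_code(raw),
    )


def _grow(parent: DualistTree) -> Iterator[DualistTree]:
    """Yield every scaffold obtained by fusing one new hexagon to `parent`."""
    adj = parent.neighbor_directions()
    for v, dirs in enumerate(adj):
        taken = sorted(dirs)
        for d in range(6):
            if any(min((d - t) % 6, (t - d) % 6) < 2 for t in taken):
                continue  # would create a 60-degree annulation (or reuse d)
            q, r = parent.cells[v]
            dq, dr = AXIAL_DIRECTIONS[d]
            cells = parent.cells + ((q + dq, r + dr),)
            edges = parent.edges + ((v, len(parent.cells)),)
            yield _finalize(cells, edges)


def enumerate_scaffolds(max_rings: int) -> list[DualistTree]:
    """All distinct cata-condensed scaffolds with 2..max_rings rings.

    Exactly one representative per free constitutional isomer is returned
    (helicenes included, enantiomers identified), ordered by
    ``(n_rings, canonical_code)``.

    Parameters
    ----------
    max_rings:
        Largest ring count, at least 2.  Tested up to 8.
    """
    if max_rings < 2:
        raise ValueError("max_rings must be at least 2")
    seed = _finalize(((0, 0), (1, 0)), ((0, 1),))
    by_size: dict[int, dict[str, DualistTree]] = {2: {seed.canonical_code: seed}}
    for n in range(2, max_rings):
        frontier: dict[str, DualistTree] = {}
        for scaffold in by_size[n].values():
            for child in _grow(scaffold):
                frontier.setdefault(child.canonical_code, child)
        by_size[n + 1] = frontier
    out: list[DualistTree] = []
    for n in range(2, max_rings + 1):
        out.extend(sorted(by_size[n].values(), key=lambda t: t.canonical_code))
    return out


def scaffold_counts(max_rings: int) -> dict[int, int]:
    """Number of distinct scaffolds per ring count, 2..max_rings."""
    counts: dict[int, int] = {}
    for scaffold in enumerate_scaffolds(max_rings):
        counts[scaffold.n_rings] = counts.get(scaffold.n_rings, 0) + 1
    return counts
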