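"""Atom-level molecular graphs for benzenoid scaffolds.

Converts a dualist tree into the carbon framework of the corresponding
polybenzenoid hydrocarbon: 4*n_rings + 2 atoms, 5*n_rings + 1 bonds,
ring membership, fused bonds and implicit hydrogen counts.  Atoms shared
between two fused rings are identified *topologically* along tree edges —
never by coordinate coincidence — so helicenes whose planar projection
self-overlaps still yield the correct graph.

Automorphism groups (with element and hydrogen count as vertex colors) are
computed on the hydrogen-suppressed graph; they are the deduplication key
for substitution-isomer counting.  Bond orders are never assigned: every
quantity downstream depends only on connectivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from bnpah.scaffolds import DualistTree

_SQRT3 = math.sqrt(3.0)

#: Idealized aromatic C-C bond length used by the planar XYZ writer (Angstrom).
CC_BOND = 1.40
CH_BOND = 1.09


@dataclass(frozen=True)
class Atom:
    index: int
    element: str  # C, B or N
    h_count: int  # 0 or 1
    ring_membership: frozenset[int]


@dataclass(frozen=True)
class MolecularGraph:
    """Hydrogen-suppressed molecular graph of a (possibly BN-doped) PBH.

    ``positions`` are idealized planar coordinates (bond length 1.40 A)
    inherited from the lattice embedding; for helicenes distinct atoms may
    share a position, which is irrelevant to every connectivity-level
    computation and only matters to the XYZ writer (which lifts them apart).
    """

    atoms: tuple[Atom, ...]
    bonds: frozenset[tuple[int, int]]
    rings: tuple[tuple[int, ...], ...]
    fused_bonds: frozenset[tuple[int, int]]
    positions: tuple[tuple[float, float], ...]
    scaffold_code: str = ""
    tree: Optional[DualistTree] = field(default=None, compare=False)

    @property
    def n_rings(self) -> int:
        return len(self.rings)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.index, element=a.element, h_count=a.h_count)
        g.add_edges_from(self.bonds)
        return g

    def elements(self) -> tuple[str, ...]:
        return tuple(a.element for a in self.atoms)

    def with_elements(self, replacements: dict[int, str]) -> "MolecularGraph":
        """Copy of the graph with some atoms' elements replaced.

        Hydrogen counts are inherited unchanged (isoelectronic BN doping
        does not alter the hydrogen framework).
        """
        atoms = tuple(
            Atom(a.index, replacements.get(a.index, a.element), a.h_count, a.ring_membership)
            for a in self.atoms
        )
        return MolecularGraph(
            atoms=atoms,
            bonds=self.bonds,
            rings=self.rings,
            fused_bonds=self.fused_bonds,
            positions=self.positions,
            scaffold_code=self.scaffold_code,
            tree=self.tree,
        )


def _hex_center(q: int, r: int) -> tuple[float, float]:
    return (_SQRT3 * (q + r / 2.0), 1.5 * r)


def _hex_corners(center: tuple[float, float]) -> list[tuple[float, float]]:
    cx, cy = center
    out = []
    for k in range(6):
        ang = math.radians(30.0 + 60.0 * k)
        out.append((cx + math.cos(ang), cy + math.sin(ang)))
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_molecular_graph(tree: DualistTree) -> MolecularGraph:
    """Carbon framework of the scaffold described by ``tree``.

    Each ring contributes six corner slots; the two slots facing a fused
    (tree) edge are merged with the matching slots of the neighboring ring.
    A single-ring tree (benzene) is accepted as a test input even though
    the enumerated chemical space starts at two rings.
    """
    tree.validate()
    n = tree.n_rings
    corners_of = []  # per ring: list of 6 (x, y)
    for q, r in tree.cells:
        corners_of.append(_hex_corners(_hex_center(q, r)))

    uf = _UnionFind(6 * n)
    for i, j in tree.edges:
        # match the two coincident corner pairs of the fused hexagons
        matches = 0
        for a in range(6):
            xa, ya = corners_of[i][a]
            for b in range(6):
                xb, yb = corners_of[j][b]
                if abs(xa - xb) < 1e-6 and abs(ya - yb) < 1e-6:
                    uf.union(6 * i + a, 6 * j + b)
                    matches += 1
        if matches != 2:  # pragma: no cover - guarded by tree.validate()
            raise ValueError(f"fused edge ({i},{j}) shares {matches} corners")

    # deterministic atom ids in first-seen (ring-major, corner-minor) order
    atom_id: dict[int, int] = {}
    positions: list[tuple[float, float]] = []
    for slot in range(6 * n):
        root = uf.find(slot)
        if root not in atom_id:
            atom_id[root] = len(atom_id)
            ring, corner = divmod(slot, 6)
            x, y = corners_of[ring][corner]
            positions.append((CC_BOND * x, CC_BOND * y))

    rings = []
    for ring in range(n):
        rings.append(tuple(atom_id[uf.find(6 * ring + c)] for c in range(6)))

    bonds: set[tuple[int, int]] = set()
    for ring_atoms in rings:
        for c in range(6):
            a, b = ring_atoms[c], ring_atoms[(c + 1) % 6]
            bonds.add((min(a, b), max(a, b)))

    membership: dict[int, set[int]] = {}
    for ring_index, ring_atoms in enumerate(rings):
        for a in ring_atoms:
            membership.setdefault(a, set()).add(ring_index)

    degree: dict[int, int] = {}
    for a, b in bonds:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1

    atoms = tuple(
        Atom(
            index=i,
            element="C",
            h_count=1 if degree[i] == 2 else 0,
            ring_membership=frozenset(membership[i]),
        )
        for i in range(len(atom_id))
    )

    fused = frozenset(
        (min(a, b), max(a, b))
        for (a, b) in bonds
        if len(membership[a]) == 2 and len(membership[b]) == 2
        and len(membership[a] & membership[b]) == 2
    )

    return MolecularGraph(
        atoms=atoms,
        bonds=frozenset(bonds),
        rings=tuple(rings),
        fused_bonds=fused,
        positions=tuple(positions),
        scaffold_code=tree.canonical_code,
        tree=tree,
    )


def automorphism_group(graph: MolecularGraph) -> tuple[tuple[int, ...], ...]:
    """Complete automorphism group of the hydrogen-suppressed graph.

    Vertices are colored by (element, h_count); each returned permutation
    ``p`` maps atom ``i`` to ``p[i]``.  The identity is always present and
    the set is closed under composition (it is the full group found by
    VF2 self-isomorphism search).
    """
    g = graph.to_networkx()
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g,
        g,
        node_match=lambda a, b: a["element"] == b["element"]
        and a["h_count"] == b["h_count"],
    )
    perms = set()
    for mapping in matcher.isomorphisms_iter():
        perms.add(tuple(mapping[i] for i in range(graph.n_atoms)))
    return tuple(sorted(perms))


# ---------------------------------------------------------------------------
# export helpers


def to_smiles(graph: MolecularGraph) -> str:
    """Connectivity-only line notation (canonical SMILES, all single bonds).

    No Kekule structure is assigned — some BN placements admit none without
    formal charges — so carbons print as bracket atoms with their explicit
    hydrogen count.  Round-trips through ``from_smiles`` preserve the graph
    up to isomorphism.
    """
    from rdkit import Chem

    mol = Chem.RWMol()
    for a in graph.atoms:
        at = Chem.Atom(a.element)
        at.SetNoImplicit(True)
        at.SetNumExplicitHs(a.h_count)
        mol.AddAtom(at)
    for a, b in sorted(graph.bonds):
        mol.AddBond(a, b, Chem.BondType.SINGLE)
    m = mol.GetMol()
    Chem.SanitizeMol(
        m, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
    )
    return Chem.MolToSmiles(m, allHsExplicit=True)


def from_smiles(smiles: str) -> nx.Graph:
    """Parse a line-notation string back into an element/h-count graph."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise ValueError(f"unparseable line notation: {smiles!r}")
    g = nx.Graph()
    for at in mol.GetAtoms():
        g.add_node(at.GetIdx(), element=at.GetSymbol(), h_count=at.GetNumExplicitHs())
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    return g


def planar_coordinates_3d(graph: MolecularGraph) -> list[tuple[str, float, float, float]]:
    """Lifted-planar coordinates including hydrogens.

    Rings are lifted along z by 0.5 A per dualist-tree depth step so that
    helicene rings whose planar projections coincide are separated; atoms
    shared by two rings sit at the mean height.  Cove/fjord scaffolds can
    still clash in this embedding — :func:`idealized_coordinates` detects
    that and switches to a distance-geometry embedding.
    """
    tree = graph.tree
    depth = {0: 0}
    if tree is not None and tree.n_rings > 1:
        adj: dict[int, list[int]] = {}
        for i, j in tree.edges:
            adj.setdefault(i, []).append(j)
            adj.setdefault(j, []).append(i)
        frontier = [0]
        while frontier:
            nxt = []
            for v in frontier:
                for w in adj.get(v, []):
                    if w not in depth:
                        depth[w] = depth[v] + 1
                        nxt.append(w)
            frontier = nxt
    rise = 0.5

    ring_z = {r: rise * depth.get(r, 0) for r in range(graph.n_rings)}
    coords: list[tuple[str, float, float, float]] = []
    ring_centers = {}
    for r in range(graph.n_rings):
        xs = [graph.positions[a][0] for a in graph.rings[r]]
        ys = [graph.positions[a][1] for a in graph.rings[r]]
        ring_centers[r] = (sum(xs) / 6.0, sum(ys) / 6.0)

    for a in graph.atoms:
        x, y = graph.positions[a.index]
        z = sum(ring_z[r] for r in a.ring_membership) / len(a.ring_membership)
        coords.append((a.element, x, y, z))

    for a in graph.atoms:
        if a.h_count:
            x, y = graph.positions[a.index]
            r = next(iter(a.ring_membership))
            cx, cy = ring_centers[r]
            dx, dy = x - cx, y - cy
            norm = math.hypot(dx, dy)
            hx = x + CH_BOND * dx / norm
            hy = y + CH_BOND * dy / norm
            coords.append(("H", hx, hy, coords[a.index][3]))
    return coords


def _embedded_coordinates_3d(
    graph: MolecularGraph, seed: int
) -> list[tuple[str, float, float, float]]:
    """Distance-geometry (ETKDG) embedding with force-field refinement."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.RWMol()
    for a in graph.atoms:
        at = Chem.Atom(a.element)
        at.SetNoImplicit(True)
        at.SetNumExplicitHs(a.h_count)
        mol.AddAtom(at)
    for a, b in sorted(graph.bonds):
        mol.AddBond(a, b, Chem.BondType.SINGLE)
    m = mol.GetMol()
    Chem.SanitizeMol(
        m, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
    )
    mh = Chem.AddHs(m)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mh, params) != 0:
        raise RuntimeError("3-D embedding failed")
    AllChem.MMFFOptimizeMolecule(mh)
    conf = mh.GetConformer()
    coords = []
    for i, at in enumerate(mh.GetAtoms()):
        p = conf.GetAtomPosition(i)
        coords.append((at.GetSymbol(), p.x, p.y, p.z))
    return coords


def _min_nonbonded_distance(
    coords: Sequence[tuple[str, float, float, float]],
    bonds: frozenset[tuple[int, int]],
    n_heavy: int,
) -> float:
    best = float("inf")
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            if (i, j) in bonds or (j, i) in bonds:
                continue
            # heavy-H bonds: H index j attached to heavy atom recorded below
            d = math.dist(coords[i][1:], coords[j][1:])
            if d < best:
                best = d
    return best


def idealized_coordinates(
    graph: MolecularGraph, seed: int = 2024
) -> list[tuple[str, float, float, float]]:
    """Idealized 3-D coordinates whose distance-perceived connectivity
    reproduces the molecular graph exactly.

    Planar scaffolds use the exact lattice geometry (1.40 A bonds).  When
    the lifted-planar embedding brings any non-bonded pair within 1.9 A —
    helicenes and tight cove/fjord motifs — a seeded distance-geometry
    embedding is used instead.
    """
    coords = planar_coordinates_3d(graph)
    # explicit-H bond list parallel to planar_coordinates_3d output order
    all_bonds = set(graph.bonds)
    h = graph.n_atoms
    for a in graph.atoms:
        if a.h_count:
            all_bonds.add((a.index, h))
            h += 1
    if _min_nonbonded_distance(coords, frozenset(all_bonds), graph.n_atoms) < 1.9:
        coords = _embedded_coordinates_3d(graph, seed)
    return coords


def write_xyz(graph: MolecularGraph, comment: str = "") -> str:
    """Single-structure XYZ block with idealized geometry."""
    coords = idealized_coordinates(graph)
    lines = [str(len(coords)), comment]
    for el, x, y, z in coords:
        lines.append(f"{el} {x:.6f} {y:.6f} {z:.6f}")
    return "\n".join(lines) + "\n"
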