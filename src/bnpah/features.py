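"""The five connectivity-only structural descriptors of a (BN)1-PBH.

All five are readable off the 2-D structure with no quantum chemistry:

* ``n_rings`` — ring count of the scaffold.
* ``n_LL`` — length, in linearly-annulated tricyclic units, of the longest
  straight (acene-like) stretch of the dualist tree: a middle ring counts
  as linear when its two fusion bonds sit on opposite hexagon edges.
  ``n_LL = max(0, straight run in rings - 2)``.
* ``b_inner`` / ``n_inner`` — whether each heteroatom sits on a fused bond
  (shared by two rings, no hydrogen) or on the perimeter.
* ``n_SP`` — carbons strictly between B and N along their shortest path
  through the molecular graph, i.e. graph distance minus one.
* ``n_DR`` — disrupted rings: every ring hosting B or N plus every ring on
  the dualist-tree path between a B-ring and an N-ring, the union minimized
  over the host-ring choices when a heteroatom belongs to two rings.

Because BN doping breaks a ring's Clar sextet (quinoidal or charge-separated
resonance only), and rings between the two heteroatoms are forced quinoidal
as well, ``n_DR`` counts the rings whose cyclic delocalization is disturbed.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import networkx as nx
import pandas as pd

from bnpah.bn_isomers import BNIsomer, enumerate_bn_isomers
from bnpah.molgraph import MolecularGraph, automorphism_group, build_molecular_graph
from bnpah.scaffolds import DualistTree, enumerate_scaffolds

FEATURE_COLUMNS = ["n_rings", "n_LL", "b_inner", "n_inner", "n_SP", "n_DR"]


@dataclass(frozen=True)
class FeatureVector:
    """Numeric encoding of the five descriptors (six components: the
    inner/outer classification is one flag per heteroatom)."""

    n_rings: int
    n_LL: int
    b_inner: int
    n_inner: int
    n_SP: int
    n_DR: int

    def __post_init__(self):
        if not 0 <= self.n_LL <= max(0, self.n_rings - 2):
            raise ValueError(f"n_LL={self.n_LL} out of range for n_rings={self.n_rings}")
        if self.b_inner not in (0, 1) or self.n_inner not in (0, 1):
            raise ValueError("inner flags must be 0/1")
        if self.n_SP < 0:
            raise ValueError("n_SP must be non-negative")
        if not 1 <= self.n_DR <= self.n_rings:
            raise ValueError(f"n_DR={self.n_DR} outside [1, {self.n_rings}]")

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(getattr(self, f.name) for f in fields(self))


def compute_n_LL(graph: MolecularGraph, tree: DualistTree) -> int:
    """Longest straight run of the dualist tree, in tricyclic (acene) units.

    A run is a chain of tree edges sharing one lattice direction; a run of
    L rings contains L - 2 linearly annulated tricycles.
    """
    adj = tree.neighbor_directions()
    best = 1
    for start in range(tree.n_rings):
        for d, nb in adj[start].items():
            if ((d + 3) % 6) in adj[start]:
                continue  # not the head of a maximal straight run
            length = 1
            v = start
            while d in adj[v]:
                v = adj[v][d]
                length += 1
            best = max(best, length)
    return max(0, best - 2)


def classify_inner_outer(
    isomer: BNIsomer, graph: MolecularGraph
) -> tuple[int, int]:
    """(b_inner, n_inner): 1 iff the heteroatom sits on a fused bond."""
    flags = []
    for idx in (isomer.b_index, isomer.n_index):
        flags.append(1 if len(graph.atoms[idx].ring_membership) == 2 else 0)
    return flags[0], flags[1]


def compute_n_SP(isomer: BNIsomer, graph: MolecularGraph) -> int:
    """Carbons strictly between B and N on their shortest path."""
    g = nx.Graph(list(graph.bonds))
    dist = nx.shortest_path_length(g, isomer.b_index, isomer.n_index)
    return dist - 1


def compute_n_DR(
    isomer: BNIsomer, graph: MolecularGraph, tree: DualistTree
) -> int:
    """Number of rings whose cyclic delocalization the BN pair disrupts."""
    rings_b = graph.atoms[isomer.b_index].ring_membership
    rings_n = graph.atoms[isomer.n_index].ring_membership
    if tree.n_rings == 1:
        return 1
    dual = nx.Graph(list(tree.edges))
    dual.add_nodes_from(range(tree.n_rings))
    best = tree.n_rings
    for rb in rings_b:
        for rn in rings_n:
            path = nx.shortest_path(dual, rb, rn)
            disrupted = set(rings_b) | set(rings_n) | set(path)
            best = min(best, len(disrupted))
    return best


def featurize(
    isomer: BNIsomer, graph: MolecularGraph, tree: DualistTree | None = None
) -> FeatureVector:
    """Assemble the full descriptor vector for one isomer.

    ``tree`` defaults to the dualist tree carried by ``graph``.
    """
    if tree is None:
        tree = graph.tree
    if tree is None:
        raise ValueError("scaffold tree not resolvable from graph; pass tree=")
    b_inner, n_inner = classify_inner_outer(isomer, graph)
    return FeatureVector(
        n_rings=graph.n_rings,
        n_LL=compute_n_LL(graph, tree),
        b_inner=b_inner,
        n_inner=n_inner,
        n_SP=compute_n_SP(isomer, graph),
        n_DR=compute_n_DR(isomer, graph, tree),
    )


def feature_table(max_rings: int = 6) -> pd.DataFrame:
    """Enumerate every scaffold and (BN)1 isomer up to ``max_rings`` rings
    and return one row per isomer with its descriptors.

    Columns: molecule_id, scaffold_code, b_index, n_index plus the six
    numeric feature columns.  Deterministic row order.
    """
    rows = []
    for tree in enumerate_scaffolds(max_rings):
        graph = build_molecular_graph(tree)
        group = automorphism_group(graph)
        # scaffold-level features are shared by all isomers
        n_ll = compute_n_LL(graph, tree)
        for isomer in enumerate_bn_isomers(graph, group):
            b_inner, n_inner = classify_inner_outer(isomer, graph)
            rows.append(
                {
                    "molecule_id": f"{tree.canonical_code}|B{isomer.b_index}N{isomer.n_index}",
                    "scaffold_code": tree.canonical_code,
                    "b_index": isomer.b_index,
                    "n_index": isomer.n_index,
                    "n_rings": graph.n_rings,
                    "n_LL": n_ll,
                    "b_inner": b_inner,
                    "n_inner": n_inner,
                    "n_SP": compute_n_SP(isomer, graph),
                    "n_DR": compute_n_DR(isomer, graph, tree),
                }
            )
    return pd.DataFrame(rows)
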