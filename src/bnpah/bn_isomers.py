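"""Enumeration of unique (BN)1 substitution isomers.

One boron and one nitrogen replace two carbons of a parent scaffold;
hydrogens are untouched, so every isomer is isoelectronic with its parent.
B and N are distinguishable, hence placements are *ordered* pairs of atom
positions, and two placements describe the same molecule exactly when a
parent-graph automorphism maps one onto the other.  Enumeration therefore
returns one representative per automorphism orbit; Burnside's lemma over
the same group provides an independent count used as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

from bnpah.molgraph import MolecularGraph, automorphism_group


@dataclass(frozen=True)
class BNIsomer:
    """One (BN)1 placement on a parent scaffold, canonicalized.

    ``b_index``/``n_index`` are atom indices of the parent carbon graph;
    ``canonical_key`` is shared by all placements in the same automorphism
    orbit (and only by those).
    """

    scaffold_code: str
    b_index: int
    n_index: int
    canonical_key: str

    def __post_init__(self):
        if self.b_index == self.n_index:
            raise ValueError("B and N must occupy distinct positions")


def _require_carbon_parent(graph: MolecularGraph) -> None:
    bad = [a.index for a in graph.atoms if a.element != "C"]
    if bad:
        raise ValueError(f"parent graph must be all-carbon; non-C at {bad}")


def enumerate_bn_isomers(
    graph: MolecularGraph,
    group: tuple[tuple[int, ...], ...] | None = None,
) -> list[BNIsomer]:
    """All unique ordered (B, N) placements on an all-carbon parent.

    Exactly one representative per orbit of ordered pairs under the parent
    automorphism group is returned: the lexicographically smallest
    ``(b_index, n_index)`` in its orbit, in sorted order.
    """
    _require_carbon_parent(graph)
    if group is None:
        group = automorphism_group(graph)
    n = graph.n_atoms
    reps: set[tuple[int, int]] = set()
    seen: set[tuple[int, int]] = set()
    for b in range(n):
        for nn in range(n):
            if b == nn or (b, nn) in seen:
                continue
            orbit = {(p[b], p[nn]) for p in group}
            seen |= orbit
            reps.add(min(orbit))
    return [
        BNIsomer(
            scaffold_code=graph.scaffold_code,
            b_index=b,
            n_index=nn,
            canonical_key=f"{graph.scaffold_code}|B{b}N{nn}",
        )
        for b, nn in sorted(reps)
    ]


def orbit_count_burnside(
    graph: MolecularGraph,
    group: tuple[tuple[int, ...], ...] | None = None,
) -> int:
    """Number of placement orbits via Burnside's lemma.

    (1/|G|) * sum over g of the number of ordered pairs of distinct atoms
    fixed by g, i.e. f_g * (f_g - 1) with f_g the count of fixed atoms.
    Must equal ``len(enumerate_bn_isomers(graph))``.
    """
    _require_carbon_parent(graph)
    if group is None:
        group = automorphism_group(graph)
    total = 0
    for p in group:
        fixed = sum(1 for i, j in enumerate(p) if i == j)
        total += fixed * (fixed - 1)
    assert total % len(group) == 0, "Burnside sum must divide evenly"
    return total // len(group)


def substituted_graph(graph: MolecularGraph, isomer: BNIsomer) -> MolecularGraph:
    """The BN-doped molecular graph of ``isomer`` (elements replaced)."""
    return graph.with_elements({isomer.b_index: "B", isomer.n_index: "N"})
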