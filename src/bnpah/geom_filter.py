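"""Geometry-based data filtration.

Optimized geometries occasionally rearrange — helicene-like structures in
particular tend to cyclize — so every molecule is screened across all of
its optimization records (two methods x three charge states).  Connectivity
is perceived from Cartesian coordinates with a covalent-radius criterion
and compared, as an element-respecting graph isomorphism, against the
intended topology.  A molecule is discarded if *any* record rearranged;
a molecule whose ionic records show imaginary frequencies is kept but
flagged for exclusion from adiabatic ionization/electron-affinity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: Single-bond covalent radii in Angstrom (Cordero et al. consensus values).
COVALENT_RADII = {"H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71}

#: Two atoms bond when their distance is below this multiple of the sum of
#: their covalent radii — standard perception practice.
BOND_SCALE = 1.2

#: Below this separation the geometry is considered corrupt, not bonded.
MIN_CONTACT = 0.4

CHARGE_STATES = ("neutral", "cation", "anion")
METHODS = ("dft", "xtb")


class GeometryError(ValueError):
    """Raised for physically impossible coordinate sets."""


@dataclass(frozen=True)
class GeometryRecord:
    """One optimized structure of one molecule in one charge state."""

    molecule_id: str
    charge_state: str  # neutral | cation | anion
    method: str  # dft | xtb
    coordinates: tuple[tuple[str, float, float, float], ...]
    imaginary_freq: bool = False


def perceive_bonds(
    coordinates: Sequence[tuple[str, float, float, float]],
) -> frozenset[tuple[int, int]]:
    """Bond set implied by interatomic distances.

    Atoms i < j bond when d(i, j) <= 1.2 * (r_cov(i) + r_cov(j)).
    Distances under 0.4 A raise :class:`GeometryError`.
    """
    if len(coordinates) < 2:
        raise GeometryError("need at least two atoms")
    bonds: set[tuple[int, int]] = set()
    for i in range(len(coordinates)):
        el_i, xi, yi, zi = coordinates[i]
        for j in range(i + 1, len(coordinates)):
            el_j, xj, yj, zj = coordinates[j]
            d2 = (xi - xj) ** 2 + (yi - yj) ** 2 + (zi - zj) ** 2
            if d2 < MIN_CONTACT**2:
                raise GeometryError(
                    f"atoms {i} and {j} overlap (d = {d2 ** 0.5:.3f} A)"
                )
            cutoff = BOND_SCALE * (COVALENT_RADII[el_i] + COVALENT_RADII[el_j])
            if d2 <= cutoff**2:
                bonds.add((i, j))
    return frozenset(bonds)


def reference_graph_with_hydrogens(reference) -> nx.Graph:
    """Expand a hydrogen-suppressed MolecularGraph to explicit hydrogens."""
    g = nx.Graph()
    for a in reference.atoms:
        g.add_node(a.index, element=a.element)
    g.add_edges_from(reference.bonds)
    h = len(reference.atoms)
    for a in reference.atoms:
        for _ in range(a.h_count):
            g.add_node(h, element="H")
            g.add_edge(a.index, h)
            h += 1
    return g


def detect_rearrangement(
    reference,
    elements: Sequence[str],
    observed_bonds: Iterable[tuple[int, int]],
) -> bool:
    """True iff the observed connectivity differs from the intended one.

    The comparison is an element-respecting graph isomorphism between the
    explicit-hydrogen reference graph and the observed graph — the same
    decision boundary as comparing connectivity-layer InChI strings.
    """
    ref = reference_graph_with_hydrogens(reference)
    obs = nx.Graph()
    for i, el in enumerate(elements):
        obs.add_node(i, element=el)
    obs.add_edges_from(observed_bonds)
    if ref.number_of_nodes() != obs.number_of_nodes():
        return True
    return not nx.is_isomorphic(
        ref, obs, node_match=lambda a, b: a["element"] == b["element"]
    )


@dataclass(frozen=True)
class FiltrationResult:
    kept: tuple[str, ...]
    discarded: tuple[str, ...]
    flagged: tuple[str, ...]  # kept, but excluded from aIP/aEA analyses


def apply_filtration(
    records: Sequence[GeometryRecord],
    references: dict[str, "object"],
) -> FiltrationResult:
    """Apply the discard/flag rules over grouped optimization records.

    A molecule is discarded when any of its records rearranged; otherwise
    it is kept, and flagged when any cationic/anionic record carries an
    imaginary frequency.  Molecules with fewer than six records are
    evaluated on what is available (with a warning).
    """
    grouped: dict[str, list[GeometryRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.molecule_id, []).append(rec)

    kept, discarded, flagged = [], [], []
    for mol_id in sorted(grouped):
        recs = grouped[mol_id]
        if len(recs) < len(METHODS) * len(CHARGE_STATES):
            logger.warning(
                "molecule %s has only %d of %d records; evaluating available ones",
                mol_id,
                len(recs),
                len(METHODS) * len(CHARGE_STATES),
            )
        reference = references[mol_id]
        rearranged = False
        for rec in recs:
            bonds = perceive_bonds(rec.coordinates)
            elements = tuple(c[0] for c in rec.coordinates)
            if detect_rearrangement(reference, elements, bonds):
                logger.info(
                    "discarding %s: %s/%s record rearranged",
                    mol_id,
                    rec.method,
                    rec.charge_state,
                )
                rearranged = True
                break
        if rearranged:
            discarded.append(mol_id)
            continue
        kept.append(mol_id)
        if any(
            rec.imaginary_freq and rec.charge_state in ("cation", "anion")
            for rec in recs
        ):
            flagged.append(mol_id)
    return FiltrationResult(tuple(kept), tuple(discarded), tuple(flagged))


# ---------------------------------------------------------------------------
# multi-structure XYZ I/O (plain text)


def write_xyz_records(records: Sequence[GeometryRecord]) -> str:
    """Concatenated-XYZ text; the comment line carries the record metadata."""
    blocks = []
    for rec in records:
        lines = [
            str(len(rec.coordinates)),
            f"{rec.molecule_id} method={rec.method} charge={rec.charge_state} "
            f"imag={int(rec.imaginary_freq)}",
        ]
        for el, x, y, z in rec.coordinates:
            lines.append(f"{el} {x:.6f} {y:.6f} {z:.6f}")
        blocks.append("\n".join(lines))
    return "\n".join(blocks) + "\n"


def read_xyz_records(text: str) -> list[GeometryRecord]:
    """Parse concatenated-XYZ text written by :func:`write_xyz_records`."""
    lines = text.splitlines()
    records = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        natoms = int(lines[i].strip())
        comment = lines[i + 1].split()
        mol_id = comment[0]
        meta = dict(tok.split("=", 1) for tok in comment[1:] if "=" in tok)
        coords = []
        for line in lines[i + 2 : i + 2 + natoms]:
            el, x, y, z = line.split()
            coords.append((el, float(x), float(y), float(z)))
        records.append(
            GeometryRecord(
                molecule_id=mol_id,
                charge_state=meta.get("charge", "neutral"),
                method=meta.get("method", "dft"),
                coordinates=tuple(coords),
                imaginary_freq=bool(int(meta.get("imag", "0"))),
            )
        )
        i += 2 + natoms
    return records
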