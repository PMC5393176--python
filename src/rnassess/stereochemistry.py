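"""Steric clash detection and the per-1000-atom clash score.

A desk-scale approximation of probe-style clash scoring: heavy atoms only,
fixed van der Waals radii, overlap >= 0.4 A counts as a clash.  Pairs that
are covalently bonded or within three bonds of each other are excluded, as
are the donor-acceptor contacts of annotated base pairs (hydrogen bonds are
not clashes).  Not a MolProbity replacement: no hydrogen placement, no
probe dots.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import annotation
from .structure_io import ResidueKey, Structure

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80}
DEFAULT_RADIUS = 1.70

BOND_INFER_MAX = 1.8   # A; heavy-atom pairs closer than this are bonded

#: standard intra-nucleotide connectivity (sugar-phosphate + base rings)
_SUGAR_BONDS = (("P", "OP1"), ("P", "OP2"), ("P", "O5'"), ("O5'", "C5'"),
                ("C5'", "C4'"), ("C4'", "O4'"), ("C4'", "C3'"), ("C3'", "O3'"),
                ("C3'", "C2'"), ("C2'", "O2'"), ("C2'", "C1'"), ("C1'", "O4'"))
_BASE_BONDS = {
    "A": (("C1'", "N9"), ("N9", "C8"), ("C8", "N7"), ("N7", "C5"),
          ("C5", "C6"), ("C6", "N6"), ("C6", "N1"), ("N1", "C2"),
          ("C2", "N3"), ("N3", "C4"), ("C4", "C5"), ("C4", "N9")),
    "G": (("C1'", "N9"), ("N9", "C8"), ("C8", "N7"), ("N7", "C5"),
          ("C5", "C6"), ("C6", "O6"), ("C6", "N1"), ("N1", "C2"),
          ("C2", "N2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"),
          ("C4", "N9")),
    "C": (("C1'", "N1"), ("N1", "C2"), ("C2", "O2"), ("C2", "N3"),
          ("N3", "C4"), ("C4", "N4"), ("C4", "C5"), ("C5", "C6"),
          ("C6", "N1")),
    "U": (("C1'", "N1"), ("N1", "C2"), ("C2", "O2"), ("C2", "N3"),
          ("N3", "C4"), ("C4", "O4"), ("C4", "C5"), ("C5", "C6"),
          ("C6", "N1")),
}

AtomRef = tuple[ResidueKey, str]


@dataclass(frozen=True)
class Clash:
    atom_a: AtomRef
    atom_b: AtomRef
    distance: float
    overlap: float


@dataclass
class ClashReport:
    clashes: list[Clash]
    n_atoms: int

    @property
    def score(self) -> Optional[float]:
        """Clashes per 1000 heavy atoms; None for an empty structure."""
        if self.n_atoms == 0:
            return None
        return 1000.0 * len(self.clashes) / self.n_atoms

    def to_tsv(self) -> str:
        lines = ["atom_a\tatom_b\tdistance\toverlap"]
        for c in self.clashes:
            lines.append(f"{_fmt(c.atom_a)}\t{_fmt(c.atom_b)}"
                         f"\t{c.distance:.3f}\t{c.overlap:.3f}")
        return "\n".join(lines) + "\n"


def _fmt(ref: AtomRef) -> str:
    (chain, num, icode), name = ref
    return f"{chain}:{num}{icode or ''}:{name}"


def _heavy_atoms(structure: Structure):
    atoms = []
    for res in structure.residues():
        for a in res.atoms:
            if not a.is_hydrogen:
                atoms.append((res, a))
    return atoms


def _bond_neighbors(structure: Structure, atoms) -> list[set[int]]:
    """Adjacency from the standard connectivity table plus a distance
    fallback for residues without a template (ligands, proteins)."""
    index: dict[AtomRef, int] = {}
    for i, (res, a) in enumerate(atoms):
        index[(res.key, a.name)] = i
    neighbors: list[set[int]] = [set() for _ in atoms]

    def link(ka: AtomRef, kb: AtomRef) -> None:
        ia, ib = index.get(ka), index.get(kb)
        if ia is not None and ib is not None:
            neighbors[ia].add(ib)
            neighbors[ib].add(ia)

    prev_by_chain: dict[str, ResidueKey] = {}
    for _, residues in structure.chains:
        prev: Optional[ResidueKey] = None
        for res in residues:
            parent = res.standard_parent
            if res.is_nucleotide:
                for a1, a2 in _SUGAR_BONDS + _BASE_BONDS[parent]:
                    link((res.key, a1), (res.key, a2))
                if prev is not None:
                    link((prev, "O3'"), (res.key, "P"))
                prev = res.key
            else:
                prev = None

    # distance fallback (covers ligands, proteins, nonstandard atoms)
    cells: dict[tuple[int, int, int], list[int]] = {}
    inv = 1.0 / BOND_INFER_MAX
    for i, (res, a) in enumerate(atoms):
        cell = tuple(np.floor(a.position * inv).astype(int))
        cells.setdefault(cell, []).append(i)
    for cell, members in cells.items():
        for d in itertools.product((-1, 0, 1), repeat=3):
            other = (cell[0] + d[0], cell[1] + d[1], cell[2] + d[2])
            for i in members:
                for j in cells.get(other, ()):
                    if j <= i or j in neighbors[i]:
                        continue
                    if np.linalg.norm(atoms[i][1].position -
                                      atoms[j][1].position) < BOND_INFER_MAX:
                        neighbors[i].add(j)
                        neighbors[j].add(i)
    return neighbors


def _excluded_through_bonds(neighbors, i: int, j: int) -> bool:
    """True when i and j are within three covalent bonds (1-2, 1-3, 1-4)."""
    ni = neighbors[i]
    if j in ni:
        return True
    nj = neighbors[j]
    if ni & nj:
        return True
    for m in ni:
        if neighbors[m] & nj:
            return True
    return False


def find_clashes(structure: Structure, threshold: float = 0.4,
                 base_pairs=None) -> list[Clash]:
    """All heavy-atom clash pairs (vdW overlap >= threshold).

    Bonded, 1-3 and 1-4 pairs are excluded (MolProbity-style through-bond
    rule), as are donor-acceptor contacts of annotated base pairs.
    """
    atoms = _heavy_atoms(structure)
    if not atoms:
        return []
    neighbors = _bond_neighbors(structure, atoms)
    if base_pairs is None:
        base_pairs = annotation.detect_base_pairs(structure)
    paired: set[frozenset[ResidueKey]] = {
        frozenset({bp.i, bp.j}) for bp in base_pairs}

    radii = np.array([VDW_RADII.get(a.element, DEFAULT_RADIUS)
                      for _, a in atoms])
    coords = np.array([a.position for _, a in atoms])
    max_r = float(radii.max())
    cutoff = 2 * max_r  # largest distance that can still overlap

    cells: dict[tuple[int, int, int], list[int]] = {}
    inv = 1.0 / cutoff
    for i, pos in enumerate(coords):
        cells.setdefault(tuple(np.floor(pos * inv).astype(int)), []).append(i)

    clashes = []
    for cell, members in cells.items():
        for d in itertools.product((-1, 0, 1), repeat=3):
            other = (cell[0] + d[0], cell[1] + d[1], cell[2] + d[2])
            if other < cell:
                continue
            for i in members:
                for j in cells.get(other, ()):
                    if other == cell and j <= i:
                        continue
                    dist = float(np.linalg.norm(coords[i] - coords[j]))
                    overlap = radii[i] + radii[j] - dist
                    if overlap < threshold:
                        continue
                    if _excluded_through_bonds(neighbors, i, j):
                        continue
                    res_i, atom_i = atoms[i]
                    res_j, atom_j = atoms[j]
                    if (frozenset({res_i.key, res_j.key}) in paired
                            and _is_hbond_pair(res_i, atom_i, res_j, atom_j)):
                        continue
                    a, b = sorted([(res_i.key, atom_i.name),
                                   (res_j.key, atom_j.name)])
                    clashes.append(Clash(atom_a=a, atom_b=b,
                                         distance=dist, overlap=overlap))
    clashes.sort(key=lambda c: (c.atom_a, c.atom_b))
    return clashes


def _is_hbond_pair(res_i, atom_i, res_j, atom_j) -> bool:
    pi, pj = res_i.standard_parent, res_j.standard_parent
    if pi is None or pj is None:
        return False
    don_i = annotation.DONOR_ATOMS.get(pi, set())
    acc_i = annotation.ACCEPTOR_ATOMS.get(pi, set())
    don_j = annotation.DONOR_ATOMS.get(pj, set())
    acc_j = annotation.ACCEPTOR_ATOMS.get(pj, set())
    return ((atom_i.name in don_i and atom_j.name in acc_j) or
            (atom_j.name in don_j and atom_i.name in acc_i))


def clash_score(structure: Structure, threshold: float = 0.4) -> ClashReport:
    """Clash report with score = 1000 x clashes / heavy atoms."""
    atoms = _heavy_atoms(structure)
    clashes = find_clashes(structure, threshold=threshold) if atoms else []
    return ClashReport(clashes=clashes, n_atoms=len(atoms))
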