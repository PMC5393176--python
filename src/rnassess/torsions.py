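"""Backbone/glycosidic torsion angles and the torsion-space similarity score
(circular mean of per-angle differences, in degrees)."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .structure_io import Residue, ResidueKey, Structure

ANGLE_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi")

#: atom quadruples as (residue offset, atom name)
_BACKBONE_DEFS = {
    "alpha": ((-1, "O3'"), (0, "P"), (0, "O5'"), (0, "C5'")),
    "beta": ((0, "P"), (0, "O5'"), (0, "C5'"), (0, "C4'")),
    "gamma": ((0, "O5'"), (0, "C5'"), (0, "C4'"), (0, "C3'")),
    "delta": ((0, "C5'"), (0, "C4'"), (0, "C3'"), (0, "O3'")),
    "epsilon": ((0, "C4'"), (0, "C3'"), (0, "O3'"), (1, "P")),
    "zeta": ((0, "C3'"), (0, "O3'"), (1, "P"), (1, "O5'")),
}
_CHI_PURINE = ((0, "O4'"), (0, "C1'"), (0, "N9"), (0, "C4"))
_CHI_PYRIMIDINE = ((0, "O4'"), (0, "C1'"), (0, "N1"), (0, "C2"))

_COLLINEAR_EPS = 1e-7


def dihedral(p0, p1, p2, p3) -> Optional[float]:
    """Signed dihedral in degrees, (-180, 180]; None when degenerate."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        return None
    b1u = b1 / nb1
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    if np.linalg.norm(v) < _COLLINEAR_EPS or np.linalg.norm(w) < _COLLINEAR_EPS:
        return None  # collinear input, torsion undefined
    ang = float(np.degrees(np.arctan2(np.dot(np.cross(b1u, v), w), np.dot(v, w))))
    if ang <= -180.0:
        ang += 360.0
    return ang


@dataclass
class TorsionProfile:
    """Per-residue torsion tuples; None marks an undefined angle."""
    angles: dict[ResidueKey, dict[str, Optional[float]]]

    def keys(self):
        return self.angles.keys()

    def get(self, key: ResidueKey, name: str) -> Optional[float]:
        return self.angles.get(key, {}).get(name)

    def shifted(self, delta: float) -> "TorsionProfile":
        out = {}
        for k, row in self.angles.items():
            out[k] = {nm: (None if v is None else _wrap(v + delta))
                      for nm, v in row.items()}
        return TorsionProfile(out)

    def to_tsv(self) -> str:
        lines = ["residue\t" + "\t".join(ANGLE_NAMES)]
        for key, row in self.angles.items():
            cells = ["NA" if row[nm] is None else f"{row[nm]:.2f}"
                     for nm in ANGLE_NAMES]
            chain, num, icode = key
            lines.append(f"{chain}:{num}{icode or ''}\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"


def _wrap(angle: float) -> float:
    a = ((angle + 180.0) % 360.0) - 180.0
    return 180.0 if a == -180.0 else a


def _chain_neighbors(structure: Structure) -> dict[ResidueKey, dict[int, Residue]]:
    nbr: dict[ResidueKey, dict[int, Residue]] = {}
    for _, residues in structure.chains:
        nts = [r for r in residues if r.is_nucleotide]
        for i, r in enumerate(nts):
            nbr[r.key] = {0: r}
            if i > 0:
                nbr[r.key][-1] = nts[i - 1]
            if i + 1 < len(nts):
                nbr[r.key][1] = nts[i + 1]
    return nbr


def torsions(structure: Structure,
             keys: Optional[Iterable[ResidueKey]] = None) -> TorsionProfile:
    """Standard torsion profile (alpha..zeta, chi) for nucleotides.

    Angles whose defining atoms are absent (chain termini, unresolved atoms)
    are None; 5'-terminal residues have no alpha, 3'-terminal ones no
    epsilon/zeta.
    """
    neighbors = _chain_neighbors(structure)
    wanted = set(keys) if keys is not None else None
    profile: dict[ResidueKey, dict[str, Optional[float]]] = {}
    for key, ring in neighbors.items():
        if wanted is not None and key not in wanted:
            continue
        res = ring[0]
        row: dict[str, Optional[float]] = {}
        for name in ANGLE_NAMES:
            if name == "chi":
                parent = res.standard_parent
                quad = _CHI_PURINE if parent in ("A", "G") else _CHI_PYRIMIDINE
            else:
                quad = _BACKBONE_DEFS[name]
            pts = []
            ok = True
            for off, atom_name in quad:
                owner = ring.get(off)
                atom = owner.atom(atom_name) if owner is not None else None
                if atom is None:
                    ok = False
                    break
                pts.append(atom.position)
            row[name] = dihedral(*pts) if ok else None
        profile[key] = row
    return TorsionProfile(profile)


def circular_diff(a: float, b: float) -> float:
    """Smaller arc between two angles in degrees, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


@dataclass
class MCQResult:
    mcq: Optional[float]     # degrees in [0, 180]; None when nothing compares
    n_compared: int
    n_penalized: int


def mcq(model: TorsionProfile, reference: TorsionProfile,
        angle_names: Iterable[str] = ANGLE_NAMES,
        penalty: float = 180.0) -> MCQResult:
    """Circular mean of per-angle differences between two torsion profiles.

    Slots where both sides are defined contribute their circular difference;
    slots defined on exactly one side contribute the penalty (default 180
    degrees); slots undefined on both sides are excluded.
    """
    diffs = []
    n_penalized = 0
    keys = set(model.keys()) | set(reference.keys())
    for key in keys:
        for name in angle_names:
            vm = model.get(key, name)
            vr = reference.get(key, name)
            if vm is None and vr is None:
                continue
            if vm is None or vr is None:
                diffs.append(penalty)
                n_penalized += 1
            else:
                diffs.append(circular_diff(vm, vr))
    if not diffs:
        return MCQResult(mcq=None, n_compared=0, n_penalized=0)
    rad = np.deg2rad(diffs)
    mean_angle = float(np.degrees(np.arctan2(np.mean(np.sin(rad)),
                                             np.mean(np.cos(rad)))))
    mean_angle = abs(_wrap(mean_angle))
    return MCQResult(mcq=mean_angle, n_compared=len(diffs),
                     n_penalized=n_penalized)
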