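"""Synthetic ground-truth structures and controlled degradations.

An idealized A-form duplex generator: planar standard-frame bases paired by
a two-fold flip, one shared ribose-phosphate template per residue, and
helical symmetry (twist 32.7 deg, rise 2.81 A, x-displacement -4.4 A,
base-pair inclination 27 deg).  The template coordinates were derived once
by least-squares closure of the O3'(i)-P(i+1) linkage under this symmetry
and are embedded as data; by construction the duplex is clash-free, every
Watson-Crick pair passes the annotation windows and consecutive residues
stack.

Degradations: i.i.d. Gaussian coordinate noise, a rigid hinge rotation of
all residues past a pivot, and a uniform torsion shift applied through an
internal-coordinate rebuild.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .structure_io import Atom, Residue, ResidueKey, Structure

TWIST_DEG = 32.7
RISE = 2.81
X_DISPLACEMENT = -4.4
Y_SHIFT = -0.10
INCLINATION_DEG = 27.0

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: planar base heavy atoms in the standard reference frame (z = 0)
BASE_TEMPLATES = {
    "A": {"N9": (-1.291, 4.498), "C8": (0.024, 4.897), "N7": (0.877, 3.902),
          "C5": (0.071, 2.771), "C6": (0.369, 1.398), "N6": (1.611, 0.909),
          "N1": (-0.668, 0.532), "C2": (-1.912, 1.023), "N3": (-2.320, 2.290),
          "C4": (-1.267, 3.124)},
    "G": {"N9": (-1.289, 4.551), "C8": (0.023, 4.962), "N7": (0.870, 3.969),
          "C5": (0.071, 2.833), "C6": (0.424, 1.460), "O6": (1.554, 0.955),
          "N1": (-0.700, 0.641), "C2": (-1.999, 1.087), "N2": (-2.949, 0.139),
          "N3": (-2.342, 2.364), "C4": (-1.265, 3.177)},
    "C": {"N1": (-1.285, 4.542), "C2": (-1.472, 3.158), "O2": (-2.628, 2.709),
          "N3": (-0.391, 2.344), "C4": (0.837, 2.868), "N4": (1.875, 2.027),
          "C5": (1.056, 4.275), "C6": (-0.023, 5.068)},
    "U": {"N1": (-1.284, 4.500), "C2": (-1.462, 3.131), "O2": (-2.563, 2.608),
          "N3": (-0.302, 2.397), "C4": (0.989, 2.884), "O4": (1.935, 2.094),
          "C5": (1.089, 4.311), "C6": (-0.024, 5.053)},
}

#: shared sugar-phosphate template in the base reference frame (see module
#: docstring; derived by closure optimization, frozen here as data)
SUGAR_TEMPLATE = {
    "O4'": (-2.9813, 6.1965, -1.1722),
    "C1'": (-2.4770, 5.3990, 0.0000),
    "C2'": (-3.6943, 5.2378, 0.9376),
    "C3'": (-4.8799, 5.1552, -0.0738),
    "C4'": (-4.4765, 6.1579, -1.1578),
    "O2'": (-3.8292, 6.3377, 1.8094),
    "O3'": (-6.2135, 4.7939, 0.2538),
    "C5'": (-5.2295, 6.1749, -2.4665),
    "O5'": (-4.2527, 6.9870, -3.1448),
    "P": (-3.5113, 6.9552, -4.5510),
    "OP1": (-3.7505, 8.2516, -5.2236),
    "OP2": (-2.6859, 5.7279, -4.6051),
}

#: in-plane shear applied to the pyrimidine base of an engineered G-U wobble
WOBBLE_SHIFT = np.array([1.9, -0.5, 0.0])

_BACKBONE_CHAIN = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")


class FixtureError(Exception):
    pass


@dataclass
class FixtureSpec:
    sequence: str
    kind: Literal["duplex", "two_domain"] = "duplex"
    seed: int = 0
    perturbation: Optional[dict] = None   # {"noise": sigma} | {"hinge": deg} | {"torsion_shift": deg}


@dataclass
class GroundTruth:
    wc_pairs: set[tuple[ResidueKey, ResidueKey]] = field(default_factory=set)
    stack_pairs: set[tuple[ResidueKey, ResidueKey]] = field(default_factory=set)
    torsions_used: dict[ResidueKey, dict[str, Optional[float]]] = field(default_factory=dict)
    domain_split: Optional[dict[str, list[ResidueKey]]] = None

    def to_json(self) -> str:
        def fk(key: ResidueKey) -> str:
            return f"{key[0]}:{key[1]}{key[2] or ''}"

        payload = {
            "wc_pairs": sorted([fk(a), fk(b)] for a, b in self.wc_pairs),
            "stack_pairs": sorted([fk(a), fk(b)] for a, b in self.stack_pairs),
            "torsions": {fk(k): v for k, v in self.torsions_used.items()},
        }
        if self.domain_split is not None:
            payload["domains"] = {name: [fk(k) for k in keys]
                                  for name, keys in self.domain_split.items()}
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# geometry helpers (self-contained so the generator stays independent of the
# metric modules it is used to test)


def _unit(v):
    return v / np.linalg.norm(v)


def _rot(axis, theta):
    axis = _unit(np.asarray(axis, float))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * K @ K


def _dihedral(p0, p1, p2, p3) -> Optional[float]:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1u = _unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        return None
    return float(np.degrees(np.arctan2(np.dot(np.cross(b1u, v), w),
                                       np.dot(v, w))))


def _angle(a, b, c) -> float:
    return float(np.degrees(np.arccos(
        np.clip(np.dot(_unit(a - b), _unit(c - b)), -1.0, 1.0))))


def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place the fourth atom of a torsion quadruple."""
    ang, tor = np.deg2rad(angle_deg), np.deg2rad(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    # component signs chosen so dihedral(a, b, c, placed) == torsion_deg
    d = bond * np.array([-np.cos(ang), np.sin(ang) * np.cos(tor),
                         np.sin(ang) * np.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


_RX = _rot([1.0, 0.0, 0.0], np.deg2rad(INCLINATION_DEG))
_FLIP = np.diag([1.0, -1.0, -1.0])
_D = np.array([X_DISPLACEMENT, Y_SHIFT, 0.0])


def _place(p: np.ndarray, level: int, strand: int) -> np.ndarray:
    """Base-frame point -> helix frame at a pairing level on strand 1 or 2."""
    q = _RX @ (np.asarray(p, float) + _D)
    if strand == 2:
        q = _FLIP @ q
    return _rot([0, 0, 1], np.deg2rad(TWIST_DEG) * level) @ q + np.array(
        [0.0, 0.0, RISE * level])


def _element(name: str) -> str:
    return name.lstrip("0123456789")[0]


# ---------------------------------------------------------------------------
# duplex generator


def build_duplex(sequence: str, seed: int = 0,
                 chain_ids: tuple[str, str] = ("A", "B"),
                 b_factor: float = 30.0,
                 mismatches: Optional[dict[int, str]] = None,
                 ) -> tuple[Structure, GroundTruth]:
    """Idealized A-form duplex for `sequence` (5'->3' strand 1).

    Strand 2 is the reverse complement unless `mismatches` substitutes the
    partner base at given strand-1 positions (1-based); a G-U substitution
    is placed with a wobble-like shear so it still hydrogen-bonds.  The
    ground truth lists the n constructed pairs and the 2(n-1) intra-strand
    neighbor stacks.  `seed` is accepted for interface uniformity; the
    construction itself is deterministic.
    """
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise FixtureError("sequence must have length >= 2")
    bad = set(sequence) - set("ACGU")
    if bad:
        raise FixtureError(f"non-ACGU characters in sequence: {sorted(bad)}")
    mismatches = mismatches or {}
    n = len(sequence)

    chains = []
    for strand, cid in ((1, chain_ids[0]), (2, chain_ids[1])):
        residues = []
        for j in range(1, n + 1):
            if strand == 1:
                base, level = sequence[j - 1], j - 1
            else:
                pos1 = n + 1 - j           # paired strand-1 position
                base = mismatches.get(pos1, COMPLEMENT[sequence[pos1 - 1]])
                level = pos1 - 1
            wobble = (strand == 2 and pos1 in mismatches
                      and frozenset({base, sequence[pos1 - 1]}) == frozenset({"G", "U"})
                      and base in "CU")
            atoms = []
            for name, xy in BASE_TEMPLATES[base].items():
                p = np.array([xy[0], xy[1], 0.0])
                if wobble:
                    p = p + WOBBLE_SHIFT
                atoms.append((name, _place(p, level, strand)))
            for name, xyz in SUGAR_TEMPLATE.items():
                if name == "C1'":
                    continue
                atoms.append((name, _place(np.asarray(xyz), level, strand)))
            # C1' comes from the sugar template too (identical for all bases)
            atoms.insert(0, ("C1'", _place(np.asarray(SUGAR_TEMPLATE["C1'"]),
                                           level, strand)))
            residues.append(Residue(
                chain_id=cid, seq_number=j, insertion_code="", res_name=base,
                atoms=[Atom(name=nm, element=_element(nm), position=pos,
                            occupancy=1.0, b_factor=b_factor)
                       for nm, pos in atoms]))
        chains.append((cid, residues))

    structure = Structure(id=f"duplex-{sequence}", chains=chains,
                          source_format="PDB")

    truth = GroundTruth()
    ca, cb = chain_ids
    for j in range(1, n + 1):
        truth.wc_pairs.add(((ca, j, ""), (cb, n + 1 - j, "")))
    for cid in chain_ids:
        for j in range(1, n):
            truth.stack_pairs.add(((cid, j, ""), (cid, j + 1, "")))
    truth.torsions_used = _measure_torsions(structure)
    return structure, truth


def _measure_torsions(structure: Structure) -> dict[ResidueKey, dict[str, Optional[float]]]:
    """Record the torsions actually realized by the construction."""
    defs = {
        "alpha": ((-1, "O3'"), (0, "P"), (0, "O5'"), (0, "C5'")),
        "beta": ((0, "P"), (0, "O5'"), (0, "C5'"), (0, "C4'")),
        "gamma": ((0, "O5'"), (0, "C5'"), (0, "C4'"), (0, "C3'")),
        "delta": ((0, "C5'"), (0, "C4'"), (0, "C3'"), (0, "O3'")),
        "epsilon": ((0, "C4'"), (0, "C3'"), (0, "O3'"), (1, "P")),
        "zeta": ((0, "C3'"), (0, "O3'"), (1, "P"), (1, "O5'")),
    }
    out: dict[ResidueKey, dict[str, Optional[float]]] = {}
    for _, residues in structure.chains:
        for i, res in enumerate(residues):
            row: dict[str, Optional[float]] = {}
            for name, quad in defs.items():
                pts = []
                ok = True
                for off, atom_name in quad:
                    idx = i + off
                    if not 0 <= idx < len(residues):
                        ok = False
                        break
                    atom = residues[idx].atom(atom_name)
                    if atom is None:
                        ok = False
                        break
                    pts.append(atom.position)
                row[name] = _dihedral(*pts) if ok else None
            n_name = "N9" if res.res_name in ("A", "G") else "N1"
            c_name = "C4" if res.res_name in ("A", "G") else "C2"
            quad = [res.atom("O4'"), res.atom("C1'"), res.atom(n_name),
                    res.atom(c_name)]
            row["chi"] = (_dihedral(*(a.position for a in quad))
                          if all(a is not None for a in quad) else None)
            out[res.key] = row
    return out


# ---------------------------------------------------------------------------
# perturbations


def perturb_noise(structure: Structure, sigma: float, seed: int = 0) -> Structure:
    """Add i.i.d. zero-mean Gaussian noise (std sigma, per coordinate)."""
    if sigma < 0:
        raise FixtureError("sigma must be >= 0")
    out = structure.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    for res in out.residues():
        for atom in res.atoms:
            atom.position = atom.position + rng.normal(0.0, sigma, size=3)
    return out


def perturb_hinge(structure: Structure, pivot: ResidueKey, angle: float,
                  axis=None, seed: int = 0,
                  ) -> tuple[Structure, dict[str, list[ResidueKey]]]:
    """Rigidly rotate every residue after `pivot` (within its chain) about an
    axis through the pivot's P atom.  Returns the new structure and the
    two-domain split."""
    out = structure.copy()
    chain = next((res_list for cid, res_list in out.chains if cid == pivot[0]),
                 None)
    if chain is None:
        raise FixtureError(f"no chain {pivot[0]!r}")
    idx = next((i for i, r in enumerate(chain) if r.key == pivot), None)
    if idx is None:
        raise FixtureError(f"no residue {pivot}")
    if idx == 0 or idx == len(chain) - 1:
        raise FixtureError("pivot must be interior to its chain")
    p_atom = chain[idx].atom("P")
    if p_atom is None:
        raise FixtureError(f"pivot {pivot} has no P atom")
    if axis is None:
        rng = np.random.default_rng(seed)
        axis = rng.normal(size=3)
    R = _rot(axis, np.deg2rad(angle))
    center = p_atom.position
    moved_keys = []
    for res in chain[idx + 1:]:
        moved_keys.append(res.key)
        for atom in res.atoms:
            atom.position = R @ (atom.position - center) + center
    fixed_keys = [r.key for r in out.residues() if r.key not in set(moved_keys)]
    return out, {"fixed": fixed_keys, "moved": moved_keys}


def perturb_torsions(structure: Structure, shift: float, seed: int = 0) -> Structure:
    """Rebuild each chain with every backbone torsion (and chi) shifted
    uniformly by `shift` degrees.

    Bond lengths and bond angles are kept exactly as measured from the
    input; the sugar ring and base ride rigidly on the rebuilt backbone,
    with the base additionally rotated about the glycosidic bond so chi
    shifts too.
    """
    out = structure.copy()
    for cid, residues in out.chains:
        nts = [r for r in residues if r.is_nucleotide]
        if len(nts) == 0:
            continue
        old = [{a.name: a.position.copy() for a in r.atoms} for r in nts]
        new: list[dict[str, np.ndarray]] = [dict() for _ in nts]
        first = old[0]
        for nm in ("P", "O5'", "C5'"):
            if nm not in first:
                raise FixtureError(
                    f"chain {cid}: first residue lacks {nm}; cannot rebuild")
            new[0][nm] = first[nm].copy()

        def put(i_tgt, name, refs, torsion_old):
            (ia, na), (ib, nb), (ic, nc) = refs
            a_old, b_old, c_old = old[ia][na], old[ib][nb], old[ic][nc]
            d_old = old[i_tgt][name]
            bond = float(np.linalg.norm(d_old - c_old))
            ang = _angle(b_old, c_old, d_old)
            a_new, b_new, c_new = new[ia][na], new[ib][nb], new[ic][nc]
            new[i_tgt][name] = _nerf(a_new, b_new, c_new, bond, ang,
                                     torsion_old + shift)

        for i in range(len(nts)):
            tor = lambda *pts: _dihedral(*pts)
            o = old[i]
            put(i, "C4'", ((i, "P"), (i, "O5'"), (i, "C5'")),
                tor(o["P"], o["O5'"], o["C5'"], o["C4'"]))
            put(i, "C3'", ((i, "O5'"), (i, "C5'"), (i, "C4'")),
                tor(o["O5'"], o["C5'"], o["C4'"], o["C3'"]))
            put(i, "O3'", ((i, "C5'"), (i, "C4'"), (i, "C3'")),
                tor(o["C5'"], o["C4'"], o["C3'"], o["O3'"]))
            if i + 1 < len(nts):
                nxt = old[i + 1]
                put(i + 1, "P", ((i, "C4'"), (i, "C3'"), (i, "O3'")),
                    tor(o["C4'"], o["C3'"], o["O3'"], nxt["P"]))
                put(i + 1, "O5'", ((i, "C3'"), (i, "O3'"), (i + 1, "P")),
                    tor(o["C3'"], o["O3'"], nxt["P"], nxt["O5'"]))
                put(i + 1, "C5'", ((i, "O3'"), (i + 1, "P"), (i + 1, "O5'")),
                    tor(o["O3'"], nxt["P"], nxt["O5'"], nxt["C5'"]))

        # ride the sugar ring + base on the rebuilt backbone
        for i, res in enumerate(nts):
            R_s, t_s = _rigid_from_triplet(
                [old[i]["C5'"], old[i]["C4'"], old[i]["C3'"]],
                [new[i]["C5'"], new[i]["C4'"], new[i]["C3'"]])
            for name, pos in old[i].items():
                if name in _BACKBONE_CHAIN or name in ("OP1", "OP2"):
                    continue
                new[i][name] = R_s @ pos + t_s
            if "OP1" in old[i] or "OP2" in old[i]:
                R_p, t_p = _rigid_from_triplet(
                    [old[i]["P"], old[i]["O5'"], old[i]["C5'"]],
                    [new[i]["P"], new[i]["O5'"], new[i]["C5'"]])
                for name in ("OP1", "OP2"):
                    if name in old[i]:
                        new[i][name] = R_p @ old[i][name] + t_p
            # chi shift: spin base atoms about the glycosidic bond
            n_name = "N9" if res.standard_parent in ("A", "G") else "N1"
            if "C1'" in new[i] and n_name in new[i]:
                axis = new[i][n_name] - new[i]["C1'"]
                R_chi = _rot(axis, np.deg2rad(shift))
                center = new[i]["C1'"]
                base_names = set(BASE_TEMPLATES[res.standard_parent])
                for name in base_names:
                    if name in new[i]:
                        new[i][name] = R_chi @ (new[i][name] - center) + center
            for atom in res.atoms:
                if atom.name in new[i]:
                    atom.position = new[i][atom.name]
    return out


def _rigid_from_triplet(old_pts, new_pts):
    """Rotation + translation mapping three old points onto three new ones."""
    def frame(p0, p1, p2):
        e1 = _unit(p1 - p0)
        v = p2 - p0
        e2 = _unit(v - np.dot(v, e1) * e1)
        return np.column_stack([e1, e2, np.cross(e1, e2)])

    Fo = frame(*[np.asarray(p, float) for p in old_pts])
    Fn = frame(*[np.asarray(p, float) for p in new_pts])
    R = Fn @ Fo.T
    t = np.asarray(new_pts[0], float) - R @ np.asarray(old_pts[0], float)
    return R, t


# ---------------------------------------------------------------------------
# dispatcher


def build_fixture(spec: FixtureSpec) -> tuple[Structure, GroundTruth]:
    structure, truth = build_duplex(spec.sequence, seed=spec.seed)
    if spec.kind == "two_domain":
        pivot = ("A", max(2, len(spec.sequence) // 2), "")
        angle = (spec.perturbation or {}).get("hinge", 30.0)
        structure, split = perturb_hinge(structure, pivot, angle,
                                         seed=spec.seed)
        truth.domain_split = split
        return structure, truth
    if spec.perturbation:
        if "noise" in spec.perturbation:
            structure = perturb_noise(structure, spec.perturbation["noise"],
                                      seed=spec.seed)
        elif "hinge" in spec.perturbation:
            pivot = ("A", max(2, len(spec.sequence) // 2), "")
            structure, split = perturb_hinge(
                structure, pivot, spec.perturbation["hinge"], seed=spec.seed)
            truth.domain_split = split
        elif "torsion_shift" in spec.perturbation:
            structure = perturb_torsions(
                structure, spec.perturbation["torsion_shift"], seed=spec.seed)
    return structure, truth
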