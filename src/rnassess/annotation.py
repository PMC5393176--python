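"""Base-pair and stacking annotation.

Base pairs are detected geometrically (hydrogen-bond-distance contacts
between donor/acceptor heavy atoms, near-coplanar rings, small vertical
offset) and classified by interacting edge (Watson-Crick / Hoogsteen /
Sugar) and glycosidic orientation (cis / trans).  Stacking uses ring
centroid/normal geometry.  The thresholds are conventional values, kept in
:class:`AnnotationConfig` so they can be overridden.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .structure_io import (BASE_RING_ATOMS, Residue, ResidueKey, Structure)

PairKey = tuple[ResidueKey, ResidueKey]

#: edge membership of base heavy atoms (used for majority-vote edge calls)
EDGE_ATOMS = {
    "A": {"WC": {"N1", "C2", "N6"},
          "Hoogsteen": {"N6", "N7", "C8"},
          "Sugar": {"N3", "C2", "O2'"}},
    "G": {"WC": {"N1", "N2", "O6"},
          "Hoogsteen": {"O6", "N7", "C8"},
          "Sugar": {"N2", "N3", "O2'"}},
    "C": {"WC": {"N3", "N4", "O2"},
          "Hoogsteen": {"N4", "C5"},
          "Sugar": {"O2", "O2'"}},
    "U": {"WC": {"N3", "O2", "O4"},
          "Hoogsteen": {"O4", "C5"},
          "Sugar": {"O2", "O2'"}},
}

DONOR_ATOMS = {
    "A": {"N6", "O2'"},
    "G": {"N1", "N2", "O2'"},
    "C": {"N4", "O2'"},
    "U": {"N3", "O2'"},
}
ACCEPTOR_ATOMS = {
    "A": {"N1", "N3", "N7", "O2'"},
    "G": {"O6", "N3", "N7", "O2'"},
    "C": {"O2", "N3", "O2'"},
    "U": {"O2", "O4", "O2'"},
}

GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}

CANONICAL_PARENTS = {frozenset({"A", "U"}), frozenset({"G", "C"}),
                     frozenset({"G", "U"})}


class AnnotationError(Exception):
    pass


class FrameUndefined(AnnotationError):
    """Residue lacks enough base ring atoms for a plane fit."""


@dataclass(frozen=True)
class AnnotationConfig:
    pair_gate: float = 6.5          # max ring-centroid distance, A
    hbond_min: float = 2.4          # donor-acceptor heavy-atom window, A
    hbond_max: float = 3.4
    min_contacts: int = 2
    plane_angle_max: float = 65.0   # deg; or >= 180 - this
    pair_vertical_max: float = 2.5  # A along mean normal
    stack_dist_max: float = 5.5
    stack_normal_max: float = 30.0
    stack_vertical_min: float = 2.0
    stack_vertical_max: float = 4.5
    stack_horizontal_max: float = 3.5
    strict_watson_crick: bool = False  # exclude G-U wobble from the wc set


DEFAULT_CONFIG = AnnotationConfig()


@dataclass
class BaseFrame:
    origin: np.ndarray        # ring centroid
    normal: np.ndarray        # unit plane normal, right-handed wrt atom order
    glycosidic_vector: np.ndarray  # unit C1' -> N1/N9


@dataclass(frozen=True)
class BasePair:
    i: ResidueKey
    j: ResidueKey
    edge_i: str
    edge_j: str
    orientation: str          # "cis" | "trans"
    is_canonical: bool

    @property
    def key(self) -> PairKey:
        return (self.i, self.j)


@dataclass(frozen=True)
class StackPair:
    i: ResidueKey
    j: ResidueKey

    @property
    def key(self) -> PairKey:
        return (self.i, self.j)


@dataclass
class InteractionSet:
    wc: frozenset[PairKey]
    nwc: frozenset[PairKey]
    stack: frozenset[PairKey]
    pairs: list[BasePair] = field(default_factory=list)

    @property
    def all(self) -> frozenset[PairKey]:
        return self.wc | self.nwc

    def restricted(self, keys: Iterable[ResidueKey]) -> "InteractionSet":
        ks = set(keys)
        keep = lambda s: frozenset(p for p in s if p[0] in ks and p[1] in ks)
        return InteractionSet(
            wc=keep(self.wc), nwc=keep(self.nwc), stack=keep(self.stack),
            pairs=[p for p in self.pairs if p.i in ks and p.j in ks])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def base_frame(residue: Residue) -> BaseFrame:
    """Least-squares base-plane frame of a nucleotide.

    The normal comes from an SVD plane fit, oriented to agree with the
    right-hand rule applied to the ring atoms in canonical order; the origin
    is the unweighted ring-atom centroid.
    """
    parent = residue.standard_parent
    ring_names = BASE_RING_ATOMS.get(parent or "", ())
    ring = [residue.atom(nm) for nm in ring_names]
    ring = [a for a in ring if a is not None]
    if len(ring) < 5:
        raise FrameUndefined(
            f"residue {residue.key}: {len(ring)} ring atoms present")
    coords = np.array([a.position for a in ring])
    origin = coords.mean(axis=0)
    centered = coords - origin
    normal = np.linalg.svd(centered)[2][-1]
    # orient by the atom-order right-hand rule (Newell's method)
    rh = np.zeros(3)
    for k in range(len(coords)):
        rh += np.cross(centered[k], centered[(k + 1) % len(coords)])
    if np.dot(normal, rh) < 0:
        normal = -normal
    c1 = residue.atom("C1'")
    n_attach = residue.atom(GLYCOSIDIC_N[parent])
    if c1 is not None and n_attach is not None:
        gly = _unit(n_attach.position - c1.position)
    else:
        gly = _unit(origin - coords[0]) if np.linalg.norm(origin - coords[0]) > 0 else normal
    return BaseFrame(origin=origin, normal=_unit(normal), glycosidic_vector=gly)


def _frames(structure: Structure) -> dict[ResidueKey, tuple[Residue, BaseFrame]]:
    out = {}
    for res in structure.nucleotides():
        try:
            out[res.key] = (res, base_frame(res))
        except FrameUndefined:
            continue
    return out


def _grid_candidates(frames: dict[ResidueKey, tuple[Residue, BaseFrame]],
                     cutoff: float):
    """Residue-key pairs whose frame origins lie within `cutoff`."""
    cells: dict[tuple[int, int, int], list[ResidueKey]] = {}
    for key, (_, fr) in frames.items():
        cell = tuple(np.floor(fr.origin / cutoff).astype(int))
        cells.setdefault(cell, []).append(key)
    seen = set()
    for cell, members in cells.items():
        for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3):
            other = (cell[0] + dx, cell[1] + dy, cell[2] + dz)
            for ki in members:
                for kj in cells.get(other, ()):
                    if ki == kj:
                        continue
                    pk = (ki, kj) if ki < kj else (kj, ki)
                    if pk in seen:
                        continue
                    seen.add(pk)
                    oi = frames[pk[0]][1].origin
                    oj = frames[pk[1]][1].origin
                    if np.linalg.norm(oi - oj) <= cutoff:
                        yield pk


def _hbond_contacts(res_i: Residue, res_j: Residue,
                    cfg: AnnotationConfig) -> list[tuple[str, str]]:
    pi, pj = res_i.standard_parent, res_j.standard_parent
    contacts = []
    for donors, acceptors, swap in (
            (DONOR_ATOMS[pi], ACCEPTOR_ATOMS[pj], False),
            (DONOR_ATOMS[pj], ACCEPTOR_ATOMS[pi], True)):
        src, dst = (res_j, res_i) if swap else (res_i, res_j)
        for dn in donors:
            da = src.atom(dn)
            if da is None:
                continue
            for an in acceptors:
                aa = dst.atom(an)
                if aa is None:
                    continue
                d = float(np.linalg.norm(da.position - aa.position))
                if cfg.hbond_min <= d <= cfg.hbond_max:
                    contacts.append((an, dn) if swap else (dn, an))
    return contacts


def _edge_of(parent: str, atom_names: Iterable[str]) -> str:
    counts = {edge: sum(1 for nm in atom_names if nm in members)
              for edge, members in EDGE_ATOMS[parent].items()}
    # deterministic tie-break: WC > Hoogsteen > Sugar
    order = ("WC", "Hoogsteen", "Sugar")
    return max(order, key=lambda e: (counts[e], -order.index(e)))


def _classify(res_i: Residue, res_j: Residue,
              fr_i: BaseFrame, fr_j: BaseFrame,
              contacts: list[tuple[str, str]]) -> BasePair:
    edge_i = _edge_of(res_i.standard_parent, [c[0] for c in contacts])
    edge_j = _edge_of(res_j.standard_parent, [c[1] for c in contacts])
    axis = _unit(fr_j.origin - fr_i.origin)
    # cis when both glycosidic bonds point to the same side of the pair axis:
    # compare signs of (axis x gly) . n for a shared reference normal
    s_i = float(np.dot(np.cross(axis, fr_i.glycosidic_vector), fr_i.normal))
    s_j = float(np.dot(np.cross(axis, fr_j.glycosidic_vector), fr_i.normal))
    orientation = "cis" if s_i * s_j > 0 else "trans"
    parents = frozenset({res_i.standard_parent, res_j.standard_parent})
    canonical = (edge_i == "WC" and edge_j == "WC" and orientation == "cis"
                 and parents in CANONICAL_PARENTS)
    return BasePair(i=res_i.key, j=res_j.key, edge_i=edge_i, edge_j=edge_j,
                    orientation=orientation, is_canonical=canonical)


def detect_base_pairs(structure: Structure,
                      config: AnnotationConfig = DEFAULT_CONFIG) -> list[BasePair]:
    frames = _frames(structure)
    pairs = []
    for ki, kj in sorted(_grid_candidates(frames, config.pair_gate)):
        res_i, fr_i = frames[ki]
        res_j, fr_j = frames[kj]
        contacts = _hbond_contacts(res_i, res_j, config)
        if len(contacts) < config.min_contacts:
            continue
        cosang = abs(float(np.dot(fr_i.normal, fr_j.normal)))
        if cosang < np.cos(np.deg2rad(config.plane_angle_max)):
            continue
        mean_normal = _unit(fr_i.normal +
                            np.sign(np.dot(fr_i.normal, fr_j.normal)) * fr_j.normal)
        vertical = abs(float(np.dot(fr_j.origin - fr_i.origin, mean_normal)))
        if vertical > config.pair_vertical_max:
            continue
        pairs.append(_classify(res_i, res_j, fr_i, fr_j, contacts))
    return pairs


def detect_stacking(structure: Structure,
                    config: AnnotationConfig = DEFAULT_CONFIG,
                    base_pairs: Optional[list[BasePair]] = None) -> list[StackPair]:
    frames = _frames(structure)
    if base_pairs is None:
        base_pairs = detect_base_pairs(structure, config)
    paired = {bp.key for bp in base_pairs}
    stacks = []
    for ki, kj in sorted(_grid_candidates(frames, config.stack_dist_max)):
        if (ki, kj) in paired:
            continue
        fr_i, fr_j = frames[ki][1], frames[kj][1]
        dvec = fr_j.origin - fr_i.origin
        dist = float(np.linalg.norm(dvec))
        if dist > config.stack_dist_max:
            continue
        cosang = abs(float(np.dot(fr_i.normal, fr_j.normal)))
        if cosang < np.cos(np.deg2rad(config.stack_normal_max)):
            continue
        mean_normal = _unit(fr_i.normal +
                            np.sign(np.dot(fr_i.normal, fr_j.normal)) * fr_j.normal)
        vertical = abs(float(np.dot(dvec, mean_normal)))
        if not (config.stack_vertical_min <= vertical <= config.stack_vertical_max):
            continue
        horizontal = float(np.sqrt(max(dist ** 2 - vertical ** 2, 0.0)))
        if horizontal > config.stack_horizontal_max:
            continue
        stacks.append(StackPair(i=ki, j=kj))
    return stacks


def interaction_sets(structure: Structure,
                     config: AnnotationConfig = DEFAULT_CONFIG) -> InteractionSet:
    """Partition detected base pairs into WC / non-WC sets, plus stacks.

    A pair lands in `wc` when it is cis WC/WC with canonical parents
    (including the G-U wobble unless `strict_watson_crick`).
    """
    base_pairs = detect_base_pairs(structure, config)
    wc, nwc = set(), set()
    for bp in base_pairs:
        in_wc = bp.is_canonical
        if config.strict_watson_crick and in_wc:
            parents = frozenset({_parent_of(structure, bp.i),
                                 _parent_of(structure, bp.j)})
            in_wc = parents != frozenset({"G", "U"})
        (wc if in_wc else nwc).add(bp.key)
    stacks = detect_stacking(structure, config, base_pairs=base_pairs)
    return InteractionSet(wc=frozenset(wc), nwc=frozenset(nwc),
                          stack=frozenset(s.key for s in stacks),
                          pairs=base_pairs)


def _parent_of(structure: Structure, key: ResidueKey) -> Optional[str]:
    res = structure.residue(key)
    return res.standard_parent if res else None


# ---------------------------------------------------------------------------
# dot-bracket output


_BRACKETS = ([("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]
             + [(chr(ord("A") + k), chr(ord("a") + k)) for k in range(26)])


def to_dot_bracket(pairs: Iterable[tuple[int, int]], length: int) -> str:
    """Render 1-based position pairs as extended dot-bracket text.

    A maximal nested subset (greedy by ascending opening position, longest
    pair first on ties) uses "()"; pairs crossing it use "[]", further
    crossing levels "{}" and "<>".
    """
    norm = []
    used: set[int] = set()
    for i, j in pairs:
        if i == j:
            raise ValueError(f"self-pair at position {i}")
        i, j = (i, j) if i < j else (j, i)
        if not (1 <= i <= length and 1 <= j <= length):
            raise ValueError(f"pair ({i},{j}) outside 1..{length}")
        for p in (i, j):
            if p in used:
                raise ValueError(f"position {p} occurs in more than one pair")
            used.add(p)
        norm.append((i, j))
    norm.sort(key=lambda p: (p[0], -p[1]))

    levels: list[list[tuple[int, int]]] = []
    for pair in norm:
        placed = False
        for lvl in levels:
            if all(not _crossing(pair, q) for q in lvl):
                lvl.append(pair)
                placed = True
                break
        if not placed:
            levels.append([pair])
    if len(levels) > len(_BRACKETS):
        raise ValueError("more crossing levels than available bracket types")

    out = ["."] * length
    for depth, lvl in enumerate(levels):
        op, cl = _BRACKETS[depth]
        for i, j in lvl:
            out[i - 1] = op
            out[j - 1] = cl
    return "".join(out)


def _crossing(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (a, b), (c, d) = sorted((p, q))
    return a < c < b < d


def export_pairs_tsv(pairs: Iterable[BasePair]) -> str:
    rows = ["i\tj\tedge_i\tedge_j\torientation\tcanonical"]
    for bp in pairs:
        rows.append("\t".join([
            _fmt_key(bp.i), _fmt_key(bp.j), bp.edge_i, bp.edge_j,
            bp.orientation, "yes" if bp.is_canonical else "no"]))
    return "\n".join(rows) + "\n"


def _fmt_key(key: ResidueKey) -> str:
    chain, num, icode = key
    return f"{chain}:{num}{icode or ''}"


def relaxed_config(**overrides) -> AnnotationConfig:
    """Convenience constructor for threshold overrides."""
    return replace(DEFAULT_CONFIG, **overrides)
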