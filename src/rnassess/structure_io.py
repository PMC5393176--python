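"""Structure parsing, normalization and model/reference residue mapping.

Coordinates are read from PDB or mmCIF files into a light-weight structure
graph (chains -> residues -> atoms) that preserves author numbering, chain
order and residue order.  Only the first MODEL of multi-model files is kept,
alternate locations are resolved to the highest-occupancy conformer and
waters are dropped.  Hetero compounds (ligands, ions) are retained but
flagged as non-polymer so that metric code can exclude them.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]


class StructureError(Exception):
    """Base error for structure I/O problems."""


class ParseError(StructureError):
    pass


class EmptyStructureError(StructureError):
    pass


class MappingError(StructureError):
    pass


#: canonical parents of common modified nucleotides (subset; unknown residues
#: are kept but excluded from nucleotide metrics)
MODIFIED_NUCLEOTIDES = {
    "PSU": "U", "H2U": "U", "5MU": "U", "4SU": "U", "DHU": "U", "UR3": "U",
    "1MA": "A", "MA6": "A", "6MZ": "A", "A2M": "A", "RIA": "A",
    "2MG": "G", "7MG": "G", "M2G": "G", "OMG": "G", "1MG": "G", "YG": "G",
    "G7M": "G", "GTP": "G", "GDP": "G",
    "5MC": "C", "OMC": "C", "4OC": "C",
}

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

AA_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "SEC": "U", "PYL": "O",
}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: canonical heavy-atom ordering used by `select_atoms` so that two
#: selections of homologous residues align positionally
BACKBONE_ATOMS = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'")
RIBOSE_ATOMS = ("C1'", "C2'", "O2'", "C3'", "C4'", "O4'")
PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

BASE_ATOMS = {
    "A": PURINE_RING + ("N6",),
    "G": PURINE_RING + ("O6", "N2"),
    "C": PYRIMIDINE_RING + ("O2", "N4"),
    "U": PYRIMIDINE_RING + ("O2", "O4"),
}

BASE_RING_ATOMS = {
    "A": PURINE_RING,
    "G": PURINE_RING,
    "C": PYRIMIDINE_RING,
    "U": PYRIMIDINE_RING,
}

_CANONICAL_ORDER: dict[str, tuple[str, ...]] = {}
for _b, _extra in BASE_ATOMS.items():
    seen: list[str] = []
    for _nm in ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
                "C2'", "O2'", "C1'") + _extra:
        if _nm not in seen:
            seen.append(_nm)
    _CANONICAL_ORDER[_b] = tuple(seen)


def standard_parent(res_name: str) -> Optional[str]:
    """Canonical parent (A/C/G/U or one-letter amino code) of a residue name."""
    name = res_name.strip().upper()
    if name in {"A", "C", "G", "U"}:
        return name
    if name in {"DA", "DC", "DG", "DT", "DU"}:
        return name[1].replace("T", "U")
    if name in MODIFIED_NUCLEOTIDES:
        return MODIFIED_NUCLEOTIDES[name]
    if name in AA_ONE:
        return AA_ONE[name]
    return None


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    is_hetero: bool = False

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def standard_parent(self) -> Optional[str]:
        return standard_parent(self.res_name)

    @property
    def is_nucleotide(self) -> bool:
        return self.standard_parent in {"A", "C", "G", "U"}

    @property
    def is_amino_acid(self) -> bool:
        return self.res_name.strip().upper() in AMINO_ACIDS

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_names(self) -> set[str]:
        return {a.name for a in self.atoms}


@dataclass
class Structure:
    id: str
    chains: list[tuple[str, list[Residue]]] = field(default_factory=list)
    source_format: str = "PDB"

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues()]
        if len(keys) != len(set(keys)):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise ValueError(f"duplicate residue key {dup}")

    def residues(self) -> Iterator[Residue]:
        for _, residues in self.chains:
            yield from residues

    def residue(self, key: ResidueKey) -> Optional[Residue]:
        return self._index().get(key)

    def _index(self) -> dict[ResidueKey, Residue]:
        idx = getattr(self, "_residue_index", None)
        if idx is None or len(idx) != sum(len(r) for _, r in self.chains):
            idx = {r.key: r for r in self.residues()}
            self._residue_index = idx
        return idx

    def nucleotides(self) -> list[Residue]:
        return [r for r in self.residues() if r.is_nucleotide]

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def copy(self) -> "Structure":
        new_chains = []
        for cid, residues in self.chains:
            new_res = []
            for r in residues:
                new_res.append(Residue(
                    chain_id=r.chain_id, seq_number=r.seq_number,
                    insertion_code=r.insertion_code, res_name=r.res_name,
                    is_hetero=r.is_hetero,
                    atoms=[Atom(a.name, a.element, a.position.copy(),
                                a.occupancy, a.b_factor) for a in r.atoms]))
            new_chains.append((cid, new_res))
        return Structure(id=self.id, chains=new_chains,
                         source_format=self.source_format)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with `x -> rotation @ x + translation` applied."""
        out = self.copy()
        for r in out.residues():
            for a in r.atoms:
                a.position = rotation @ a.position + np.asarray(translation, float)
        return out


@dataclass
class ResidueMapping:
    pairs: list[tuple[ResidueKey, ResidueKey]]
    strategy: str
    coverage: float

    def __post_init__(self) -> None:
        left = [p[0] for p in self.pairs]
        right = [p[1] for p in self.pairs]
        if len(left) != len(set(left)) or len(right) != len(set(right)):
            raise ValueError("mapping is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def model_key(self, reference_key: ResidueKey) -> Optional[ResidueKey]:
        for m, r in self.pairs:
            if r == reference_key:
                return m
        return None


# ---------------------------------------------------------------------------
# reading


def _element_of(atom_name: str, bio_element: str) -> str:
    if bio_element and bio_element.strip():
        return bio_element.strip().upper().capitalize()
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[:2].upper() in {"CL", "BR", "MG", "MN", "ZN", "FE", "NA", "SE"}:
        return stripped[:2].capitalize()
    return stripped[0].upper()


def read_structure(path, fmt: Literal["auto", "PDB", "mmCIF"] = "auto") -> Structure:
    """Parse a PDB or mmCIF file into a normalized :class:`Structure`.

    Keeps only the first MODEL, resolves alternate locations by occupancy
    (ties keep the first conformer in file order), drops waters and keeps
    hetero compounds flagged as such.
    """
    from Bio.PDB import MMCIFParser, PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if fmt == "auto":
        fmt = "mmCIF" if path.suffix.lower() in {".cif", ".mmcif"} else "PDB"

    parser = (MMCIFParser(QUIET=True) if fmt == "mmCIF"
              else PDBParser(QUIET=True))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError, KeyError) as exc:
        raise ParseError(f"cannot parse {path} as {fmt}: {exc}") from exc

    models = list(bio.get_models())
    if not models:
        raise EmptyStructureError(f"{path}: no models")
    if len(models) > 1:
        logger.warning("%s: %d MODEL blocks, keeping only the first",
                       path.name, len(models))
    model = models[0]

    chains: list[tuple[str, list[Residue]]] = []
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, seq_number, icode = bio_res.id
            res_name = bio_res.resname.strip()
            if res_name.upper() in WATER_NAMES or hetflag == "W":
                continue
            atoms: list[Atom] = []
            names_seen: set[str] = set()
            for bio_atom in bio_res:
                if bio_atom.is_disordered():
                    children = sorted(
                        bio_atom.disordered_get_list(),
                        key=lambda a: -(a.get_occupancy() or 0.0))
                    best = children[0]
                else:
                    best = bio_atom
                name = best.get_name().strip()
                if name in names_seen:
                    continue
                names_seen.add(name)
                atoms.append(Atom(
                    name=name,
                    element=_element_of(name, best.element or ""),
                    position=np.array(best.get_coord(), dtype=float),
                    occupancy=float(best.get_occupancy() or 1.0),
                    b_factor=float(best.get_bfactor() or 0.0)))
            if atoms:
                residues.append(Residue(
                    chain_id=bio_chain.id.strip() or "A",
                    seq_number=int(seq_number),
                    insertion_code=(icode or " ").strip(),
                    res_name=res_name,
                    atoms=atoms,
                    is_hetero=(hetflag.strip() != "")))
        if residues:
            chains.append((bio_chain.id.strip() or "A", residues))

    if not chains:
        raise EmptyStructureError(f"{path}: zero residues after filtering")
    return Structure(id=path.stem, chains=chains, source_format=fmt)


# ---------------------------------------------------------------------------
# writing (fixtures and round-trips; plain PDB v3.3 ATOM/HETATM records)


def write_pdb(structure: Structure, path) -> None:
    lines = []
    serial = 1
    for cid, residues in structure.chains:
        for res in residues:
            record = "HETATM" if res.is_hetero else "ATOM  "
            for atom in res.atoms:
                name = atom.name
                # PDB column rules: 1-char elements start in column 14
                if len(name) < 4 and len(atom.element) == 1:
                    name_field = f" {name:<3s}"
                else:
                    name_field = f"{name:<4s}"
                x, y, z = atom.position
                lines.append(
                    f"{record}{serial:>5d} {name_field} "
                    f"{res.res_name:<3s} {cid[:1]:1s}{res.seq_number:>4d}"
                    f"{(res.insertion_code or ' '):1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
                    f"{atom.b_factor:6.2f}          {atom.element:>2s}")
                serial += 1
        lines.append(f"TER   {serial:>5d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# atom selection


def select_atoms(residue: Residue,
                 selection: Literal["heavy", "backbone", "base", "ribose", "all"] = "heavy",
                 ) -> list[Atom]:
    """Ordered atom subset of a residue; missing atoms are silently omitted."""
    parent = residue.standard_parent
    if selection == "all":
        return list(residue.atoms)
    heavy = [a for a in residue.atoms if not a.is_hydrogen]
    by_name = {a.name: a for a in heavy}
    if selection == "heavy":
        order = _CANONICAL_ORDER.get(parent or "", ())
        picked = [by_name[nm] for nm in order if nm in by_name]
        rest = sorted((a for a in heavy if a.name not in order),
                      key=lambda a: a.name)
        return picked + rest
    if selection == "backbone":
        return [by_name[nm] for nm in BACKBONE_ATOMS if nm in by_name]
    if selection == "ribose":
        return [by_name[nm] for nm in RIBOSE_ATOMS if nm in by_name]
    if selection == "base":
        ring = BASE_RING_ATOMS.get(parent or "", ())
        return [by_name[nm] for nm in ring if nm in by_name]
    raise ValueError(f"unknown selection {selection!r}")


# ---------------------------------------------------------------------------
# residue mapping


def _chain_sequence(residues: Sequence[Residue]) -> str:
    out = []
    for r in residues:
        p = r.standard_parent
        out.append(p if p and len(p) == 1 else "X")
    return "".join(out)


def _polymer_chains(structure: Structure,
                    include_amino: bool) -> list[tuple[str, list[Residue]]]:
    chains = []
    for cid, residues in structure.chains:
        poly = [r for r in residues
                if r.is_nucleotide or (include_amino and r.is_amino_acid)]
        if poly:
            chains.append((cid, poly))
    return chains


def _align_chain(model_res: list[Residue], ref_res: list[Residue]):
    """Global alignment (match +1, mismatch -1, gap -2) of two chains."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    seq_m = _chain_sequence(model_res)
    seq_r = _chain_sequence(ref_res)
    aln = aligner.align(seq_m, seq_r)[0]
    pairs = []
    for (ms, me), (rs, re_) in zip(*aln.aligned):
        for off in range(me - ms):
            pairs.append((model_res[ms + off], ref_res[rs + off]))
    return float(aln.score), pairs


def map_residues(model: Structure, reference: Structure,
                 strategy: Literal["auto", "identifier", "alignment"] = "auto",
                 include_amino: bool = False,
                 allow_mismatch: bool = False,
                 min_coverage: float = 0.3) -> ResidueMapping:
    """One-to-one residue correspondence between model and reference.

    `identifier` matches on (chain_id, seq_number, insertion_code);
    `alignment` pairs chains by best global sequence alignment score and maps
    aligned non-gap columns.  `auto` tries identifier first and falls back to
    alignment when identifier coverage drops below 0.8.
    """
    ref_nucleotides = reference.nucleotides()
    if not model.nucleotides() or not ref_nucleotides:
        raise MappingError("both structures must contain at least one nucleotide")

    def _coverage(pairs) -> float:
        mapped_ref = {r.key for _, r in pairs if r.is_nucleotide}
        return len(mapped_ref) / len(ref_nucleotides)

    def _identifier_pairs():
        model_idx = {r.key: r for r in model.residues()
                     if r.is_nucleotide or (include_amino and r.is_amino_acid)}
        pairs = []
        for r in reference.residues():
            if not (r.is_nucleotide or (include_amino and r.is_amino_acid)):
                continue
            m = model_idx.get(r.key)
            if m is None:
                continue
            if not allow_mismatch and m.standard_parent != r.standard_parent:
                continue
            pairs.append((m, r))
        return pairs

    def _alignment_pairs():
        model_chains = _polymer_chains(model, include_amino)
        ref_chains = _polymer_chains(reference, include_amino)
        scored = []
        for mi, (mc, mres) in enumerate(model_chains):
            for ri, (rc, rres) in enumerate(ref_chains):
                score, pairs = _align_chain(mres, rres)
                scored.append((score, mi, ri, pairs))
        scored.sort(key=lambda t: (-t[0], t[1], t[2]))
        used_m: set[int] = set()
        used_r: set[int] = set()
        pairs = []
        for score, mi, ri, chain_pairs in scored:
            if mi in used_m or ri in used_r or score <= 0:
                continue
            used_m.add(mi)
            used_r.add(ri)
            pairs.extend(chain_pairs)
        if not allow_mismatch:
            pairs = [(m, r) for m, r in pairs
                     if m.standard_parent == r.standard_parent]
        return pairs

    if strategy == "identifier":
        pairs = _identifier_pairs()
    elif strategy == "alignment":
        pairs = _alignment_pairs()
    else:
        pairs = _identifier_pairs()
        strategy = "identifier"
        if _coverage(pairs) < 0.8:
            alt = _alignment_pairs()
            if _coverage(alt) > _coverage(pairs):
                pairs, strategy = alt, "alignment"

    coverage = _coverage(pairs)
    if coverage < min_coverage:
        raise MappingError(
            f"mapping coverage {coverage:.2f} < {min_coverage} "
            f"({len(pairs)} pairs); check chain pairing")
    return ResidueMapping(pairs=[(m.key, r.key) for m, r in pairs],
                          strategy=strategy, coverage=coverage)
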