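"""Rigid superposition, RMSD, deformation index and deformation profile."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .structure_io import (Residue, ResidueKey, ResidueMapping, Structure,
                           select_atoms)


class SuperpositionError(Exception):
    pass


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3 proper rotation
    translation: np.ndarray   # applied as x @ R.T + t
    rmsd: float
    n_atoms: int

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray,
                     weights: Optional[np.ndarray] = None) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation (Kabsch/SVD).

    Returns the transform that maps `moving` onto `fixed`; reflections are
    corrected by flipping the sign of the smallest singular vector.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise SuperpositionError(
            f"point sets differ in shape: {moving.shape} vs {fixed.shape}")
    if moving.ndim != 2 or moving.shape[1] != 3 or moving.shape[0] < 3:
        raise SuperpositionError("need at least 3 points of dimension 3")
    n = moving.shape[0]
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise SuperpositionError("weights must be non-negative, length n")
    wsum = w.sum()
    cm = (w[:, None] * moving).sum(axis=0) / wsum
    cf = (w[:, None] * fixed).sum(axis=0) / wsum
    P = moving - cm
    Q = fixed - cf
    H = (w[:, None] * P).T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    diff = (moving @ R.T + t) - fixed
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum() / wsum))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


# ---------------------------------------------------------------------------
# structure-level RMSD


def _common_coords(model_res: Residue, ref_res: Residue,
                   selection: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    m_atoms = {a.name: a for a in select_atoms(model_res, selection)}
    names = [a.name for a in select_atoms(ref_res, selection) if a.name in m_atoms]
    if not names:
        return np.empty((0, 3)), np.empty((0, 3)), []
    mc = np.array([m_atoms[nm].position for nm in names])
    rc = np.array([ref_res.atom(nm).position for nm in names])
    return mc, rc, names


def _stack_mapped(model: Structure, reference: Structure,
                  mapping: ResidueMapping, selection: str,
                  nucleotides_only: bool = True):
    """Stacked common-atom coordinate arrays over all mapped residues."""
    blocks_m, blocks_r, owners = [], [], []
    for mk, rk in mapping.pairs:
        mres, rres = model.residue(mk), reference.residue(rk)
        if mres is None or rres is None:
            continue
        if nucleotides_only and not rres.is_nucleotide:
            continue
        mc, rc, names = _common_coords(mres, rres, selection)
        if len(names) == 0:
            continue
        blocks_m.append(mc)
        blocks_r.append(rc)
        owners.extend([rk] * len(names))
    if not blocks_m:
        return np.empty((0, 3)), np.empty((0, 3)), []
    return np.vstack(blocks_m), np.vstack(blocks_r), owners


def global_rmsd(model: Structure, reference: Structure,
                mapping: ResidueMapping, selection: str = "heavy",
                include_amino: bool = False) -> float:
    """All-common-atom RMSD after one optimal global superposition."""
    mc, rc, owners = _stack_mapped(model, reference, mapping, selection,
                                   nucleotides_only=not include_amino)
    if len(owners) == 0:
        first = mapping.pairs[0][1] if mapping.pairs else None
        raise SuperpositionError(
            f"no common atoms under selection {selection!r}"
            + (f"; first mapped reference residue {first}" if first else ""))
    if len(owners) < 3:
        raise SuperpositionError("fewer than 3 common atoms")
    return kabsch_superpose(mc, rc).rmsd


def superpose_structures(model: Structure, reference: Structure,
                         mapping: ResidueMapping, selection: str = "heavy",
                         ) -> SuperpositionResult:
    mc, rc, owners = _stack_mapped(model, reference, mapping, selection)
    if len(owners) < 3:
        raise SuperpositionError("fewer than 3 common atoms")
    return kabsch_superpose(mc, rc)


# ---------------------------------------------------------------------------
# deformation profile


@dataclass
class DPMatrix:
    residue_keys: list[ResidueKey]   # reference keys of the mapped residues
    values: np.ndarray               # N x N, A; NaN rows = degenerate anchor

    def row(self, key: ResidueKey) -> np.ndarray:
        return self.values[self.residue_keys.index(key)]

    @property
    def flagged_rows(self) -> list[ResidueKey]:
        return [k for k, row in zip(self.residue_keys, self.values)
                if np.all(np.isnan(row))]

    def to_tsv(self) -> str:
        header = "\t".join([""] + [_fmt_key(k) for k in self.residue_keys])
        lines = [header]
        for k, row in zip(self.residue_keys, self.values):
            cells = ["NA" if np.isnan(v) else f"{v:.3f}" for v in row]
            lines.append("\t".join([_fmt_key(k)] + cells))
        return "\n".join(lines) + "\n"


def _fmt_key(key: ResidueKey) -> str:
    chain, num, icode = key
    return f"{chain}:{num}{icode or ''}"


def deformation_profile(model: Structure, reference: Structure,
                        mapping: ResidueMapping,
                        selection: str = "heavy") -> DPMatrix:
    """Per-nucleotide deformation profile.

    Row i is produced by superposing the model on the reference using only
    residue i's common atoms; entry (i, j) is then the mean distance over
    residue j's common atoms.  Anchors with fewer than 3 common atoms give a
    NaN-flagged row.
    """
    per_res: list[tuple[ResidueKey, np.ndarray, np.ndarray]] = []
    for mk, rk in mapping.pairs:
        mres, rres = model.residue(mk), reference.residue(rk)
        if mres is None or rres is None or not rres.is_nucleotide:
            continue
        mc, rc, names = _common_coords(mres, rres, selection)
        per_res.append((rk, mc, rc))
    if not per_res:
        raise SuperpositionError("no mapped nucleotides with common atoms")
    n = len(per_res)
    values = np.full((n, n), np.nan)
    for i, (ki, mi, ri) in enumerate(per_res):
        if len(mi) < 3:
            continue  # degenerate anchor, row stays flagged
        sup = kabsch_superpose(mi, ri)
        for j, (kj, mj, rj) in enumerate(per_res):
            if len(mj) == 0:
                continue
            moved = sup.apply(mj)
            values[i, j] = float(np.mean(np.linalg.norm(moved - rj, axis=1)))
    return DPMatrix(residue_keys=[k for k, _, _ in per_res], values=values)


# ---------------------------------------------------------------------------
# domain aggregation


@dataclass
class DomainDefinition:
    name: str
    members: set[ResidueKey]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"domain {self.name}: empty member set")


@dataclass
class DomainDPStats:
    domain_a: str
    domain_b: str
    min: float
    max: float
    mean: float


def parse_domain_ranges(spec: dict[str, list[str]],
                        keys: Iterable[ResidueKey]) -> list[DomainDefinition]:
    """Expand a `{name: ["A:2-9", ...]}` config into domain definitions.

    Ranges are chain:start-end, inclusive, author numbering; single residues
    may be given as chain:n.
    """
    available = list(keys)
    domains = []
    for name, ranges in spec.items():
        members: set[ResidueKey] = set()
        for rng in ranges:
            chain, _, span = rng.partition(":")
            if not span:
                raise ValueError(f"domain {name}: bad range {rng!r}")
            if "-" in span.lstrip("-"):
                lo_s, _, hi_s = span.rpartition("-")
                lo, hi = int(lo_s), int(hi_s)
            else:
                lo = hi = int(span)
            hit = [k for k in available if k[0] == chain and lo <= k[1] <= hi]
            if not hit:
                raise ValueError(
                    f"domain {name}: range {rng!r} matches no mapped residue")
            members.update(hit)
        domains.append(DomainDefinition(name=name, members=members))
    return domains


def aggregate_dp(dp: DPMatrix,
                 domains: Sequence[DomainDefinition]) -> list[DomainDPStats]:
    """Min/max/mean DP statistics over every ordered domain pair."""
    index = {k: i for i, k in enumerate(dp.residue_keys)}
    for dom in domains:
        missing = dom.members - set(index)
        if missing:
            raise ValueError(
                f"domain {dom.name}: residues not in DP matrix: {sorted(missing)[:3]}")
    stats = []
    for da in domains:
        rows = [index[k] for k in sorted(da.members)]
        for db in domains:
            cols = [index[k] for k in sorted(db.members)]
            block = dp.values[np.ix_(rows, cols)]
            valid = block[~np.isnan(block)]
            if valid.size == 0:
                stats.append(DomainDPStats(da.name, db.name,
                                           float("nan"), float("nan"), float("nan")))
            else:
                stats.append(DomainDPStats(
                    da.name, db.name, float(valid.min()), float(valid.max()),
                    float(valid.mean())))
    return stats


def domain_stats_tsv(stats: Sequence[DomainDPStats]) -> str:
    lines = ["domain_a\tdomain_b\tmin\tmax\tmean"]
    for s in stats:
        lines.append(f"{s.domain_a}\t{s.domain_b}\t{s.min:.3f}\t{s.max:.3f}\t{s.mean:.3f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------


def deformation_index(rmsd: float, inf_all: Optional[float]) -> Optional[float]:
    """DI = RMSD / INF_all; undefined (None) when INF_all is 0 or undefined."""
    if rmsd < 0:
        raise ValueError("rmsd must be >= 0")
    if inf_all is None or inf_all == 0:
        return None
    return rmsd / inf_all
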