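"""Metric-panel orchestration: per-reference assessment, ranking and report
data (tables, radar ranks, B-factor profiles)."""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import annotation, stereochemistry, superposition, torsions
from .annotation import AnnotationConfig, DEFAULT_CONFIG, InteractionSet
from .structure_io import (MappingError, ResidueKey, ResidueMapping, Structure,
                           map_residues)
from .superposition import (DomainDefinition, DomainDPStats, DPMatrix,
                            aggregate_dp, deformation_index,
                            deformation_profile, global_rmsd)


class AssessmentError(Exception):
    pass


def inf(reference_set: Iterable, model_set: Iterable) -> Optional[float]:
    """Interaction network fidelity: geometric mean of precision and recall.

    Both sets empty -> None (nothing to score); empty model against a
    non-empty reference -> 0.0.
    """
    ref = set(reference_set)
    mod = set(model_set)
    if not ref and not mod:
        return None
    if not mod:
        return 0.0
    tp = len(ref & mod)
    fp = len(mod - ref)
    fn = len(ref - mod)
    if tp == 0:
        return 0.0
    ppv = tp / (tp + fp)
    sty = tp / (tp + fn)
    return math.sqrt(ppv * sty)


@dataclass
class MetricRecord:
    model_id: str
    reference_id: str
    rmsd: float
    inf_all: Optional[float]
    inf_wc: Optional[float]
    inf_nwc: Optional[float]
    inf_stack: Optional[float]
    di_all: Optional[float]
    mcq: Optional[float]
    clash_score: Optional[float]
    coverage: float
    group_id: Optional[str] = None
    submitted_rank: Optional[int] = None
    dp: Optional[DPMatrix] = None
    domain_stats: Optional[list[DomainDPStats]] = None

    def metric(self, name: str) -> Optional[float]:
        return getattr(self, name)

    def as_dict(self) -> dict:
        def fmt(v):
            return None if v is None else round(float(v), 4)
        return {
            "model": self.model_id,
            "group": self.group_id,
            "submitted_rank": self.submitted_rank,
            "reference": self.reference_id,
            "RMSD": fmt(self.rmsd),
            "DI_all": fmt(self.di_all),
            "INF_all": fmt(self.inf_all),
            "INF_wc": fmt(self.inf_wc),
            "INF_nwc": fmt(self.inf_nwc),
            "INF_stack": fmt(self.inf_stack),
            "MCQ": fmt(self.mcq),
            "Clash": fmt(self.clash_score),
            "coverage": fmt(self.coverage),
        }


#: metric -> True when lower is better
METRIC_ASCENDING = {
    "rmsd": True, "di_all": True, "mcq": True, "clash_score": True,
    "inf_all": False, "inf_wc": False, "inf_nwc": False, "inf_stack": False,
}


def _mapped_interactions(structure: Structure, keys: Iterable[ResidueKey],
                         config: AnnotationConfig) -> InteractionSet:
    return annotation.interaction_sets(structure, config).restricted(keys)


def _rekey_profile(profile: torsions.TorsionProfile,
                   mapping: ResidueMapping) -> torsions.TorsionProfile:
    """Re-key a model torsion profile by the mapped reference keys."""
    to_ref = {m: r for m, r in mapping.pairs}
    return torsions.TorsionProfile(
        {to_ref[k]: row for k, row in profile.angles.items() if k in to_ref})


def assess_pair(model: Structure, reference: Structure,
                mapping: Optional[ResidueMapping] = None,
                domains: Optional[dict[str, list[str]]] = None,
                config: AnnotationConfig = DEFAULT_CONFIG,
                clash: Optional[float] = "auto",
                with_dp: bool = True) -> MetricRecord:
    """Full metric panel for one (model, reference) pair."""
    if mapping is None:
        mapping = map_residues(model, reference)
    ref_keys = [r for _, r in mapping.pairs]
    model_keys = [m for m, _ in mapping.pairs]

    rmsd = global_rmsd(model, reference, mapping)

    ref_sets = _mapped_interactions(reference, ref_keys, config)
    # model interactions expressed in reference keys so the sets compare
    model_sets_raw = _mapped_interactions(model, model_keys, config)
    to_ref = {m: r for m, r in mapping.pairs}

    def rekey(pairs):
        return {tuple(sorted((to_ref[a], to_ref[b]))) for a, b in pairs}

    def norm(pairs):
        return {tuple(sorted(p)) for p in pairs}

    inf_all = inf(norm(ref_sets.all), rekey(model_sets_raw.all))
    inf_wc = inf(norm(ref_sets.wc), rekey(model_sets_raw.wc))
    inf_nwc = inf(norm(ref_sets.nwc), rekey(model_sets_raw.nwc))
    inf_stack = inf(norm(ref_sets.stack), rekey(model_sets_raw.stack))
    di_all = deformation_index(rmsd, inf_all)

    prof_ref = torsions.torsions(reference, keys=ref_keys)
    prof_model = _rekey_profile(torsions.torsions(model, keys=model_keys),
                                mapping)
    mcq_result = torsions.mcq(prof_model, prof_ref)

    if clash == "auto":
        clash = stereochemistry.clash_score(model).score

    dp = None
    domain_stats = None
    if with_dp:
        dp = deformation_profile(model, reference, mapping)
        if domains:
            defs = superposition.parse_domain_ranges(domains, dp.residue_keys)
            domain_stats = aggregate_dp(dp, defs)

    return MetricRecord(
        model_id=model.id, reference_id=reference.id, rmsd=rmsd,
        inf_all=inf_all, inf_wc=inf_wc, inf_nwc=inf_nwc, inf_stack=inf_stack,
        di_all=di_all, mcq=mcq_result.mcq, clash_score=clash,
        coverage=mapping.coverage, dp=dp, domain_stats=domain_stats)


def assess_model(model: Structure, references: Sequence[Structure],
                 domains: Optional[dict[str, list[str]]] = None,
                 config: AnnotationConfig = DEFAULT_CONFIG,
                 with_dp: bool = True,
                 ) -> tuple[list[MetricRecord], MetricRecord]:
    """Assess one model against every reference; best = minimal RMSD.

    The clash score is computed once (it is a property of the model alone)
    and repeated in every record.
    """
    if not references:
        raise AssessmentError("at least one reference is required")
    clash = stereochemistry.clash_score(model).score
    records = []
    errors = []
    for ref in references:
        try:
            records.append(assess_pair(model, ref, domains=domains,
                                       config=config, clash=clash,
                                       with_dp=with_dp))
        except (MappingError, superposition.SuperpositionError) as exc:
            errors.append(f"{ref.id}: {exc}")
    if not records:
        raise AssessmentError(
            "model could not be assessed against any reference: "
            + "; ".join(errors))
    best = min(records, key=lambda r: r.rmsd)
    return records, best


# ---------------------------------------------------------------------------
# ranking


@dataclass
class RankingTable:
    metric: str
    order: list[str]                  # model ids, best first
    ranks: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.ranks = {mid: i + 1 for i, mid in enumerate(self.order)}


def rank_models(records: Sequence[MetricRecord], metric: str = "rmsd",
                ) -> RankingTable:
    """Total order over models for one metric.

    RMSD/DI/MCQ/clash rank ascending, INF metrics descending; undefined
    values sink to the bottom; ties break lexicographically on model id.
    """
    if metric not in METRIC_ASCENDING:
        raise AssessmentError(f"unknown metric {metric!r}; "
                              f"choose from {sorted(METRIC_ASCENDING)}")
    ascending = METRIC_ASCENDING[metric]

    def sort_key(rec: MetricRecord):
        v = rec.metric(metric)
        if v is None:
            return (1, 0.0, rec.model_id)
        return (0, v if ascending else -v, rec.model_id)

    ordered = sorted(records, key=sort_key)
    return RankingTable(metric=metric, order=[r.model_id for r in ordered])


RADAR_METRICS = ("rmsd", "di_all", "inf_wc", "inf_nwc", "inf_stack",
                 "mcq", "clash_score")


@dataclass
class RadarData:
    metrics: tuple[str, ...]
    first_model: dict[str, dict[str, int]]   # group -> metric -> rank
    best_model: dict[str, dict[str, int]]

    def as_dict(self) -> dict:
        return {"metrics": list(self.metrics),
                "first_model": self.first_model,
                "best_model": self.best_model}


def radar_data(records: Sequence[MetricRecord],
               metrics: Sequence[str] = RADAR_METRICS) -> RadarData:
    """Relative per-metric ranks of each group's first-submitted model and
    best-RMSD model, across all groups."""
    groups: dict[str, list[MetricRecord]] = {}
    for rec in records:
        if rec.group_id is None:
            continue
        groups.setdefault(rec.group_id, []).append(rec)

    selections = {}
    for gid, recs in sorted(groups.items()):
        ranked = [r for r in recs if r.submitted_rank is not None]
        if not ranked:
            import logging
            logging.getLogger(__name__).warning(
                "group %s has no submitted_rank; excluded from radar", gid)
            continue
        first = min(ranked, key=lambda r: r.submitted_rank)
        best = min(recs, key=lambda r: (r.rmsd, r.model_id))
        selections[gid] = (first, best)

    def rank_among(selected: list[tuple[str, MetricRecord]]):
        out: dict[str, dict[str, int]] = {g: {} for g, _ in selected}
        for metric in metrics:
            table = rank_models([r for _, r in selected], metric)
            pos = {r.model_id: i for i, (_, r) in enumerate(selected)}
            # table.order has model ids; map back to the owning group
            by_model = {r.model_id: g for g, r in selected}
            for rank, mid in enumerate(table.order, start=1):
                out[by_model[mid]][metric] = rank
        return out

    first_sel = [(g, fr) for g, (fr, _) in selections.items()]
    best_sel = [(g, bt) for g, (_, bt) in selections.items()]
    return RadarData(metrics=tuple(metrics),
                     first_model=rank_among(first_sel),
                     best_model=rank_among(best_sel))


# ---------------------------------------------------------------------------
# B-factor profile


def bfactor_profile(reference: Structure,
                    keys: Optional[Iterable[ResidueKey]] = None,
                    ) -> list[tuple[ResidueKey, float]]:
    """Per-residue mean heavy-atom B-factor, in residue order."""
    wanted = set(keys) if keys is not None else None
    out = []
    for res in reference.residues():
        if wanted is not None and res.key not in wanted:
            continue
        heavy = [a.b_factor for a in res.atoms if not a.is_hydrogen]
        if heavy:
            out.append((res.key, float(np.mean(heavy))))
    return out


# ---------------------------------------------------------------------------
# report export


CSV_COLUMNS = ["model", "group", "submitted_rank", "reference", "RMSD",
               "DI_all", "INF_all", "INF_wc", "INF_nwc", "INF_stack", "MCQ",
               "Clash", "coverage"]


def records_to_csv(records: Sequence[MetricRecord]) -> str:
    import pandas as pd

    rows = [r.as_dict() for r in records]
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return frame.to_csv(index=False, na_rep="NA")


def report_json(per_reference: Sequence[MetricRecord],
                best: MetricRecord) -> str:
    payload = {
        "records": [r.as_dict() for r in per_reference],
        "best": best.as_dict(),
    }
    return json.dumps(payload, indent=2)
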