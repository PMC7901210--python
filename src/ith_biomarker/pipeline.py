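"""End-to-end orchestration: ingest -> clonality -> biomarkers -> associations.

Stages communicate through plain data structures and typed TSV/JSON files
so each can also run standalone from the CLI.  The report embeds a hash of
the fully-serialized configuration, and identical config + seed yields a
byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import burden, clonality, neoantigen, stats, variant_io
from .clonality import ClonalityConfig
from .model import (
    ClinicalRecord,
    CopyNumberSegment,
    NeoantigenCandidate,
    PatientBiomarkers,
    VariantCall,
)
from .neoantigen import FitnessParams, ScoreWeights


@dataclass
class RunConfig:
    """Analysis constants of one pipeline run."""

    exome_mb: float
    ith_cutoff: float = burden.DEFAULT_ITH_CUTOFF
    tmb_top_fraction: float = burden.DEFAULT_TMB_TOP_FRACTION
    tmb_cutoff: Optional[float] = None  # overrides the quantile when set
    clonality: ClonalityConfig = field(default_factory=ClonalityConfig)
    fitness: FitnessParams = field(default_factory=FitnessParams)
    score_weights: ScoreWeights = field(default_factory=ScoreWeights)
    top_n_neoantigens: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exome_mb <= 0:
            raise ValueError("exome_mb must be > 0")
        if not (0 <= self.ith_cutoff <= 1):
            raise ValueError("ith_cutoff must be in [0,1]")
        if not (0 < self.tmb_top_fraction < 1):
            raise ValueError("tmb_top_fraction must be in (0,1)")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def patient_ith(
    variants: Sequence[VariantCall],
    segments: Sequence[CopyNumberSegment],
    purity: float,
    patient_id: str,
    config: ClonalityConfig = clonality.DEFAULT_CONFIG,
) -> tuple:
    """CCF-estimate every countable variant of one patient and compute ITH."""
    index = variant_io.SegmentIndex(segments)
    estimates = []
    for v in variants:
        if v.depth < 1:
            continue
        cn = index.lookup(v)
        estimates.append(clonality.estimate_ccf(v, purity, cn, config=config))
    return clonality.compute_ith(estimates, patient_id, config), estimates


def compute_cohort_biomarkers(
    variants: Sequence[VariantCall],
    segments: Sequence[CopyNumberSegment],
    clinical: Sequence[ClinicalRecord],
    cfg: RunConfig,
) -> tuple[list[PatientBiomarkers], dict]:
    """Per-patient ITH + TMB with group labels; returns (patients, ccf_map)."""
    by_patient: dict[str, list[VariantCall]] = {}
    for v in variants:
        by_patient.setdefault(v.sample_id, []).append(v)
    purity_of = {r.patient_id: r.purity for r in clinical}

    biomarkers = []
    ccf_map = {}
    for rec in clinical:
        pvars = by_patient.get(rec.patient_id, [])
        ith_res, estimates = patient_ith(
            pvars,
            [s for s in segments if s.sample_id in ("", rec.patient_id)],
            purity_of[rec.patient_id],
            rec.patient_id,
            cfg.clonality,
        )
        ccf_map[rec.patient_id] = (ith_res, estimates)
        biomarkers.append(
            PatientBiomarkers(
                patient_id=rec.patient_id,
                tmb=burden.compute_tmb(pvars, cfg.exome_mb),
                ith=ith_res.ith,
            )
        )
    grouped = burden.assign_groups(
        biomarkers,
        ith_cutoff=cfg.ith_cutoff,
        tmb_cutoff=cfg.tmb_cutoff,
        tmb_top_fraction=cfg.tmb_top_fraction,
    )
    return grouped, ccf_map


def _rate_table(flags_by_group: dict, favorable: str, unfavorable: str):
    fav = flags_by_group[favorable]
    unf = flags_by_group[unfavorable]
    return stats.ContingencyTable2x2(
        a=sum(fav), b=len(fav) - sum(fav), c=sum(unf), d=len(unf) - sum(unf)
    )


def _group_comparison(
    patients: Sequence[PatientBiomarkers],
    clinical_by_id: dict,
    group_attr: str,
    favorable: str,
    unfavorable: str,
) -> dict:
    """Fisher DCB/ORR rates + KM/log-rank/Cox for a two-level grouping."""
    sel = [p for p in patients if getattr(p, group_attr) is not None]
    groups = {favorable: [], unfavorable: []}
    times, events, indicator = [], [], []
    dcb = {favorable: [], unfavorable: []}
    orr = {favorable: [], unfavorable: []}
    for p in sel:
        g = getattr(p, group_attr)
        rec = clinical_by_id[p.patient_id]
        groups[g].append(p)
        dcb[g].append(rec.dcb)
        orr[g].append(rec.orr)
        times.append(rec.pfs_days)
        events.append(rec.pfs_event)
        indicator.append(1.0 if g == unfavorable else 0.0)

    dcb_table = _rate_table(dcb, favorable, unfavorable)
    orr_table = _rate_table(orr, favorable, unfavorable)
    _, dcb_p = stats.fisher_exact(dcb_table)
    _, orr_p = stats.fisher_exact(orr_table)
    hr, lo, hi = stats.cox_hr(times, events, indicator)
    med = {
        g: stats.km_median(
            [clinical_by_id[p.patient_id].pfs_days for p in groups[g]],
            [clinical_by_id[p.patient_id].pfs_event for p in groups[g]],
        )
        for g in (favorable, unfavorable)
    }
    return {
        "n": {g: len(groups[g]) for g in groups},
        "dcb_rate": {
            favorable: _rate(dcb[favorable]),
            unfavorable: _rate(dcb[unfavorable]),
        },
        "orr_rate": {
            favorable: _rate(orr[favorable]),
            unfavorable: _rate(orr[unfavorable]),
        },
        "dcb_fisher_p": dcb_p,
        "orr_fisher_p": orr_p,
        "median_pfs_days": med,
        "logrank_p": stats.logrank(
            times, events, ["B" if i else "A" for i in indicator]
        ),
        "hr": hr,
        "hr_ci": [lo, hi],
    }


def _rate(flags: list) -> float:
    return sum(flags) / len(flags) if flags else math.nan


def analyze_cohort(
    patients: Sequence[PatientBiomarkers],
    clinical: Sequence[ClinicalRecord],
    cfg: RunConfig,
) -> dict:
    """Every cohort-level association statistic the pipeline reports."""
    clin = {r.patient_id: r for r in clinical}
    evaluable = [p for p in patients if p.ith_group is not None]

    report: dict = {}
    report["ith_groups"] = _group_comparison(patients, clin, "ith_group", "ITH-L", "ITH-H")
    report["tmb_groups"] = _group_comparison(patients, clin, "tmb_group", "TMB-H", "TMB-L")

    # combined strata: DCB rate and KM median per combo group
    combos = ("TMB-H", "TMB-L&ITH-L", "TMB-L&ITH-H")
    combo_stats = {}
    for g in combos:
        members = [p for p in evaluable if p.combo_group == g]
        if not members:
            combo_stats[g] = {"n": 0}
            continue
        t = [clin[p.patient_id].pfs_days for p in members]
        e = [clin[p.patient_id].pfs_event for p in members]
        combo_stats[g] = {
            "n": len(members),
            "dcb_rate": _rate([clin[p.patient_id].dcb for p in members]),
            "orr_rate": _rate([clin[p.patient_id].orr for p in members]),
            "median_pfs_days": stats.km_median(t, e),
        }
    report["combo_groups"] = combo_stats

    # ITH within the TMB-L subgroup
    tmb_low = [p for p in evaluable if p.tmb_group == "TMB-L"]
    if sum(1 for p in tmb_low if p.ith_group == "ITH-L") >= 2 and sum(
        1 for p in tmb_low if p.ith_group == "ITH-H"
    ) >= 2:
        report["tmb_low_ith_groups"] = _group_comparison(
            tmb_low, clin, "ith_group", "ITH-L", "ITH-H"
        )

    # TMB x ITH interaction (Cox product term) and ITH-TMB correlation
    times = [clin[p.patient_id].pfs_days for p in evaluable]
    events = [clin[p.patient_id].pfs_event for p in evaluable]
    tmb_ind = [1.0 if p.tmb_group == "TMB-H" else 0.0 for p in evaluable]
    ith_ind = [1.0 if p.ith_group == "ITH-H" else 0.0 for p in evaluable]
    try:
        report["interaction_p"] = stats.interaction_p(times, events, tmb_ind, ith_ind)
    except (ValueError, RuntimeError) as exc:
        report["interaction_p"] = None
        report["interaction_error"] = str(exc)
    rho, sp_p = stats.spearman(
        [p.ith for p in evaluable], [p.tmb for p in evaluable]
    )
    report["ith_tmb_spearman"] = {"rho": rho, "p": sp_p}
    return report


def analyze_neoantigens(
    candidates: Sequence[NeoantigenCandidate],
    patients: Sequence[PatientBiomarkers],
    epitopes: Sequence[str],
    cfg: RunConfig,
) -> dict:
    """Per-patient top-N quality scores, clonal proportions and fitness."""
    by_patient: dict[str, list[NeoantigenCandidate]] = {}
    for c in candidates:
        by_patient.setdefault(c.patient_id, []).append(c)
    group_of = {p.patient_id: p.ith_group for p in patients}

    per_patient = {}
    for pid, cands in sorted(by_patient.items()):
        top = neoantigen.top_candidates(cands, cfg.top_n_neoantigens, cfg.score_weights)
        scores = [neoantigen.neoantigen_score(c, cfg.score_weights) for c in top]
        fit = neoantigen.evaluate_patient_fitness(cands, epitopes, cfg.fitness, pid)
        per_patient[pid] = {
            "ith_group": group_of.get(pid),
            "n_candidates": len(cands),
            "mean_top_score": float(np.mean(scores)),
            "clonal_neoantigen_proportion": fit.clonal_neoantigen_proportion,
            "fitness": fit.fitness,
        }

    def _group_mean(key: str, group: str) -> float:
        vals = [
            d[key]
            for d in per_patient.values()
            if d["ith_group"] == group and not math.isnan(d[key])
        ]
        return float(np.mean(vals)) if vals else math.nan

    summary = {
        g: {
            "mean_top_score": _group_mean("mean_top_score", g),
            "mean_clonal_proportion": _group_mean("clonal_neoantigen_proportion", g),
            "mean_fitness": _group_mean("fitness", g),
        }
        for g in ("ITH-L", "ITH-H")
    }
    return {"per_patient": per_patient, "by_ith_group": summary}


def run_pipeline(
    cfg: RunConfig,
    variants: Sequence[VariantCall],
    segments: Sequence[CopyNumberSegment],
    clinical: Sequence[ClinicalRecord],
    neoantigens: Sequence[NeoantigenCandidate] = (),
    epitopes: Sequence[str] = (),
) -> dict:
    """Full analysis report for one cohort (JSON-serializable dict)."""
    patients, ccf_map = compute_cohort_biomarkers(variants, segments, clinical, cfg)
    tmb_cutoff = cfg.tmb_cutoff
    if tmb_cutoff is None:
        tmb_cutoff = burden.quantile_cutoff(
            [p.tmb for p in patients], cfg.tmb_top_fraction
        )
    report = {
        "config_hash": cfg.digest(),
        "config": json.loads(json.dumps(asdict(cfg), sort_keys=True, default=str)),
        "cutoffs": {"ith": cfg.ith_cutoff, "tmb": tmb_cutoff},
        "patients": [
            {
                "patient_id": p.patient_id,
                "n_clonal": ccf_map[p.patient_id][0].n_clonal,
                "n_subclonal": ccf_map[p.patient_id][0].n_subclonal,
                "ith": None if math.isnan(p.ith) else p.ith,
                "tmb": p.tmb,
                "ith_group": p.ith_group,
                "tmb_group": p.tmb_group,
                "combo_group": p.combo_group,
            }
            for p in patients
        ],
        "associations": analyze_cohort(patients, clinical, cfg),
    }
    if neoantigens:
        report["neoantigens"] = analyze_neoantigens(
            neoantigens, patients, list(epitopes), cfg
        )
    return report


def write_report(report: dict, path) -> None:
    """Canonical serialization: sorted keys, fixed float formatting."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def ith_table(ccf_map: dict) -> pd.DataFrame:
    """Per-patient clonal/subclonal counts and ITH (summary-table layout)."""
    rows = []
    for pid, (ith_res, _) in sorted(ccf_map.items()):
        rows.append(
            {
                "patient_id": pid,
                "n_clonal": ith_res.n_clonal,
                "n_subclonal": ith_res.n_subclonal,
                "ith": ith_res.ith,
            }
        )
    return pd.DataFrame(rows)
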