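"""Synthetic immunotherapy cohorts with known clone structure and outcomes.

Each simulated tumor has a truncal clone at CCF 1 plus a subclone; a
configured fraction of mutations is truncal, so the true ITH is one minus
the truncal fraction.  Read counts are binomial draws at Poisson depths
from the purity/copy-number-corrected expected VAF, and response / PFS
outcomes carry planted logistic and proportional-hazards effects of ITH
and TMB, emulating a cohort where low heterogeneity and high mutational
burden both favor benefit.  Every draw flows from one seeded generator,
so a fixed seed reproduces the cohort exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    ClinicalRecord,
    CopyNumberSegment,
    Effect,
    NeoantigenCandidate,
    VariantCall,
)
from . import variant_io

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# effect mix of called somatic exome variants (nonsynonymous-dominated)
_EFFECT_CHOICES = [
    (Effect.MISSENSE, 0.70),
    (Effect.NONSENSE, 0.05),
    (Effect.FRAMESHIFT, 0.05),
    (Effect.SPLICE, 0.03),
    (Effect.INFRAME_INDEL, 0.02),
    (Effect.SYNONYMOUS, 0.10),
    (Effect.NONCODING, 0.05),
]

_CHROM_LENGTH = 100_000_000  # nominal per-chromosome span for random positions


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions of the simulated cohort.

    Defaults mirror an anti-PD-(L)1 NSCLC cohort of 69 whole-exome-sequenced
    patients: two clones per tumor, purity 0.8, mean coverage 200x, TMB
    log-normal around 3.5 mutations/Mb on a 30 Mb footprint, and planted
    effects with hazard ratio 2.71 for high ITH and 2.66 favoring high TMB.
    """

    n_patients: int = 69
    # clone architecture
    n_clones: int = 2
    subclone_ccf: float = 0.4
    truncal_fraction_range: tuple[float, float] = (0.2, 0.9)
    # sequencing
    depth: float = 200.0
    purity: float = 0.8
    exome_mb: float = 30.0
    tmb_log_mean: float = math.log(3.5)
    tmb_log_sd: float = 0.8
    # response model: P(DCB) = logistic(alpha + beta_ith*ith + beta_tmb*tmb/tmb_scale)
    baseline_dcb_prob: float = 0.40
    beta_ith: float = -4.5
    beta_tmb: float = 2.5
    tmb_scale: float = 10.0
    orr_given_dcb: float = 0.7
    # PFS model: hazard = lambda0 * exp(gamma_ith*[ith>cut] + gamma_tmb*[tmb high])
    pfs_baseline_hazard: float = math.log(2) / 100.0  # per day
    gamma_ith: float = math.log(2.71)
    gamma_tmb: float = -math.log(2.66)
    ith_hazard_cutoff: float = 0.45
    tmb_hazard_top_fraction: float = 0.33
    censoring_rate: float = 0.2
    # neoantigens
    neo_per_mutation: float = 0.5
    kd_range: tuple[float, float] = (10.0, 5000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.purity <= 1):
            raise ValueError("purity must be in (0,1]")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0,1)")
        if not (0 < self.subclone_ccf < 1):
            raise ValueError("subclone_ccf must be in (0,1)")
        lo, hi = self.truncal_fraction_range
        if not (0 < lo <= hi < 1):
            raise ValueError("truncal_fraction_range must lie inside (0,1)")


def expected_vaf(purity: float, m: int, ccf: float, total_cn: int) -> float:
    """E[VAF] = p*m*ccf / (p*CN_t + (1-p)*2)."""
    return purity * m * ccf / (purity * total_cn + (1.0 - purity) * 2.0)


def diploid_segments(sample_id: str) -> list[CopyNumberSegment]:
    """One 1/1 segment spanning each autosome."""
    return [
        CopyNumberSegment(
            chrom=str(c),
            start=1,
            end=_CHROM_LENGTH,
            major_cn=1,
            minor_cn=1,
            sample_id=sample_id,
        )
        for c in range(1, 23)
    ]


def simulate_tumor(
    n_mutations: int,
    truncal_fraction: float,
    rng: np.random.Generator,
    sample_id: str = "P0",
    depth: float = 200.0,
    purity: float = 0.8,
    subclone_ccf: float = 0.4,
    depth_floor: int = 20,
) -> tuple[list[VariantCall], list[CopyNumberSegment], float, dict]:
    """One two-clone tumor: variants, diploid segments, purity, truth record.

    Exactly round(truncal_fraction * n) mutations are truncal (CCF 1); the
    rest belong to the subclone, so the planted ITH is 1 - truncal_fraction.
    Per-site depth is Poisson(depth) floored at ``depth_floor`` reads and
    alt counts are binomial at the expected VAF.
    """
    if not (0 < truncal_fraction < 1):
        raise ValueError("truncal_fraction must be in (0,1)")
    segments = diploid_segments(sample_id)
    n_truncal = int(round(truncal_fraction * n_mutations))
    clone_of = np.array([0] * n_truncal + [1] * (n_mutations - n_truncal))
    ccf_of_clone = (1.0, subclone_ccf)

    effects, probs = zip(*_EFFECT_CHOICES)
    eff_idx = rng.choice(len(effects), size=n_mutations, p=probs)
    chroms = rng.integers(1, 23, size=n_mutations)
    positions = rng.integers(1, _CHROM_LENGTH, size=n_mutations)
    depths = np.maximum(rng.poisson(depth, size=n_mutations), depth_floor)

    variants: list[VariantCall] = []
    truth_clone: list[int] = []
    for i in range(n_mutations):
        ccf = ccf_of_clone[clone_of[i]]
        evaf = expected_vaf(purity, 1, ccf, 2)
        if evaf > 1:
            raise ValueError("configuration implies expected VAF > 1")
        alt = int(rng.binomial(depths[i], evaf))
        ref, alt_base = _random_snv(rng)
        variants.append(
            VariantCall(
                chrom=str(chroms[i]),
                pos=int(positions[i]),
                ref=ref,
                alt=alt_base,
                ref_count=int(depths[i] - alt),
                alt_count=alt,
                gene=f"GENE{i:04d}",
                effect=effects[eff_idx[i]],
                sample_id=sample_id,
            )
        )
        truth_clone.append(int(clone_of[i]))
    truth = {
        "sample_id": sample_id,
        "true_ith": 1.0 - truncal_fraction,
        "truncal_fraction": truncal_fraction,
        "clone_ccfs": list(ccf_of_clone),
        "clone_assignment": truth_clone,
        "purity": purity,
    }
    return variants, segments, purity, truth


def _random_snv(rng: np.random.Generator) -> tuple[str, str]:
    bases = "ACGT"
    ref = bases[rng.integers(4)]
    alt = bases[rng.integers(4)]
    while alt == ref:
        alt = bases[rng.integers(4)]
    return ref, alt


def simulate_outcomes(
    truth: pd.DataFrame,
    cfg: SyntheticCohortConfig,
    rng: np.random.Generator,
) -> list[ClinicalRecord]:
    """Planted-effect response and survival outcomes from biomarker truth.

    ``truth`` needs columns patient_id, true_ith, tmb, purity.  DCB is
    Bernoulli under the logistic model; ORR is a stricter Bernoulli nested
    within DCB; PFS is exponential under the proportional-hazards model
    with independent uniform censoring at the configured rate.
    """
    alpha = math.log(cfg.baseline_dcb_prob / (1.0 - cfg.baseline_dcb_prob))
    tmb_cut = np.quantile(
        truth["tmb"], 1.0 - cfg.tmb_hazard_top_fraction, method="lower"
    )
    records = []
    for _, row in truth.iterrows():
        eta = alpha + cfg.beta_ith * row["true_ith"] + cfg.beta_tmb * (
            row["tmb"] / cfg.tmb_scale
        )
        p_dcb = 1.0 / (1.0 + math.exp(-eta))
        dcb = bool(rng.random() < p_dcb)
        orr = bool(dcb and rng.random() < cfg.orr_given_dcb)
        hazard = cfg.pfs_baseline_hazard * math.exp(
            cfg.gamma_ith * (row["true_ith"] > cfg.ith_hazard_cutoff)
            + cfg.gamma_tmb * (row["tmb"] >= tmb_cut)
        )
        t_event = rng.exponential(1.0 / hazard)
        if rng.random() < cfg.censoring_rate:
            pfs, event = t_event * rng.random(), False
        else:
            pfs, event = t_event, True
        records.append(
            ClinicalRecord(
                patient_id=row["patient_id"],
                dcb=dcb,
                orr=orr,
                pfs_days=max(float(pfs), 0.5),
                pfs_event=event,
                purity=float(row["purity"]),
            )
        )
    return records


def simulate_neoantigens(
    variants: list[VariantCall],
    truth: dict,
    cfg: SyntheticCohortConfig,
    rng: np.random.Generator,
) -> list[NeoantigenCandidate]:
    """Random 9-mer mutant/wild-type pairs hanging off nonsynonymous mutations.

    Candidate count per mutation is Poisson(neo_per_mutation); kd values
    are log-uniform over ``kd_range``; clonality and CCF follow the source
    mutation's clone.
    """
    lo, hi = cfg.kd_range
    out: list[NeoantigenCandidate] = []
    clone_ccfs = truth["clone_ccfs"]
    for variant, clone in zip(variants, truth["clone_assignment"]):
        if variant.effect not in (Effect.MISSENSE, Effect.NONSENSE):
            continue
        for _ in range(rng.poisson(cfg.neo_per_mutation)):
            wt = "".join(_AMINO_ACIDS[i] for i in rng.integers(0, 20, size=9))
            pos = int(rng.integers(9))
            mut_res = _AMINO_ACIDS[rng.integers(20)]
            while mut_res == wt[pos]:
                mut_res = _AMINO_ACIDS[rng.integers(20)]
            mut = wt[:pos] + mut_res + wt[pos + 1 :]
            kd_mut, kd_wt = np.exp(
                rng.uniform(math.log(lo), math.log(hi), size=2)
            )
            out.append(
                NeoantigenCandidate(
                    patient_id=truth["sample_id"],
                    mut_peptide=mut,
                    wt_peptide=wt,
                    hla_allele=f"HLA-A*02:{rng.integers(1, 99):02d}",
                    kd_mut=float(kd_mut),
                    kd_wt=float(kd_wt),
                    source_ccf=float(clone_ccfs[clone]),
                    clonal=clone == 0,
                )
            )
    return out


@dataclass
class SyntheticCohort:
    """Everything the downstream pipeline consumes, plus ground truth."""

    config: SyntheticCohortConfig
    variants: list[VariantCall]
    segments: list[CopyNumberSegment]
    clinical: list[ClinicalRecord]
    neoantigens: list[NeoantigenCandidate]
    truth: pd.DataFrame  # per-patient: patient_id, true_ith, tmb, n_mutations, purity
    truth_records: list[dict]

    def write(self, out_dir) -> dict:
        """Write MAF, SEG, clinical TSV, candidate TSV and truth JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "maf": out / "cohort.maf",
            "seg": out / "cohort.seg.tsv",
            "clinical": out / "clinical.tsv",
            "neoantigens": out / "neoantigens.tsv",
            "truth": out / "truth.json",
        }
        variant_io.write_maf(self.variants, paths["maf"])
        variant_io.write_segments(self.segments, paths["seg"])
        variant_io.write_clinical(self.clinical, paths["clinical"])
        pd.DataFrame(
            [
                {
                    "patient_id": c.patient_id,
                    "mut_peptide": c.mut_peptide,
                    "wt_peptide": c.wt_peptide,
                    "hla_allele": c.hla_allele,
                    "kd_mut": c.kd_mut,
                    "kd_wt": c.kd_wt,
                    "source_ccf": c.source_ccf,
                    "clonal": int(c.clonal),
                }
                for c in self.neoantigens
            ]
        ).to_csv(paths["neoantigens"], sep="\t", index=False)
        payload = {
            "config": _jsonable(asdict(self.config)),
            "patients": self.truth.to_dict(orient="records"),
        }
        paths["truth"].write_text(json.dumps(payload, indent=2, sort_keys=True))
        return {k: str(v) for k, v in paths.items()}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def simulate_cohort(
    cfg: Optional[SyntheticCohortConfig] = None,
    seed: Optional[int] = None,
) -> SyntheticCohort:
    """Simulate a full cohort under ``cfg`` (seed overrides cfg.seed)."""
    if cfg is None:
        cfg = SyntheticCohortConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    lo, hi = cfg.truncal_fraction_range
    all_variants: list[VariantCall] = []
    all_segments: list[CopyNumberSegment] = []
    all_neo: list[NeoantigenCandidate] = []
    truth_rows = []
    truth_records = []
    from .model import NONSYNONYMOUS_EFFECTS

    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        t = float(rng.uniform(lo, hi))
        tmb_true = float(rng.lognormal(cfg.tmb_log_mean, cfg.tmb_log_sd))
        n_mut = max(int(round(tmb_true * cfg.exome_mb)), 10)
        variants, segments, purity, truth = simulate_tumor(
            n_mut,
            t,
            rng,
            sample_id=pid,
            depth=cfg.depth,
            purity=cfg.purity,
            subclone_ccf=cfg.subclone_ccf,
        )
        neo = simulate_neoantigens(variants, truth, cfg, rng)
        n_nonsyn = sum(1 for v in variants if v.effect in NONSYNONYMOUS_EFFECTS)
        all_variants.extend(variants)
        all_segments.extend(segments)
        all_neo.extend(neo)
        truth_records.append(truth)
        truth_rows.append(
            {
                "patient_id": pid,
                "true_ith": truth["true_ith"],
                "tmb": n_nonsyn / cfg.exome_mb,
                "n_mutations": n_mut,
                "purity": purity,
            }
        )
    truth_df = pd.DataFrame(truth_rows)
    clinical = simulate_outcomes(truth_df, cfg, rng)
    return SyntheticCohort(
        config=cfg,
        variants=all_variants,
        segments=all_segments,
        clinical=clinical,
        neoantigens=all_neo,
        truth=truth_df,
        truth_records=truth_records,
    )
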