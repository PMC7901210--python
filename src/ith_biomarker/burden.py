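"""Tumor mutational burden, biomarker dichotomization and TMBxITH strata.

TMB is the count of nonsynonymous somatic mutations per megabase of
sequenced exome.  Patients are dichotomized at an ITH cutoff (default
0.45, ties to ITH-L) and at a TMB cutoff — either a fixed value or the
cohort's top-fraction quantile (default top 33%, ties to TMB-H) — and
combined into three strata: TMB-H, TMB-L&ITH-L and TMB-L&ITH-H, with
TMB-H collapsing both ITH states.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

from .model import NONSYNONYMOUS_EFFECTS, PatientBiomarkers, VariantCall

DEFAULT_ITH_CUTOFF = 0.45
DEFAULT_TMB_TOP_FRACTION = 0.33


def compute_tmb(
    variants: Sequence[VariantCall],
    exome_mb: float,
    include_synonymous: bool = False,
) -> float:
    """Nonsynonymous mutations per megabase of sequenced exome.

    ``exome_mb`` has no default on purpose: the callable footprint is
    assay-specific and silently guessing it would corrupt the TMB scale.
    """
    if exome_mb <= 0:
        raise ValueError(f"exome_mb must be > 0, got {exome_mb}")
    if include_synonymous:
        n = len(variants)
    else:
        n = sum(1 for v in variants if v.effect in NONSYNONYMOUS_EFFECTS)
    return n / exome_mb


def quantile_cutoff(values: Sequence[float], top_fraction: float) -> float:
    """Nearest-rank cutoff such that values >= cutoff form the top fraction.

    With no ties at the boundary, exactly ceil(n * top_fraction) values are
    "high".  The nearest-rank (inclusive) convention is used because
    interpolated quantiles differ across platforms.
    """
    n = len(values)
    if n < 3:
        raise ValueError(f"need >= 3 values to set a quantile cutoff, got {n}")
    if not 0.0 < top_fraction < 1.0:
        raise ValueError(f"top_fraction must be in (0,1), got {top_fraction}")
    ordered = sorted(values, reverse=True)
    if ordered[0] == ordered[-1]:
        warnings.warn("all values identical; quantile cutoff is degenerate")
    k = math.ceil(n * top_fraction)
    return float(ordered[k - 1])


def assign_groups(
    patients: Sequence[PatientBiomarkers],
    ith_cutoff: float = DEFAULT_ITH_CUTOFF,
    tmb_cutoff: Optional[float] = None,
    tmb_top_fraction: float = DEFAULT_TMB_TOP_FRACTION,
) -> list[PatientBiomarkers]:
    """Assign ITH-L/H, TMB-L/H and the combined stratum to each patient.

    ith <= cutoff -> ITH-L (ties low); tmb >= cutoff -> TMB-H (ties high).
    If ``tmb_cutoff`` is None it is derived from the cohort as the
    top-``tmb_top_fraction`` nearest-rank quantile.  Patients with
    non-evaluable (NaN) ITH keep their TMB group but get no ITH-dependent
    labels.
    """
    if tmb_cutoff is None:
        tmb_cutoff = quantile_cutoff([p.tmb for p in patients], tmb_top_fraction)
    out = []
    for p in patients:
        tmb_group = "TMB-H" if p.tmb >= tmb_cutoff else "TMB-L"
        if math.isnan(p.ith):
            ith_group = combo = None
        else:
            ith_group = "ITH-L" if p.ith <= ith_cutoff else "ITH-H"
            if tmb_group == "TMB-H":
                combo = "TMB-H"
            else:
                combo = f"TMB-L&{ith_group}"
        out.append(
            PatientBiomarkers(
                patient_id=p.patient_id,
                tmb=p.tmb,
                ith=p.ith,
                tnb=p.tnb,
                ith_group=ith_group,
                tmb_group=tmb_group,
                combo_group=combo,
            )
        )
    return out
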