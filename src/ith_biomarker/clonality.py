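"""Cancer cell fraction estimation and the intratumoral heterogeneity statistic.

The mutation-frequency-based construction: the expected VAF of a mutation
present in a fraction ``ccf`` of tumor cells, on ``m`` of ``CN_t`` copies,
in a sample of purity ``p`` is

    E[VAF] = p * m * ccf / (p * CN_t + (1 - p) * 2)

Inverting gives the point estimate; uncertainty comes from the exact
Clopper-Pearson binomial interval of the observed allele fraction pushed
through the same linear map.  A mutation is clonal when its CCF (interval
or point, per policy) is compatible with 1; ITH is the subclonal fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy.stats import beta

from .model import CCFEstimate, CopyNumberSegment, ITHResult, VariantCall


@dataclass(frozen=True)
class ClonalityConfig:
    """Constants of the clonality caller; every threshold is explicit.

    policy: "ci-overlap" calls a mutation clonal when the upper bound of its
    CCF credible interval reaches ``ci_clonal_bound`` (default 0.95);
    "point-threshold" compares the point estimate against ``tau``.
    Boundary ties resolve to clonal (>= is inclusive).
    """

    policy: str = "ci-overlap"
    ci_clonal_bound: float = 0.95
    tau: float = 0.9
    interval_level: float = 0.95
    min_mutations: int = 5
    ctdna_rho: float = 0.5

    def __post_init__(self) -> None:
        if self.policy not in ("ci-overlap", "point-threshold"):
            raise ValueError(f"unknown clonality policy {self.policy!r}")


DEFAULT_CONFIG = ClonalityConfig()


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion k/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def estimate_multiplicity(
    vaf: float, purity: float, total_cn: int, major_cn: int
) -> int:
    """Most-likely number of mutated copies per tumor cell.

    m = round(vaf / purity * (purity * CN_t + (1 - purity) * 2)), clamped
    to [1, max(major_cn, 1)] — a clonal mutation cannot sit on more copies
    than the major allele carries.
    """
    if purity <= 0 or purity > 1:
        raise ValueError(f"purity must be in (0,1], got {purity}")
    if total_cn < 1:
        raise ValueError(f"total_cn must be >= 1, got {total_cn}")
    if not 0 <= vaf <= 1:
        raise ValueError(f"vaf must be in [0,1], got {vaf}")
    denom_adjust = purity * total_cn + (1.0 - purity) * 2.0
    m = round(vaf / purity * denom_adjust)
    return int(min(max(m, 1), max(major_cn, 1)))


def estimate_ccf(
    variant: VariantCall,
    purity: float,
    cn: CopyNumberSegment,
    m: Optional[int] = None,
    config: ClonalityConfig = DEFAULT_CONFIG,
) -> CCFEstimate:
    """CCF point estimate and Clopper-Pearson credible interval for one mutation.

    The linear map ccf = vaf * (p*CN_t + (1-p)*2) / (p*m) is applied to the
    observed VAF and to both interval bounds.  Reported values are clamped
    to [0,1]; the pre-clamp upper bound (``ccf_high_raw``) drives clonality.
    """
    n = variant.depth
    if n < 1:
        raise ValueError(
            f"variant {variant.chrom}:{variant.pos} has no reads; cannot estimate CCF"
        )
    if m is None:
        m = estimate_multiplicity(variant.vaf, purity, cn.total_cn, cn.major_cn)
    if purity * m <= 0:
        raise ValueError("purity * multiplicity must be positive")

    scale = (purity * cn.total_cn + (1.0 - purity) * 2.0) / (purity * m)
    vaf_low, vaf_high = clopper_pearson(variant.alt_count, n, config.interval_level)
    ccf_point = variant.vaf * scale
    ccf_high_raw = vaf_high * scale

    clamp = lambda x: min(max(x, 0.0), 1.0)
    est = dict(
        multiplicity=m,
        ccf=clamp(ccf_point),
        ccf_low=clamp(vaf_low * scale),
        ccf_high=clamp(ccf_high_raw),
        ccf_high_raw=ccf_high_raw,
    )
    label = _classify(est["ccf"], est["ccf_high_raw"], config)
    return CCFEstimate(variant=variant, label=label, **est)


def _classify(ccf: float, ccf_high_raw: float, config: ClonalityConfig) -> str:
    if config.policy == "ci-overlap":
        return "clonal" if ccf_high_raw >= config.ci_clonal_bound else "subclonal"
    return "clonal" if ccf >= config.tau else "subclonal"


def classify_clonality(
    est: CCFEstimate, config: ClonalityConfig = DEFAULT_CONFIG
) -> str:
    """Clonal/subclonal call under the configured policy (ties -> clonal)."""
    return _classify(est.ccf, est.ccf_high_raw, config)


def compute_ith(
    estimates: Sequence[CCFEstimate],
    patient_id: str = "",
    config: ClonalityConfig = DEFAULT_CONFIG,
) -> ITHResult:
    """ITH = subclonal / (clonal + subclonal) over classifiable mutations.

    Patients with fewer than ``config.min_mutations`` classifiable mutations
    are flagged non-evaluable rather than silently reported as 0.
    """
    n_clonal = sum(1 for e in estimates if e.label == "clonal")
    n_subclonal = len(estimates) - n_clonal
    evaluable = len(estimates) >= config.min_mutations
    if not evaluable:
        warnings.warn(
            f"patient {patient_id!r}: only {len(estimates)} classifiable "
            f"mutation(s) (< {config.min_mutations}); ITH non-evaluable"
        )
    return ITHResult(
        patient_id=patient_id,
        n_clonal=n_clonal,
        n_subclonal=n_subclonal,
        evaluable=evaluable,
    )


def compute_ith_ctdna(
    variants: Sequence[VariantCall],
    rho: Optional[float] = None,
    patient_id: str = "",
    config: ClonalityConfig = DEFAULT_CONFIG,
) -> ITHResult:
    """Panel/ctDNA variant of ITH when purity and copy number are unavailable.

    Each VAF is normalized by the patient's maximum VAF; a mutation is
    clonal when its normalized frequency reaches ``rho`` (default 0.5).
    Invariant to rescaling all VAFs by a positive constant.
    """
    if rho is None:
        rho = config.ctdna_rho
    vafs = [v.vaf for v in variants if v.depth > 0]
    max_vaf = max(vafs, default=0.0)
    if max_vaf <= 0.0:
        warnings.warn(f"patient {patient_id!r}: all VAFs zero; ctDNA ITH non-evaluable")
        return ITHResult(patient_id, 0, 0, evaluable=False)
    n_clonal = sum(1 for f in vafs if f / max_vaf >= rho)
    n_subclonal = len(vafs) - n_clonal
    # panel assays carry few variants by design; no minimum-count gate here
    return ITHResult(
        patient_id=patient_id,
        n_clonal=n_clonal,
        n_subclonal=n_subclonal,
        evaluable=True,
    )
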