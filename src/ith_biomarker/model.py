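"""Core domain types shared by every stage of the pipeline.

All genomic coordinates are 1-based inclusive (MAF/SEG convention; VCF
positions are already 1-based and are used as-is).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Effect(str, Enum):
    """Functional class of a somatic variant.

    The first five classes count as nonsynonymous for tumor mutational
    burden; ``synonymous`` and ``noncoding`` do not.
    """

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    NONCODING = "noncoding"


NONSYNONYMOUS_EFFECTS = frozenset(
    {
        Effect.MISSENSE,
        Effect.NONSENSE,
        Effect.FRAMESHIFT,
        Effect.SPLICE,
        Effect.INFRAME_INDEL,
    }
)


@dataclass(frozen=True)
class VariantCall:
    """One somatic mutation with allelic read counts.

    ``ref_count``/``alt_count`` are tumor-sample read depths supporting the
    reference and alternate allele; their ratio is the observed variant
    allele frequency (VAF) that drives cancer-cell-fraction estimation.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ref_count: int
    alt_count: int
    gene: str = ""
    effect: Effect = Effect.MISSENSE
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError(
                f"negative read count at {self.chrom}:{self.pos}: "
                f"ref={self.ref_count}, alt={self.alt_count}"
            )

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def vaf(self) -> float:
        """alt reads / total reads; NaN if depth is zero."""
        if self.depth == 0:
            return float("nan")
        return self.alt_count / self.depth


@dataclass(frozen=True)
class CopyNumberSegment:
    """Allele-specific copy-number segment, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.minor_cn < 0 or self.major_cn < 0:
            raise ValueError("copy numbers must be >= 0")
        if self.major_cn < self.minor_cn:
            raise ValueError(
                f"major_cn {self.major_cn} < minor_cn {self.minor_cn} "
                f"({self.chrom}:{self.start}-{self.end})"
            )

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient outcomes and tumor purity.

    dcb: durable clinical benefit (True) vs no durable benefit.
    orr: objective response (True) vs non-objective response.
    pfs_days: progression-free survival in days; pfs_event True if
    progression was observed (False = censored).
    """

    patient_id: str
    dcb: bool
    orr: bool
    pfs_days: float
    pfs_event: bool
    purity: float = 1.0

    def __post_init__(self) -> None:
        if self.pfs_days <= 0:
            raise ValueError(f"pfs_days must be > 0 for {self.patient_id}")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0,1] for {self.patient_id}")


@dataclass(frozen=True)
class CCFEstimate:
    """Cancer cell fraction of one mutation with its 95% credible interval.

    ``multiplicity`` is the number of mutated copies per tumor cell (m).
    ``ccf`` is clamped to [0,1] for reporting; ``ccf_high_raw`` keeps the
    pre-clamp upper bound that drives the clonality call.
    """

    variant: VariantCall
    multiplicity: int
    ccf: float
    ccf_low: float
    ccf_high: float
    ccf_high_raw: float
    label: str  # "clonal" | "subclonal"

    def __post_init__(self) -> None:
        if not (self.ccf_low <= self.ccf <= self.ccf_high + 1e-12):
            raise ValueError(
                f"interval does not bracket point estimate: "
                f"[{self.ccf_low}, {self.ccf_high}] vs {self.ccf}"
            )
        if self.label not in ("clonal", "subclonal"):
            raise ValueError(f"unknown clonality label {self.label!r}")


@dataclass(frozen=True)
class ITHResult:
    """Per-patient intratumoral heterogeneity: subclonal mutation fraction."""

    patient_id: str
    n_clonal: int
    n_subclonal: int
    evaluable: bool = True

    @property
    def n_total(self) -> int:
        return self.n_clonal + self.n_subclonal

    @property
    def ith(self) -> float:
        if not self.evaluable or self.n_total == 0:
            return float("nan")
        return self.n_subclonal / self.n_total


@dataclass
class PatientBiomarkers:
    """Per-patient biomarker values and dichotomized group labels."""

    patient_id: str
    tmb: float
    ith: float  # NaN if non-evaluable
    tnb: Optional[float] = None
    ith_group: Optional[str] = None  # "ITH-L" | "ITH-H"
    tmb_group: Optional[str] = None  # "TMB-L" | "TMB-H"
    combo_group: Optional[str] = None  # "TMB-H" | "TMB-L&ITH-L" | "TMB-L&ITH-H"


@dataclass(frozen=True)
class NeoantigenCandidate:
    """Mutant/wild-type peptide pair with MHC binding and clonality context.

    kd values are predicted peptide–MHC dissociation constants in nM
    (lower = stronger binding).
    """

    patient_id: str
    mut_peptide: str
    wt_peptide: str
    hla_allele: str
    kd_mut: float
    kd_wt: float
    source_ccf: float
    clonal: bool

    def __post_init__(self) -> None:
        if len(self.mut_peptide) != len(self.wt_peptide):
            raise ValueError("mutant and wild-type peptides must have equal length")
        if not (8 <= len(self.mut_peptide) <= 11):
            raise ValueError("peptides must be 8-11-mers")
        if self.mut_peptide == self.wt_peptide:
            raise ValueError("mutant peptide identical to wild-type")
        if self.kd_mut <= 0 or self.kd_wt <= 0:
            raise ValueError("dissociation constants must be > 0")

    @property
    def mutated_positions(self) -> list[int]:
        """1-based positions where mutant differs from wild-type."""
        return [
            i + 1
            for i, (m, w) in enumerate(zip(self.mut_peptide, self.wt_peptide))
            if m != w
        ]


@dataclass
class FitnessResult:
    """Per-patient neoantigen fitness summary."""

    patient_id: str
    fitness: float  # <= 0: -(clone-frequency-weighted max of A*R)
    clonal_neoantigen_proportion: float  # NaN if no candidates
    per_candidate: list = field(default_factory=list)  # (candidate, A, R, A*R)
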