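"""Neoantigen quality score and the neoantigen fitness model.

The fitness model scores each mutant peptide by two factors: the MHC
presentation amplitude A = Kd_wt / Kd_mut, and the T-cell recognition
probability R, a logistic aggregate of gapless local-alignment scores
between the mutant peptide and a reference set of experimentally
validated immunogenic epitopes:

    S = sum_e exp(-k * (a - |s, e|)),   R = S / (1 + S)

with midpoint a = 26 and steepness k = 4.87 under BLOSUM62 scoring (the
canonical parameterization; both configurable).  A patient's fitness is
the negated clone-frequency-weighted maximum of A*R over each clone's
candidates, so more immunogenic dominant clones give more negative
fitness.

The composite neoantigen quality score combines residue-chemistry,
peptide-position, MHC-binding and clonal-frequency components on [0,1];
its functional form is a declared package default and each component
weight is configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .model import FitnessResult, NeoantigenCandidate


@dataclass(frozen=True)
class FitnessParams:
    """Fitness-model constants: alignment-score midpoint ``a`` and slope ``k``."""

    a: float = 26.0
    k: float = 4.87
    matrix: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.a <= 0 or self.k <= 0:
            raise ValueError("fitness parameters a and k must be > 0")


DEFAULT_FITNESS_PARAMS = FitnessParams()

# residues with hydrophobic side chains (Kyte-Doolittle positive)
_HYDROPHOBIC = frozenset("AVLIMFWC")


def _make_aligner(matrix: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # gapless: any gap is prohibitively expensive
    aligner.open_gap_score = -1e9
    aligner.extend_gap_score = -1e9
    return aligner


def alignment_score(peptide: str, epitope: str, matrix: str = "BLOSUM62") -> float:
    """Gapless Smith-Waterman local-alignment score |s, e| under BLOSUM62."""
    return float(_make_aligner(matrix).score(peptide, epitope))


def amplitude(kd_wt: float, kd_mut: float) -> float:
    """MHC presentation amplitude A = Kd_wt / Kd_mut (>1 favors the mutant)."""
    if kd_wt <= 0 or kd_mut <= 0:
        raise ValueError("dissociation constants must be > 0")
    return kd_wt / kd_mut


def recognition_probability(
    mut_peptide: str,
    epitope_set: Sequence[str],
    params: FitnessParams = DEFAULT_FITNESS_PARAMS,
) -> float:
    """T-cell recognition probability R = S / (1 + S) in [0, 1).

    S sums exp(-k * (a - score)) over the epitope set; an epitope aligning
    exactly at the midpoint ``a`` contributes 1, putting R at 0.5 for a
    single such epitope.  An empty epitope set gives R = 0.
    """
    if not epitope_set:
        warnings.warn("empty epitope set; recognition probability is 0")
        return 0.0
    aligner = _make_aligner(params.matrix)
    s = sum(
        math.exp(-params.k * (params.a - float(aligner.score(mut_peptide, e))))
        for e in epitope_set
    )
    return s / (1.0 + s)


def candidate_fitness_terms(
    candidate: NeoantigenCandidate,
    epitope_set: Sequence[str],
    params: FitnessParams = DEFAULT_FITNESS_PARAMS,
) -> tuple[float, float, float]:
    """(A, R, A*R) for one candidate — the product enters the patient aggregate."""
    A = amplitude(candidate.kd_wt, candidate.kd_mut)
    R = recognition_probability(candidate.mut_peptide, epitope_set, params)
    return A, R, A * R


def patient_fitness(
    candidates_by_clone: dict, clone_frequencies: dict
) -> float:
    """fitness = -sum_clones X_clone * max(A*R over the clone's candidates).

    ``candidates_by_clone`` maps clone label -> list of (A, R, product)
    triples (or bare products); clones without candidates contribute 0.
    Frequencies must be non-negative and sum to at most 1.
    """
    for clone, x in clone_frequencies.items():
        if x < 0:
            raise ValueError(f"negative clone frequency for {clone!r}")
    if sum(clone_frequencies.values()) > 1.0 + 1e-9:
        raise ValueError("clone frequencies must sum to <= 1")
    total = 0.0
    for clone, x in clone_frequencies.items():
        terms = candidates_by_clone.get(clone, [])
        if not terms:
            continue
        products = [t[-1] if isinstance(t, (tuple, list)) else float(t) for t in terms]
        total += x * max(products)
    return -total


def default_clone_frequencies(
    candidates: Sequence[NeoantigenCandidate],
) -> dict:
    """Two-level clonal/subclonal frequency split.

    X_clonal = 1 (truncal mutations are in every tumor cell); X_subclonal =
    mean CCF of the subclonal candidates' source mutations, 0 if none.
    Only the clonal/subclonal dichotomy is available from the clonality
    caller, so this is the finest resolution the pipeline supports.
    """
    sub_ccfs = [c.source_ccf for c in candidates if not c.clonal]
    has_clonal = any(c.clonal for c in candidates)
    freqs = {}
    if has_clonal:
        freqs["clonal"] = 1.0
    if sub_ccfs:
        freqs["subclonal"] = min(sum(sub_ccfs) / len(sub_ccfs), 1.0)
    total = sum(freqs.values())
    if total > 1.0:  # weights must form a (sub-)distribution over clones
        freqs = {k: v / total for k, v in freqs.items()}
    return freqs


def evaluate_patient_fitness(
    candidates: Sequence[NeoantigenCandidate],
    epitope_set: Sequence[str],
    params: FitnessParams = DEFAULT_FITNESS_PARAMS,
    patient_id: str = "",
) -> FitnessResult:
    """Full per-patient fitness evaluation from raw candidates."""
    per_candidate = [
        (c, *candidate_fitness_terms(c, epitope_set, params)) for c in candidates
    ]
    by_clone: dict[str, list[float]] = {}
    for c, A, R, prod in per_candidate:
        by_clone.setdefault("clonal" if c.clonal else "subclonal", []).append(prod)
    fitness = patient_fitness(by_clone, default_clone_frequencies(candidates))
    return FitnessResult(
        patient_id=patient_id,
        fitness=fitness,
        clonal_neoantigen_proportion=clonal_neoantigen_proportion(candidates)
        if candidates
        else math.nan,
        per_candidate=per_candidate,
    )


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the composite quality score; normalized to sum to 1."""

    aa: float = 0.25
    struct: float = 0.25
    hla: float = 0.25
    freq: float = 0.25

    def normalized(self) -> "ScoreWeights":
        vals = (self.aa, self.struct, self.hla, self.freq)
        if any(v < 0 for v in vals):
            raise ValueError("weights must be non-negative")
        total = sum(vals)
        if total <= 0:
            raise ValueError("weight vector must have positive sum")
        return ScoreWeights(*(v / total for v in vals))


DEFAULT_WEIGHTS = ScoreWeights()

# half-saturation constant of the MHC-binding component (nM); 500 nM is the
# conventional weak-binder threshold
KD_MIDPOINT_NM = 500.0


def neoantigen_score(
    candidate: NeoantigenCandidate,
    weights: ScoreWeights = DEFAULT_WEIGHTS,
) -> float:
    """Composite neoantigen quality on [0,1].

    Components: residue chemistry (1 if the substitution switches
    hydrophobicity class), peptide position (1 outside the MHC anchor
    positions 2 and C-terminus, else 0.5), MHC binding 1/(1 + Kd_mut/500),
    and the source mutation's CCF.
    """
    w = weights.normalized()
    pos = candidate.mutated_positions[0]
    length = len(candidate.mut_peptide)
    wt_res = candidate.wt_peptide[pos - 1]
    mut_res = candidate.mut_peptide[pos - 1]
    s_aa = 1.0 if (wt_res in _HYDROPHOBIC) != (mut_res in _HYDROPHOBIC) else 0.0
    s_struct = 0.5 if pos in (2, length) else 1.0
    s_hla = 1.0 / (1.0 + candidate.kd_mut / KD_MIDPOINT_NM)
    s_freq = min(max(candidate.source_ccf, 0.0), 1.0)
    return w.aa * s_aa + w.struct * s_struct + w.hla * s_hla + w.freq * s_freq


def top_candidates(
    candidates: Sequence[NeoantigenCandidate],
    n: int = 100,
    weights: ScoreWeights = DEFAULT_WEIGHTS,
) -> list[NeoantigenCandidate]:
    """Top-n candidates by quality score; ties break lexicographically.

    The ordering is total, so the selected set is invariant to any
    permutation of the input list.
    """
    ranked = sorted(
        candidates, key=lambda c: (-neoantigen_score(c, weights), c.mut_peptide)
    )
    return ranked[:n]


def clonal_neoantigen_proportion(candidates: Sequence[NeoantigenCandidate]) -> float:
    """Fraction of candidates whose source mutation is clonal."""
    if not candidates:
        raise ValueError("no candidates; clonal proportion non-evaluable")
    return sum(1 for c in candidates if c.clonal) / len(candidates)


def read_epitopes(path) -> list[str]:
    """Epitope reference set from FASTA or a single-column TSV/text file."""
    path = str(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        return [str(rec.seq) for rec in SeqIO.parse(path, "fasta")]
    with open(path) as fh:
        return [line.strip().split("\t")[0] for line in fh if line.strip()]
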