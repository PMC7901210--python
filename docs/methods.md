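# Methods

This note documents the models implemented in `ith_biomarker`, the
constants they expose, the design choices made where the construction was
genuinely open, and what the synthetic cohort does and does not emulate.

## Cancer cell fraction estimation

For a somatic mutation with `alt` of `n` reads in a sample of purity
`p ∈ (0,1]`, at a locus with allele-specific copy number (major, minor),
the model assumes every tumor cell in the mutated fraction carries the
variant on `m` of `CN_t = major + minor` copies, and contaminating normal
cells are diploid and unmutated:

```
E[VAF] = p · m · CCF / (p · CN_t + (1 − p) · 2)
```

- **Multiplicity** `m = round(VAF/p · (p·CN_t + (1−p)·2))`, clamped to
  `[1, max(major, 1)]`. The clamp encodes that a mutation cannot occupy
  more copies than the major allele count, and that an observed mutation
  occupies at least one copy.
- **Point estimate**: the linear map inverted at the observed VAF.
  Estimates above 1 (sampling noise, purity error) are clamped to 1 for
  reporting, but the pre-clamp value feeds classification so boundary
  behavior is not distorted by the clamp.
- **Interval**: the exact Clopper–Pearson 95% binomial interval of
  `alt/n` (Beta-quantile form) transformed through the same linear map.
  Exact intervals were chosen over normal approximations because panel
  and low-coverage sites otherwise produce degenerate bounds at `alt = 0`
  or `alt = n`. The interval level is configurable
  (`ClonalityConfig.interval_level`, default 0.95).
- Variants with no reads are excluded from CCF estimation; variants with
  no covering copy-number segment default to diploid heterozygous
  (major 1 / minor 1), a deliberate neutral prior.

## Clonality policies and ITH

Two interchangeable decision rules (`ClonalityConfig.policy`):

- `ci-overlap` (default): clonal iff the (pre-clamp) CCF interval upper
  bound ≥ 0.95. This asks whether the data are *compatible* with full
  clonality and is robust at moderate depth.
- `point-threshold`: clonal iff the point estimate ≥ τ (default 0.9),
  the simpler rule some pipelines use at high depth.

All boundary ties resolve toward *clonal* (≥), a deterministic and
documented convention. ITH is the subclonal fraction of classifiable
mutations; patients with fewer than `min_mutations` (default 5) are
flagged non-evaluable rather than reported as ITH 0 — a silent zero would
masquerade as "fully clonal".

The ctDNA variant normalizes each VAF by the patient's maximum VAF and
calls a mutation clonal when the normalized frequency ≥ ρ (default 0.5).
The normalization removes the unknown, shared ctDNA-fraction scale factor;
the statistic is provably invariant to multiplying all VAFs by a positive
constant. No minimum-count gate is applied: targeted panels carry few
variants by design. All-zero VAFs are non-evaluable.

## TMB and stratification

TMB counts missense, nonsense, frameshift, splice and in-frame-indel
variants per megabase; synonymous and noncoding calls are excluded by
default (an `include_synonymous` switch exists because assay conventions
differ). The exome footprint (Mb) must be supplied explicitly — it is
assay-specific, and a silent default would corrupt the TMB scale.

Dichotomization: ITH ≤ 0.45 → ITH-L (ties low); TMB at the cohort's
top-33% quantile, nearest-rank inclusive convention, ties high. The
nearest-rank rule is used because interpolated quantiles differ across
software platforms, which would make the "top-k patients" property
irreproducible. With 69 patients this yields exactly 23 TMB-high patients
absent ties. The three combined strata are TMB-H (collapsing both ITH
states), TMB-L&ITH-L and TMB-L&ITH-H; non-evaluable-ITH patients retain
TMB-only labels.

## Association layer

- **Fisher exact** (via scipy): two-sided p by the probability-mass
  convention — the sum of hypergeometric probabilities of all tables with
  the observed margins no more probable than the observed table. The test
  suite verifies exact agreement with integer-arithmetic enumeration over
  every 2×2 table with total ≤ 40. Odds ratio: sample `ad/bc` by default,
  conditional MLE optionally. A zero margin returns p = 1 with a warning.
- **Kaplan–Meier / log-rank / Cox** (via lifelines): median = first time
  the product-limit estimate drops to ≤ 0.5 (undefined if never reached);
  Cox fits use Efron tie handling (PFS in days carries heavy ties) with
  Wald 95% CIs `exp(β ± 1.96·SE)`. Hazard ratios are oriented so the
  unfavorable group (ITH-H, TMB-L) has HR > 1. Fewer than 5 events per
  arm triggers a warning rather than an error.
- **Interaction**: a Cox model with both group indicators and their
  product; the reported p is the Wald p of the product term. Rank-deficient
  (nested/collinear) groupings raise rather than silently dropping terms.
- **Spearman**: average ranks for ties; for n ≤ 9 the p-value is computed
  by exhaustive permutation enumeration (two-sided, |ρ| ≥ observed),
  otherwise by the usual t-approximation.

## Neoantigen quality and fitness

Amplitude `A = Kd_wt / Kd_mut` measures differential MHC presentation of
the mutant versus its wild-type counterpart. Recognition probability

```
R = S / (1 + S),   S = Σ_e exp(−k (a − |s, e|))
```

aggregates gapless Smith–Waterman BLOSUM62 alignment scores `|s, e|`
against a reference set of validated immunogenic epitopes; `a = 26` is
the logistic midpoint and `k = 4.87` the steepness (the canonical
parameterization of this model; both configurable, as is the substitution
matrix). Gaplessness is enforced with prohibitive gap penalties inside
Biopython's aligner. Note that R saturates to 1.0 in floating point for
alignment scores far above `a`; the regime of interest — partial matches
near the midpoint — is well resolved.

Patient fitness is `−Σ_clones X_clone · max(A·R)` over each clone's
candidates. Only the clonal/subclonal dichotomy is available from the
clonality caller, so the default clone frequencies are the two-level
split X_clonal = 1, X_subclonal = mean source-mutation CCF, normalized to
a distribution when the raw weights exceed 1 (the weighting must form a
sub-distribution for the aggregate to stay a weighted maximum). Clones
without candidates contribute zero.

The composite quality score is a weighted mean (default equal weights) of
four [0,1] components: hydrophobicity-class switch of the substituted
residue; position outside the MHC anchor positions (2 and C-terminus;
anchor hits score 0.5, so this component's floor is 0.5 by construction);
MHC binding `1/(1 + Kd_mut/500 nM)` with the conventional 500 nM
weak-binder midpoint; and the source mutation's CCF. The functional form
is a declared package default, replaceable via `ScoreWeights` and
intended to be swapped for an assay-calibrated score when one is
available. Top-N selection (default 100) orders by score with
lexicographic peptide tie-breaks, making the selected set permutation-
invariant.

## Synthetic cohort generator

The generator emulates a 69-patient anti-PD-(L)1 NSCLC whole-exome
cohort:

- **Clone structure**: two clones — truncal at CCF 1 and one subclone at
  CCF 0.4; the truncal fraction *t* is drawn per patient from
  Uniform(0.2, 0.9), so planted ITH = 1 − *t* spans both sides of the
  0.45 cutoff. Exactly round(*t*·n) mutations are truncal, which makes
  the planted ITH exact rather than binomially noisy.
- **Sequencing**: purity 0.8, mean depth 200× (Poisson per site, floored
  at 20 reads to keep exact binomial intervals non-degenerate), diploid
  copy-number profile, alt counts binomial at the expected VAF.
- **Burden**: per-patient TMB log-normal (median 3.5 mut/Mb, σ = 0.8) on
  a 30 Mb footprint — a realistic NSCLC exome burden distribution whose
  top-33% cutoff lands in the few-mutations-per-Mb range.
- **Outcomes**: DCB ~ Bernoulli(logistic(α + β_ith·ITH + β_tmb·TMB/10))
  with α = logit(0.40), β_ith = −4.5, β_tmb = 2.5; ORR a stricter
  Bernoulli (0.7) nested within DCB; PFS exponential with baseline median
  100 days and log-hazards +log 2.71 for ITH > 0.45 and −log 2.66 for
  top-tercile TMB — the planted hazard ratios; 20% independent uniform
  censoring. The logistic coefficients were set analytically (closed-form
  stratum means at large n) so the planted DCB rates are ≈39%/16% for
  ITH-L/H, ≈46%/18% for TMB-H/L and ≈46%/28%/8% across the three combined
  strata.
- **Neoantigens**: Poisson(0.5) random 9-mer single-substitution
  candidates per missense/nonsense mutation, Kd log-uniform on
  [10, 5000] nM, clonality inherited from the source mutation.

All draws flow from one `numpy` Generator, so a seed fixes the full
cohort byte-for-byte across platforms.

**What the generator does not emulate** — and therefore what passing
tests do not establish about real data: mutational signatures and
sequence context; copy-number aberrations and purity estimation error
(CCF inputs are taken as exact); multi-region or more-than-two-clone
architectures; panel-of-normals artifacts and variant-calling error;
informative censoring; correlation between TMB and ITH (simulated
independent); and any biological link between peptide sequence and Kd.
Recovery results quantify estimator behavior under the stated sampling
model, not robustness to these real-data features.

## Problem sizes and numerical choices

Simulation-backed tests use the sizes at which their guarantees are
stated: 20 replicates of 100-mutation tumors at depth 200 for ITH
recovery (±0.05); a 200-patient cohort for rank-correlation recovery
(ρ ≥ 0.9); 50 replicates of n = 2000 for Cox recovery of HR 2.7 (±10% in
≥90%); 200 null replicates of n = 2000 for interaction-test calibration
(rejection rate in [0.03, 0.07] at α = 0.05). Fisher enumeration covers
all 132,470 non-degenerate tables with total ≤ 40 exactly. Reports are
serialized with sorted keys and embed a SHA-256 config digest, so
identical config + seed gives byte-identical output.

## Known limitations

- Single-sample, frequency-based clonality cannot separate distinct
  subclones at similar CCFs; the pipeline deliberately reports only the
  clonal/subclonal dichotomy, not clone trees.
- The ITH cutoff 0.45 and TMB top-tercile are cohort-derived analysis
  constants, not universal thresholds; both are exposed as configuration.
- Multiplicity is a point assignment (rounded), not marginalized; at low
  depth this can bias CCF for high-copy loci.
- The composite neoantigen score is a stand-in ranking, not a validated
  immunogenicity predictor.
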