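# ith-biomarker

Intratumoral heterogeneity (ITH) as a predictive biomarker for immune
checkpoint inhibitor (ICI) therapy, computed from single-sample somatic
variant calls — together with tumor mutational burden (TMB), combined
TMB×ITH stratification, the response/survival association layer, and a
neoantigen quality + fitness model.

The package is aimed at translational cancer-genomics analysts who have
per-patient somatic calls (MAF or VCF with allelic depths), tumor purity,
allele-specific copy number and a clinical outcome table, and want to ask:
*does the subclonal fraction of a patient's mutations predict benefit from
anti-PD-(L)1 therapy, alone or combined with TMB?*

## The method

**Cancer cell fraction (CCF).** A mutation observed at variant allele
frequency (VAF) in a sample of purity *p*, at a locus of total tumor copy
number *CN<sub>t</sub>*, carried on *m* copies, has expected VAF

```
E[VAF] = p · m · CCF / (p · CN_t + (1 − p) · 2)
```

Multiplicity is estimated as *m* = round(VAF/p · (p·CN<sub>t</sub> + (1−p)·2))
clamped to [1, major CN], and the map is inverted for the CCF point
estimate. Uncertainty comes from the exact Clopper–Pearson 95% binomial
interval of the allele fraction pushed through the same linear map.

**Clonality and ITH.** A mutation is *clonal* when the upper bound of its
CCF interval reaches 0.95 (alternative: point estimate ≥ τ). Then

```
ITH = n_subclonal / (n_clonal + n_subclonal)
```

so ITH = 0 means a fully clonal tumor. For ctDNA panels, where purity and
copy number are unavailable, VAFs are normalized by the patient's maximum
VAF and a mutation is clonal when its normalized frequency ≥ ρ (default
0.5) — this variant is invariant to rescaling all VAFs.

**Biomarker strata.** TMB = nonsynonymous mutations / Mb. Patients split
at ITH ≤ 0.45 (ITH-L) and at the cohort's top-33% TMB quantile (TMB-H,
nearest-rank), and combine into three strata: TMB-H, TMB-L&ITH-L,
TMB-L&ITH-H.

**Associations.** Fisher exact tests (probability-mass two-sided p) on
durable clinical benefit (DCB) and objective response (ORR); Kaplan–Meier
medians and log-rank tests on progression-free survival (PFS); univariable
Cox hazard ratios with Wald 95% CIs (Efron ties); a Cox product term for
the TMB×ITH interaction; Spearman correlation (exact p for n ≤ 9).

**Neoantigen fitness.** For each mutant peptide, amplitude
A = K<sub>d</sub><sup>WT</sup>/K<sub>d</sub><sup>MUT</sup> and recognition
probability R = S/(1+S) with S = Σ<sub>e</sub> exp(−k(a − |s,e|)), where
|s,e| is the gapless BLOSUM62 local-alignment score against an immunogenic
epitope set (a = 26, k = 4.87). Patient fitness is the negated
clone-frequency-weighted maximum of A·R. A composite quality score on
[0,1] combines residue chemistry, anchor-position, MHC-binding and CCF
components.

## Worked example

Simulate a 69-patient cohort with planted effects (low ITH and high TMB
favor benefit) and run the full pipeline:

```python
from ith_biomarker import simulate_cohort, SyntheticCohortConfig
from ith_biomarker.pipeline import RunConfig, run_pipeline

cohort = simulate_cohort(SyntheticCohortConfig(n_patients=69, seed=1))
rep = run_pipeline(RunConfig(exome_mb=30.0),
                   cohort.variants, cohort.segments, cohort.clinical)
g = rep["associations"]["ith_groups"]
print(f"DCB rate: {g['dcb_rate']['ITH-L']:.1%} vs {g['dcb_rate']['ITH-H']:.1%}")
print(f"mPFS: {g['median_pfs_days']['ITH-L']:.0f} vs "
      f"{g['median_pfs_days']['ITH-H']:.0f} days (log-rank p={g['logrank_p']:.2g})")
print(f"HR = {g['hr']:.2f} [95% CI {g['hr_ci'][0]:.2f}-{g['hr_ci'][1]:.2f}]")
```

prints

```
DCB rate: 23.5% vs 11.4%
mPFS: 189 vs 66 days (log-rank p=7.4e-05)
HR = 3.12 [95% CI 1.74-5.62]
```

i.e. ITH-low patients (ITH ≤ 0.45) show a higher durable-benefit rate, a
three-fold longer median PFS, and a hazard ratio of ~3 for progression in
the ITH-high group — the planted direction recovered end-to-end from raw
read counts. Per-patient rows carry the clonal/subclonal counts behind
each ITH value, e.g.

```
{'patient_id': 'P001', 'n_clonal': 113, 'n_subclonal': 90, 'ith': 0.443,
 'tmb': 5.93, 'ith_group': 'ITH-L', 'tmb_group': 'TMB-H', 'combo_group': 'TMB-H'}
```

The same stages are available from the shell:

```sh
ith-biomarker simulate --seed 1 --out-dir sim/
ith-biomarker run --cohort-dir sim/ --exome-mb 30 --out report.json
```

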