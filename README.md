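# exonsurv

Exon-level RNA-seq inclusion indices, patient stratification, and survival
analysis for exon-skipping biomarkers.

## The problem

Aberrant splicing can delete a single exon from an otherwise expressed gene.
In B-precursor acute lymphoblastic leukemia (B-ALL), skipping of CD22 exon 12
truncates the cytoplasmic domain of the inhibitory co-receptor CD22 and has
been proposed as a driver lesion; patients whose blasts retain very little
exon-12-containing transcript ("CD22E12-low") appear to fare worse under
standard therapy. Detecting such a subgroup from archived exon-level
quantification tables — and testing whether it independently predicts
outcome — takes a small but complete pipeline:

1. **Exon quantification.** For exon *e* of length *L<sub>e</sub>* bp with
   raw count *c* in a library of *N* mapped reads,
   RPKM = (*c* / (*N*/10⁶)) / (*L<sub>e</sub>*/10³).
2. **Panel normalization.** Within a gene, each patient's exon RPKM is
   divided by their mean RPKM over a small panel (here CD22 exons 11–14),
   giving a dimensionless inclusion index with per-patient panel mean 1.
   A uniformly included exon sits near 1; a skipped exon falls well below.
3. **Stratification.** Patients with a normalized target-exon value below a
   cutoff (0.8 for the exon-12 panel) are called *low*; Ward-linkage
   hierarchical clustering provides the exploratory companion view, and a
   two-factor (group × exon) ANOVA with Benjamini–Hochberg FDR control
   confirms that the reduction is selective for the target exon.
4. **Outcome analysis.** Kaplan–Meier curves with Greenwood variance,
   two-group log-rank tests, and univariate/multivariate Cox proportional
   hazards models (Newton–Raphson on the partial likelihood, Efron ties)
   quantify the prognostic effect as hazard ratios HR = e^β with Wald
   95% CIs, adjusting for age band, sex, molecular markers, WBC, and
   end-of-induction MRD.
5. **Cohort characteristics.** Baseline comparisons use two-sided Fisher
   exact tests (point-probability criterion), Mann–Whitney U, and Welch *t*.

Because patient-level outcome data from the original repositories are access
restricted, the package ships a fully synthetic cohort generator that
emulates the published study conditions — a 141-patient cohort with a
planted 21-patient low-inclusion subset, negative-binomial exon counts,
clinical covariates at published frequencies, and exponential survival with
configurable hazard ratios — so every stage is testable end to end.

The survival and contingency statistics are implemented from first
principles (lifelines and scipy's tests serve only as cross-check oracles in
the test suite), so every numerical convention is explicit and verifiable.

## Worked example

```python
from exonsurv import (SyntheticSpec, simulate_cohort, normalize_exon_panel,
                      classify_low, run_outcome_analysis)

cohort = simulate_cohort(SyntheticSpec(), seed=7)
matrix = normalize_exon_panel(cohort.exon_table)
labels = classify_low(matrix, target_exon="E12", threshold=0.8)
print(f"{labels.n_low} low / {labels.n_other} other")

reports = run_outcome_analysis(cohort.clinical, labels, endpoints=("os",))
rep = reports["os"]
row = rep.multivariate.summary.loc["low"]
print(f"log-rank chi-square = {rep.logrank.chi_square:.2f}, "
      f"p = {rep.logrank.p_value:.4f}")
print(f"median OS: low = {rep.medians['low'].median:.0f} d, "
      f"other = {rep.medians['other'].median:.0f} d")
print(f"multivariate Cox HR (low) = {row['hr']:.2f} "
      f"(95% CI {row['hr_lower']:.2f}-{row['hr_upper']:.2f}, p = {row['p']:.4f})")
```

prints

```
22 low / 119 other
log-rank chi-square = 15.61, p = 0.0001
median OS: low = 656 d, other = 2028 d
multivariate Cox HR (low) = 2.93 (95% CI 1.61-5.33, p = 0.0004)
```

The threshold classifier finds 22 of the 21 planted low patients plus one
boundary case; the low group's overall survival is markedly worse (median
656 vs 2028 days), and the adjusted hazard ratio of 2.93 brackets the
planted OS hazard ratio of 2.3 well inside its confidence interval — a
single simulated cohort of 141 patients carries exactly the kind of sampling
noise the multivariate model has to cope with.

The same chain is available from a shell:

```bash
exonsurv simulate --seed 7 --out sim/
exonsurv quantify --exon-table sim/exon_quant.tsv --out norm.tsv
exonsurv classify --matrix norm.tsv --threshold 0.8 --out labels.tsv
exonsurv table1 --labels labels.tsv --clinical sim/clinical.tsv --out table1.tsv
exonsurv outcomes --labels labels.tsv --clinical sim/clinical.tsv --out reports/
```

or end to end with a config file and a reproducibility manifest:
`exonsurv run --config config.yaml`.

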