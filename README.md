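# cohortqc

Ensemble structural-variant (SV) call-set integration and cohort-scale
quality control for trio-structured whole-genome sequencing studies.

Modern population WGS resources genotype thousands of samples, including
hundreds of father–mother–child trios, and call SVs with several
independent pipelines whose error profiles differ sharply.  `cohortqc`
re-implements, as a tested and reusable library, the computational
machinery such resources are built on:

- **Ensemble SV integration** — reciprocal-overlap clustering of
  multi-caller call sets, a per-SV-class gradient-boosted quality model
  ("boost score") over read evidence, FDR-targeted threshold selection,
  and canonical record selection per locus.
- **Trio metrics** — Mendelian error rate, de novo and inheritance
  rates, parental transmission rate, and singleton stratification by
  relatedness.
- **Haplotype-panel filtering** — the PASS / missingness / Hardy-Weinberg
  / Mendelian-error / minor-allele-count cascade that prepares sites for
  statistical phasing, plus the male-X ploidy fix.
- **Phasing evaluation** — switch error rate against a truth panel, SV
  flip rate against flanking SNVs, and trio-based parental flip rate.
- **Imputation evaluation** — dosage r² by allele-frequency bin,
  IMPUTE-style info scores, hard-call genotype discordance, and
  info/MAF-binned variant counts.
- **Truth-set construction** — integration of two independent SV
  genotypers (GQ- and FILTER-gated, discordance → missing), ±50 bp /
  80%-length-ratio site matching, genotype concordance and
  non-reference precision.
- **Synthetic cohorts** — a first-class generator of trio pedigrees
  with Mendelian inheritance, configurable de novo rates, multi-caller
  call sets with logged false positives and breakpoint jitter, phased
  haplotypes with injected switch/flip errors, and imputation-style
  genotype probabilities, so every metric can be validated against a
  known injection log.

## The core rules and statistics

Two same-class SVs $a, b$ are **concordant** when their reciprocal
overlap $\mathrm{RO} = \min(o/\ell_a,\, o/\ell_b)$ (overlap $o$, lengths
$\ell$) reaches 50% for pairs larger than 5 kb and 10% below; insertion
pairs are concordant when their insertion points lie within 100 bp.
Clustered records are scored per genome by a LightGBM model over depth,
1-kb flank depth, pair-end count (≤150 bp), split-read count (≤100 bp
of each breakpoint), size, allele fraction, genomic context, and de
novo fraction; calls with boost score > 0.448 PASS, and call-set-specific
loci failing in ≥48% of carrier samples are dropped.

The panel filter retains sites with FILTER = PASS, genotype missingness
< 5%, HWE exact-test p > 10⁻¹⁰ in at least one super-population,
Mendelian error rate ≤ 5%, and minor allele count ≥ 2.  Switch error
rate is `switches / assessed heterozygous pairs`; dosage r² is the
squared Pearson correlation between imputed and truth dosages
$e = p_{het} + 2 p_{homalt}$; the info score is
$1 - \sum_i (f_i - e_i^2) / (2N\theta(1-\theta))$ with
$f_i = p_{het} + 4 p_{homalt}$.

## Worked example

Simulate a default cohort (30 trios + 40 unrelated samples, 300 true
SVs on a synthetic chromosome), derive two corrupted caller call sets,
train the boost model on injection-log labels, and integrate:

```bash
$ cohortqc integrate --seed 3
{
 "final_loci": 300,
 "false_loci": 5,
 "fdr_percent": 1.67,
 "recall_shared_percent": 100.0,
 "threshold": 0.448
}
```

Of the 300 loci in the final integrated call set, 5 contain only
injected false-positive records (FDR 1.67%, under the 5% design
target), every true SV discovered by both callers was recovered, and
the PASS threshold applied to caller-specific loci was the default
boost-score cutoff 0.448.

The same machinery is available programmatically:

```python
from cohortqc import SimulationConfig, simulate_cohort, corrupt_callsets
from cohortqc.pipeline import run_ensemble_integration

evaluation, cohort, log = run_ensemble_integration(seed=3)
print(evaluation.fdr, evaluation.recall_shared)
```

`cohortqc simulate --seed 3 --out DIR` writes the truth VCFs, pedigree,
per-caller call sets, and the JSON injection log; `cohortqc
panel-filter` and `cohortqc truth-match` expose the filter cascade and
SV site matching on arbitrary VCF/PED inputs.

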