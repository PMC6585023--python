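# Methods

This note documents the statistical model behind `rareburden`, the
conventions the implementation commits to where several are defensible, what
the synthetic cohort generator does and does not emulate, and known
limitations.

## The discovery model

The pipeline targets the regime of a modest exome case cohort (order 10²
cases) screened for rare variants of large effect. Discovery is not a
regression on genotypes but a cascade of set operations followed by two
gene-level accumulation tests:

1. **Variant qualification.** A variant qualifies if it is a SNV, is
   unreported or has frequency < 0.01 in every public allele-frequency
   panel, is absent from in-house control exomes, and has a scaled CADD
   C score > 20 (phred-scaled: top 1% most deleterious genome-wide). All
   four thresholds are strict inequalities; a variant at exactly the
   threshold (frequency = 0.01, C score = 20) does not qualify.
2. **Gene qualification.** Genes must be expressed in brain: the expression
   summary is the mean of 13 per-region median RPKM values; genes with
   summary ≤ 0 are removed, and among the remainder genes in the extreme
   low-expression tail (z ≤ −1.96) are removed.
3. **Poisson accumulation.** Under the null, qualifying variants land on
   genes in proportion to coding length. With M total qualifying variants
   over the tested genes and L_g the CDS length of gene g,

       λ_g = M · L_g / Σ_j L_j,   p_g = P(X ≥ k_g),  X ~ Poisson(λ_g),

   where k_g counts *distinct qualifying variant sites* (not carrier
   events; a carrier-event count is a trivial variation but the site count
   is the default). Benjamini–Hochberg gives q values; discovery at
   q < 0.01. By construction Σ λ_g = M exactly — this conservation is
   asserted in the test suite.
4. **Carrier accumulation.** Genes significant in step 3 are re-tested
   case-vs-control: the 2×2 table of carriers/non-carriers by cohort, with
   an uncorrected Pearson χ² (1 df) and BH at q < 0.05. The discovery
   inputs carry no control genotypes for the candidate variants themselves
   (those were excluded in step 1), so control carriers are counted from
   control-exome variants passing the same variant-level qualification in
   the same genes.
5. **Validation and triage.** Variants failing orthogonal validation (e.g.
   non-polymorphic by Sanger) are masked; of the remainder, only variants
   with *zero* carriers among first-stage genotyped controls advance to
   expanded genotyping.

## Association statistics

Stage-2 association uses carrier-count 2×2 tables per cohort stratum.

* **Per-stratum:** odds ratio ad/bc; Woolf CI
  exp(ln OR ± z·√(1/a + 1/b + 1/c + 1/d)); two-sided P from the
  *uncorrected* Pearson χ² (1 df).
* **Combined:** Mantel-Haenszel common OR Σ(a_i d_i/n_i)/Σ(b_i c_i/n_i);
  CI from the Robins-Breslow-Greenland variance of ln OR_MH (valid for
  sparse strata); P from the MH χ² with the ½ continuity correction.
* **Multiplicity:** Bonferroni, multiplying by the number of variants taken
  into stage 2 (7 in the shipped fixture), capped at 1.
* **MAF:** carriers/(2N determined) — all carriers assumed heterozygous,
  which is the right reading for variants this rare.

The per-stratum/combined conventions are deliberately asymmetric
(no continuity correction within a stratum, continuity correction for the
combined test): this pairing is the one that reproduces every printed
statistic of the two-cohort study the packaged fixture comes from, and both
switches are exposed as flags. Known discrepancies in that source table are
*not* chased: its second-cohort confidence interval 0.02–89.51 comes from an
unstated (likely exact conditional) method and is not reproduced — the
package reports the Woolf interval with the Haldane correction where needed;
and its first-cohort corrected P of 0.77 for the *TYK2* variant is
presumably a typographical slip for 0.077 = 7 × 0.011, which is what
`bonferroni` returns. The published combined corrected P (8.05 × 10⁻⁵)
equals 7 × the MH P *at its printed precision* (1.15 × 10⁻⁵); the unrounded
chain gives 8.07 × 10⁻⁵.

Zero cells: `odds_ratio`/`woolf_ci` default to the Haldane-Anscombe +0.5
correction and flag the row; a zero margin yields χ² = 0, p = 1 by
convention rather than NaN.

## The synthetic cohort generator

The generator exists so that every pipeline stage is exercised end to end
with data of the right *shape*; defaults are pinned to the study regime the
package was built around:

| parameter | default | rationale |
| --- | --- | --- |
| `n_cases` / `n_controls` | 202 / 176 | discovery cohort sizes |
| `baseline_rate` | 0.001 /bp | ≈ 17k qualifying variants over ~8k genes of mean CDS ~2 kb |
| CDS lengths | log-normal, median 1500 bp, σ = 0.8, floor 100 bp | heavy-tailed human CDS scale; tests are length-normalized so any heavy tail works |
| `frac_brain_silent` | 0.19 | fraction of variant-bearing genes with zero brain RPKM in the reference regime |
| expression | shared gene-level log-normal factor + per-region noise (σ 0.7 / 0.15 log₁₀) | regions strongly correlated within gene, realistic z-score tails |
| `frac_panel_reported` / `frac_panel_common` | 0.5 / 0.05 | unreported, rare-reported and common-reported variants all occur, exercising both branches of the rarity rule |
| `cadd_pass_prob` | 0.3 | C > 20 enrichment among rare coding candidates (the empirical distribution of the reference call set is unpublished; this is a documented stand-in) |
| carriers | heterozygous singletons | rare-variant regime where MAF = carriers/2N; homozygotes behind `frac_homozygous` |

Counts are drawn per gene as Poisson(rate × L), with the case rate
multiplied by ρ (`risk_rate_multiplier`) in a random `risk_gene_fraction`
of genes; `simulate_gene_counts` exposes this count layer directly and
`generate_cohort` materialises variants, annotations and carriers on top of
it. Identical configurations produce byte-identical output; independent
seeded streams per stage keep the gene universe stable when cohort
parameters change.

What the generator does **not** emulate: linkage and haplotype structure,
population stratification, genotyping error, realistic indels (indels exist
only as a class label to exercise the SNV restriction), site-frequency
spectra within a cohort (every synthetic variant is a singleton), or
correlation between CADD score and panel frequency. Passing tests on
synthetic data therefore demonstrate the *mechanics* of the cascade and the
calibration of the count-level tests — not robustness to the confounders of
real cohorts.

## Numerical and design choices

* **Expression z-score scale.** The z-score is computed on log₁₀ of the
  expression summary among genes with positive summary. On the raw scale a
  −1.96 threshold on a right-skewed RPKM distribution excludes essentially
  nothing; the log scale gives the ≈ 2.5% lower-tail exclusion that a
  normal-tail threshold is meant to give. A `zscore_log=False` switch
  restores the raw scale.
* **Z-score boundary.** A gene at exactly z = cutoff is excluded (the kept
  set is z > cutoff), making all four filter thresholds consistently
  strict-in-the-keeping-direction. The boundary has measure zero, so this
  is a convention, not a modelling decision.
* **Minimum patient count.** "More than two patients" is read
  conventionally as ≥ 2 (default `min_patients=2`, configurable); the
  literal reading ≥ 3 is available by flag and the ambiguity is noted here
  rather than resolved.
* **Normalization set.** M and ΣL are computed over the genes entering the
  Poisson test (post minimum-patient filter). Widening to all
  expression-passing genes is a caller-side choice: pass the wider count
  table.
* **BH implementation.** The step-up is implemented directly (six lines)
  because the testing family size must be overridable (`m=`); it is
  cross-checked against `statsmodels.stats.multitest.multipletests`
  (`fdr_bh`) in the test suite. Ties are broken by a stable sort on
  (p, gene) for deterministic output order.
* **Cross-checks.** The MH OR, RBG CI and MH test are implemented from
  their defining formulas and verified in the test suite against
  `statsmodels.stats.contingency_tables.StratifiedTable` on random strata,
  and against the published two-cohort table at printed precision.
* **Missing CADD scores** drop the variant by default (candidates must
  demonstrate deleteriousness); `keep` and `error` policies exist.
* **Degenerate inputs.** Empty cohorts produce empty, well-formed tables and
  an all-zero trace; a zero total CDS length is an error; conflicting REF
  alleles at one position are rejected at merge time.

## Calibration of the Poisson burden test

The burden p value P(X ≥ k) is a *discrete* one-sided tail probability, and
its null distribution is therefore super-uniform (stochastically larger than
Uniform(0,1)): P(p ≤ t) ≤ t for every t, with atoms whose mass is the
Poisson pmf at the attained count. Mixing over the continuous spread of
λ_g across genes smooths but does not remove these atoms — at the default
regime (λ_g of order 1–5) the deviation of the p-value CDF from the diagonal
is an order of magnitude larger than the two-sided Kolmogorov-Smirnov
critical distance at 5000 genes, so a two-sided KS test against uniformity
rejects in essentially every null replicate, *for any* realistic variant
rate. This is a property of discrete tests, not an implementation defect:
the error is entirely on the conservative side. The acceptance suite asserts
both faces honestly: the consequence that matters for inference — under a
global null, BH at q < 0.01 yields discoveries in ≤ ~1% of replicate
cohorts, i.e. FDR is controlled — passes; the literal KS-uniformity
assertion fails and is left failing rather than replaced by a weaker check.
Calibration and recovery checks run at 500 null replicates × 5000 genes and
100 spiked replicates per effect size (ρ ∈ {1, 3, 10}, five spiked genes of
median CDS length), sizes at which the binomial bounds used in the
assertions are meaningful.

## Limitations

* No covariate adjustment, kinship handling or population-structure
  correction anywhere in the cascade; the association stage assumes
  well-matched strata.
* The Poisson null attributes all length dependence to CDS length alone —
  no per-gene mutability, GC content or coverage terms.
* Carrier χ² at the accumulation step uses asymptotic Pearson despite small
  expected counts; with singleton-level counts an exact test would be more
  conservative.
* Exact conditional (Fisher-type) confidence intervals are out of scope;
  sparse strata rely on the RBG variance, which is designed for them.
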