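# Methods

## The statistical problem

GWAS of an adjusted-model trait Y·adjZ (here: WHR adjusted for BMI) do not
estimate "Y effects independent of Z". When both phenotypes are analyzed
as inverse-normal residuals, the per-variant effects are tied, to first
order, by

    b_WHRadjBMI ≈ b_WHR − r · b_BMI,

with r the observational BMI–WHR correlation in the analyzed sample. Two
consequences drive everything this package does: (i) an adjusted-trait
scan enriches for variants whose WHR effect is *unexpected* given their
BMI effect — including variants with opposite BMI effects — so adjusted-
and unadjusted-scan hits must be interpreted jointly; (ii) the relation is
invertible, so the unadjusted WHR effect can be *computed* from the
adjusted and BMI effects at a small, quantifiable cost in precision.

## The four classes

Each lead variant is placed on the b_WHR–b_BMI plane and labeled from the
nominal (α = 0.05) significance and direction of its two effects:
concordant `BMI+WHR+` (both significant, same direction, including
supra-expected WHR effects), `BMIonly+`, `WHRonly-`, and discordant
`BMI+WHR-`. Effects are aligned to the BMI-increasing allele where a BMI
effect exists, and to the WHR-decreasing allele for `WHRonly-`; this
single convention makes all four classes hip-increasing-aligned, which is
what lets directional enrichment counts and joint allele scores be summed
within a class. An `unclassified` label exists for completeness; variants
selected at genome-wide significance on BMI or WHR cannot land there, but
adjusted-scan-only variants in principle could. A supra-expected
indicator (WHR effect in the BMI direction exceeding r·b_BMI by more than
1.96 propagated SEs) is emitted as metadata, not as a class: the class
rule alone cannot distinguish supra-expected from merely concordant, and
keeping it metadata preserves the four-class partition.

Degenerate inputs (exactly zero beta with p < α, impossible with
continuous data) are treated as non-significant for that trait.

## Conversion and error propagation

`unadjusted_from_adjusted` computes b_WHR = b_adj + r·b_BMI with
se² = se²_adj + r²·se²_BMI, treating the two input estimates' sampling
errors as independent; the covariance between the adjusted-trait and
covariate-trait estimates is ≈ 0 by construction of the adjustment (in
the bundled generator it is exactly 0 when the estimate-error correlation
equals r). This is an approximation for meta-analyzed inputs with
partially overlapping study samples, and it is validated empirically: on
simulated cohorts the converted p-values are uniform under the null and
the propagated SE always exceeds the directly estimated one (the "small
loss in precision", a factor ≈ √(1 + r²·se²_BMI/se²_adj) ≈ 1.09 at the
bundled conditions). P-values are always recomputed from beta/se after
conversion; the input p is discarded. When sex-specific effects are
converted, sex-specific r must be used; the package's comparison
experiment shows the sex-stratified-conversion + IVW-meta path matches or
slightly improves on the overall-r path even when both are nearly
perfect, with the advantage growing with effect dimorphism.

## Selection and clumping

Candidates are all variants with P < 5×10⁻⁸ (strict) in any scan, after
QC (N ≥ 10,000, autosomes only). Clumping is greedy: the unassigned
candidate with the smallest cross-scan P seeds a signal and absorbs every
unassigned candidate within 500 kb to either side *or* with r² > 0.1
against it; independence therefore requires failing *both* criteria.
Cross-scan P values are compared directly, without recalibration. Ties on
P break by chromosome, then position, then variant ID — the rule is
arbitrary but fixed, making runs deterministic. Without an LD source the
clumping is distance-only (r² taken as 0, with a logged warning); LD can
be supplied as an (id1, id2, r²) table or as equicorrelated blocks.

## Enrichment

For a class and lookup trait, n_tested counts the class variants with an
available lookup estimate (missing lookups shrink n_tested; they are not
non-significant observations), and the increasing/decreasing counts
require nominal significance on the aligned allele. Under the null either
direction is Binomial(n_tested, 0.025): the nominal two-sided rate split
evenly between directions. The tail P(X ≥ n) is computed through the
regularized incomplete beta identity, which stays accurate at the
observed extremes (0.025⁸² ≈ 4×10⁻¹³²); a log-sum-exp fallback covers
tails below double-precision range. Significance is Bonferroni across the
whole battery (0.05/168 for 4 classes × 21 traits × 2 directions).

## Class-restricted Mendelian randomization

The causal effect of BMI on an outcome is the first-order IVW estimator
over one class's variants, equal to the zero-intercept WLS regression of
outcome effects on BMI effects with weights 1/se²_y — the meta-regression
line on the exposure–outcome plane, interpretable as a genetic-risk-score
association. Second-order weights (exposure-SE terms) are deliberately
not used, matching the first-order estimator the framing assumes;
Cochran's Q is emitted as a heterogeneity diagnostic since pleiotropy is
the core caveat of class-restricted instruments. `WHRonly-` is refused as
an instrument set — no BMI effect, no exposure signal. The joint class
risk is the exponentiated sum of aligned per-allele log-odds (one copy of
every aligned allele vs none); this additive-allele definition is one of
several possible summaries and is recorded as such in the output.

## The synthetic generator

The generator exists so every downstream stage is testable without
external data. It emulates: per-variant effects on two correlated unit-
variance phenotypes; rank-based inverse-normal transformation of the
phenotype (Blom offset, (rank − 3/8)/(n + 1/4) — the offset choice is
arbitrary but fixed) or of the WHR-on-BMI OLS residual for the adjusted
trait; sampling noise scaling as 1/√(2f(1−f)N); a planted four-class
architecture (concordant +,+; BMI-only +,0; WHR-only 0,−; discordant
+,−); and a binary disease drawn from a logistic model downstream of the
BMI phenotype (logistic rather than probit liability so outcome effects
are log-odds, the scale disease consortia publish). A fast direct path
draws effect estimates straight from their sampling distribution with
BMI/WHR error correlation equal to the phenotype correlation and the
adjusted estimate defined by the linear relation; the two paths are
distribution-matched (KS-tested in the suite).

Default study conditions, fixed once: N = 50,000; MAF uniform on
0.25–0.35 (the intermediate-frequency range typical of anthropometry lead
variants); phenotype correlation 0.44 overall, 0.46 women / 0.60 men;
class counts 20/10/10/10; per-allele effects 0.055 SD (BMI) and 0.031 SD
(WHR), sized so BMI-scan selection power is high (non-centrality ≈ 8)
while WHR effects sit near nominal-detection power (≈ 4.5); disease
prevalence 10% with 0.5 log-odds per BMI SD. Sexes are assigned exactly
1:1; sex-specific architectures scale true effects per stratum. An
optional multiplicative per-variant effect jitter (off by default)
provides realistic rank spread for fidelity experiments.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: LD beyond optional equicorrelated blocks,
population structure and relatedness, confounding by age or ancestry
(real scans residualize on age, age², and principal components; the
simulator omits nuisance covariates because they are orthogonal to the
tested math), between-study heterogeneity of meta-analyses, and sample
overlap between the exposure and outcome GWAS of the MR stage.

## Benchmark designs and their rationale

* **Enrichment tails** are checked against an explicit brute-force
  summation oracle and against reference two-significant-figure values
  for 37 count pairs; p₀ = 0.025 is pinned by those values (0.025⁸²
  reproduces the most extreme cell exactly).
* **Conversion fidelity** uses one cohort (n = 50,000, 200 variants,
  r = 0.44, jittered effects) and demands Spearman > 0.97 between
  computed and observed WHR effects; the realized (not nominal)
  phenotype correlation is used, as a single-study analysis would.
* **Class recovery** is benchmarked at the Bonferroni-style strict
  threshold (0.05/#variants) with effects sized for > 99% per-variant
  power there, demanding ≥ 95% per-class diagonal. At nominal α = 0.05
  the single-trait classes have an irreducible expected diagonal of
  power × 0.95 (< 95%): a true BMI-only variant shows a chance WHR effect
  5% of the time by construction. The strict threshold is the regime in
  which "recovery" is a well-posed demand; the nominal classifier remains
  the default everywhere else.
* **Adjusted-scan confinement** checks that adjusted-scan significant
  variants land in the two WHR-decrease classes. The benchmark uses
  moderate BMI effects (0.045 SD) so the BMI and adjusted scans select
  essentially disjoint sets, mirroring the empirical non-overlap of BMI-
  and WHRadjBMI-derived loci. The demanded fraction is ≥ 0.96 rather
  than 1.0: a true WHR-only variant whose BMI estimate is nominally
  significant by chance in the same direction classifies as concordant
  (probability ≈ 2.5% conditional on adjusted-scan significance, since
  the adjusted z-score is independent of the BMI z-score when the error
  correlation equals r) — the synthetic counterpart of the rare
  supra-expected exceptions seen in real data.
* **MR recovery** plants a 0.5 log-odds/SD causal effect and demands the
  IVW slope lie within 2 SE of it in ≥ 90% of 200 cohort replicates. The
  mean recovered slope (≈ 0.48) sits slightly below the planted value:
  logistic non-collapsibility (marginalizing the unit-variance phenotype
  residual attenuates log-odds by ≈ 4%) plus regression dilution from
  estimated exposure effects (≈ 2%); both are far inside the coverage
  band at these conditions. Per-variant disease effects are exact
  logistic MLEs computed on genotype-aggregated counts (three cells per
  variant) — identical to the individual-level fit for a single dosage
  covariate, orders of magnitude faster.

## Numerical choices and edge cases

* P-value/effect consistency at parse time: 10% relative tolerance on the
  −log10 scale with an absolute floor of 0.1, absorbing meta-analysis
  rounding; inconsistent rows are dropped and counted.
* Strand-ambiguous variants (A/T, C/G) are kept and flagged, not dropped;
  downstream users decide. Irreconcilable allele pairs drop the variant
  from all tables.
* Positions are 1-based; all distance arithmetic is in base pairs.
* Reported p-values are floored at the smallest positive double so they
  remain in (0, 1].
* Monomorphic variants yield missing effect estimates and are logged,
  never silently filled.
* Infeasible simulation requests (phenotype correlation unreachable given
  the planted genetic covariance) raise a parameter error rather than
  silently clipping.

## Known limitations

* The SE-propagation independence assumption understates the variance of
  converted effects when the input scans share heterogeneous study
  overlap; the package exposes r per stratum but cannot estimate the
  induced covariance from summary data.
* Clumping quality is bounded by the supplied LD source; distance-only
  clumping merges nothing across the window and can over-split long-range
  LD regions.
* The joint relative-risk summary assumes additivity of per-allele
  log-odds and carrying one copy of each aligned allele; it is a
  descriptive compression, not an estimator with a standard error.
* Class labels are threshold classifications of noisy estimates; near
  the significance boundary they are unstable by construction, which is
  why the strict-threshold sensitivity re-classification is part of the
  pipeline output rather than an afterthought.
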