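# adipoclass

A joint view on the genetics of adiposity: classify GWAS variants by their
co-association with body mass index (BMI) and waist-to-hip ratio (WHR),
instead of keeping the three overlapping genome scans — BMI, WHR, and WHR
adjusted for BMI (WHRadjBMI) — apart.

Adjusted-model traits are statistically entangled with their covariate:
per variant, the adjusted-scan effect obeys

    b_WHRadjBMI = b_WHR − r · b_BMI

where *r* is the observational BMI–WHR phenotype correlation in the
analyzed sample (≈ 0.44–0.50 overall; ≈ 0.46 in women, ≈ 0.60 in men). A
WHRadjBMI scan therefore also picks up variants with opposite BMI effects,
and a variant's position on the *b*\_WHR–*b*\_BMI plane — not the scan it
came from — is what carries the biology. `adipoclass` implements that
joint view as a tested pipeline for GWAS summary statistics:

* **sumstats** — read/write GIANT-dialect summary-statistics tables,
  validate records, harmonize effect alleles across traits and strata.
* **selection** — select genome-wide significant variants (*P* < 5×10⁻⁸,
  strict) across the three scans and clump the union into independent
  signals (greedy by smallest *P*; absorbed if within 500 kb **or**
  *r*² > 0.1 of the lead).
* **algebra** — convert between adjusted and unadjusted effects with SE
  propagation (se² = se²\_adj + r²·se²\_BMI), convert lookup *Z* scores to
  betas (β = Z/√(2·f·(1−f)·N)), and IVW-meta-analyze strata.
* **classify** — assign each lead variant to one of four classes from
  nominal significance and direction of its BMI and WHR effects
  (`BMI+WHR+`, `BMIonly+`, `WHRonly-`, `BMI+WHR-`), align alleles so all
  classes are effectively hip-increasing, re-classify at stricter
  thresholds, and test sex differences.
* **enrichment** — per class × lookup trait × direction, an exact upper
  binomial tail P(X ≥ n) with p₀ = 0.025 per direction, Bonferroni-judged
  across the battery (0.05/168 for 4 classes × 21 traits × 2 directions).
* **mr** — class-restricted inverse-variance-weighted Mendelian
  randomization of outcomes on BMI (slope = Σbₓb_y/se²_y ÷ Σb²ₓ/se²_y, the
  zero-intercept weighted meta-regression line), with `WHRonly-` refused
  as an instrument set, plus joint allele-score relative risks.
* **synthetic** — a seeded generator of individual-level cohorts (and a
  fast direct-sampling path) with a planted four-class architecture,
  correlated phenotypes, inverse-normal-residual association analysis,
  and a logistic disease downstream of BMI, so every stage is testable
  without external data.

## Worked example

Run the seeded synthetic pipeline end to end (50 planted variants in a
cohort of 50,000; classes 20/10/10/10):

```sh
adipoclass run-all --seed 42 --outdir runs/demo
```

which prints the run manifest:

```json
{
  "class_counts": {"BMI+WHR+": 20, "BMI+WHR-": 11, "BMIonly+": 9, "WHRonly-": 2},
  "gws_per_scan": {"BMI": 40, "WHR": 5, "WHRadjBMI": 13},
  "n_gws_candidates": 42,
  "n_signals": 42,
  "reclassification": {"changed_class": 3, "newly_unclassified": 0, "retained": 39},
  "true_class_counts": {"BMI+WHR+": 20, "BMI+WHR-": 10, "BMIonly+": 10, "WHRonly-": 10},
  "whr_source": "observed",
  ...
}
```

Reading: 42 of the 50 planted variants reach genome-wide significance in
at least one scan (power at these effect sizes is ≈ 85–100% for classes
with a BMI effect, lower for `WHRonly-`, whose only route is the WHR/adj
scans); each clumps into its own signal because the planted loci are well
separated. The classified counts track the planted architecture: every
selected concordant variant is recovered, and the `WHRonly-` deficit is
selection (those variants are the hardest to detect), not
misclassification. `runs/demo/classification.tsv` holds the per-variant
plane coordinates:

```
variant_id  class      aligned_allele  b_bmi    p_bmi     b_whr     p_whr    ...
var0043     BMI+WHR-   A               0.0525   6.5e-14   -0.0425   1.3e-09
var0023     BMIonly+   A               0.0658   7.0e-23    0.0013   0.84
```

`enrichment.tsv`, `mr.tsv` and `joint_risk.tsv` contain the directional
enrichment battery and the class-restricted MR against the synthetic
disease; `transitions.tsv` the strict-threshold re-classification.

The same stages are importable as a library:

```python
from adipoclass import (ArchitectureSpec, simulate_cohort, cohort_to_sumstats,
                        select_gws, clump, classify, ivw_mr)
```

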