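# Methods

This note documents the statistical procedures implemented in
`mirlifespan`, the conventions chosen where several were defensible, what
the synthetic-data generator does and does not emulate, and the package's
known limitations.

## Data model and normalization

A qPCR panel yields a rectangular samples × assays matrix of threshold
cycles. A well that never crosses the fluorescence threshold is a
*censored* observation: the transcript is below the detection limit, which
bounds its abundance from above but does not make it zero or missing.
`CtMatrix` stores censored wells as a distinct state (NaN inside an
otherwise finite float matrix) and enforces that every finite Ct lies in
`(0, ct_max]` with `ct_max = 40` cycles by default — the cycling limit of
the array instrument, configurable. Values read above `ct_max` are coerced
to censored with a logged count, since they cannot be distinguished from
non-amplification.

ΔCt normalization subtracts the per-sample Ct of an endogenous control
(RNU48 by default): `ΔCt = Ct(target) − Ct(control)`; relative expression
is `2^(−ΔCt)`, so *lower* ΔCt means *higher* abundance. The control column
is consumed rather than reported as an all-zero ΔCt column, and a censored
control is a hard error naming the sample: normalization is then impossible
rather than approximate. The per-sample control Ct is retained on the
`DeltaCtMatrix` because the detection-limit ΔCt, `ct_max − Ct(control)`,
is sample-specific and needed for censored-value imputation.

**Censor policy.** For rank tests the default policy imputes a censored
cell at its sample's detection-limit ΔCt (the standard censored-qPCR
convention): this preserves sample size, is conservative (the true value is
at least that large), and lets assays that are heavily censored in one
cohort remain testable; midranks handle the resulting ties. A `drop`
policy is available; an assay whose usable values vanish under it is kept
under a distinct `untestable` label rather than silently removed.

## Detectability and the five classes

An assay is *detectable* in a cohort when it amplified in at least
`min_frac` (default 0.30, boundary inclusive) of that cohort's samples, and
enters the analysis when detectable in at least one of the two comparison
cohorts. "Expressed in one group only" is operationalized as detectable in
exactly one cohort — the other cohort may still show sporadic
sub-threshold detections, which matches how age-limited expression presents
in practice.

Detectable-in-both assays are compared by a two-sided Wilcoxon rank-sum
test on ΔCt. The exact permutation null of the midrank-sum statistic is
enumerated whenever the arrangement count `C(n_A+n_B, n_A)` is at most
20,000 (the two-sided p is the doubled smaller tail, capped at 1); larger
instances use the normal approximation with midrank tie correction. The
arrangement-count switch, rather than a combined-n switch, guarantees the
exact path is used exactly where exhaustive enumeration is feasible and
keeps small unbalanced designs exact. When every pooled observation is
identical the statistic is degenerate and p = 1.

The per-test threshold is `alpha_family / m` with m the number of
detectable assays on the analyzed panel — dynamic rather than hard-coded,
so a 228-assay detectable set reproduces 0.05/228 ≈ 2.19e−4 while other
panel compositions stay correctly calibrated.

**Fold-change convention.** The signed fold change is computed from cohort
mean ΔCt (equivalently, the ratio of geometric-mean expressions):
`r = 2^(ΔCt_den − ΔCt_num)` for a numerator and denominator cohort,
reported as `r` when `r ≥ 1` and `−1/r` otherwise, so its magnitude is
always ≥ 1. The numerator is always the *older* cohort (adults over
preterm; middle-aged over young), which makes a negative value mean
decreasing expression with age — e.g. a 0.678-cycle ΔCt rise from young to
middle-aged adults reports −1.6.

## Adult aging analyses

Adults are split at 35 years, inclusive on the young side (age ≤ 35 is
young). The young vs middle-aged rank test runs over the assays detectable
in the pooled adult cohort; this universe (≈ 200–230 assays in practice) is
the m for Benjamini–Hochberg step-up selection at FDR level q = 0.20, and
is configurable because the appropriate family is a judgment call. The
realized crude-p cutoff `q·k/m` for k discoveries is reported alongside
the flags so the correction is auditable (6 discoveries in a 205-test
universe at q = 0.20 realize a cutoff of ≈ 0.006).

Discoveries are followed up with correlation against age on the `−ΔCt`
(log2 expression) scale — the scale on which Pearson correlation is
appropriate for roughly log-normal expression noise. The partial
correlation adjusts for gender by residualizing both expression and age on
the gender indicator and correlating the residuals, with `df = n − 3` for
the t-based p. The follow-up family uses Bonferroni `0.05/k` (0.0083 for
six candidates). A validation-style three-cohort comparison (one-way
ANOVA with α/3-adjusted pairwise t-tests) is provided for targeted assays.

**Transition patterns.** Trajectories over the four ordered strata
(preterm, child, young adult, middle-aged adult) are matched to four
templates. Adult-onset is called from detectability alone: below
`min_frac` in both pre-adult strata, detectable in both adult strata. The
remaining templates are called from the expression-scale signs of the three
successive contrasts, each a rank test at α/3 (rank tests rather than ANOVA
post-hocs, for robustness at small strata): (flat, −, −) stable→down→
diminish, (flat, +, −) stable→up→diminish, (−, +, −) down→up→diminish;
anything else is unclassified rather than force-fitted.

## Hot-spot scanning

Loci come from miRBase-style GFF3 (primary-transcript records, so each
record is one gene placement; a miRNA may own several) or a flat TSV.
Coordinates are 1-based inclusive throughout; UCSC cytoband files, which
are 0-based half-open, are converted on read and queried by interval
lookup at the locus start. The *locus* of the hot-spot rule is the
cytogenetic band, and a hot spot is a (band, class) pair with **strictly
more than** `cluster_threshold` (default 5) distinct same-class miRNAs. A
multi-locus miRNA contributes its class once to every band it maps to, so
band counts sum to placements, not to distinct miRNAs — per-location
accounting. Each hot spot carries the within-band class proportion, the
genome-wide proportion of that class among distinct classified miRNAs, and
a right-tail hypergeometric enrichment p (a formal counterpart to the
descriptive proportion contrast; it assumes exchangeable placement, which
clustered miRNA families violate, so it is reported as a ranking aid, not
an inferential claim).

## 2×2 association and the network score

The detection-state/outcome association (e.g. marker detection vs
periventricular leukomalacia among preterm infants) is computed both ways:
Pearson chi-squared with 1 df, continuity correction off by default — the
variant that reproduces a printed P = 0.015 on the 20-vs-10-infant table —
and Fisher's exact test (≈ 0.026 on the same table), side by side, since
the appropriate choice at these cell counts is debatable. The network
score is `−log10(p)` of a right-tailed Fisher exact p, the transform used
by pathway-analysis software (1e−24 → 24); the knowledge-base network
construction behind such scores is deliberately not reimplemented.

## Synthetic data

The generator emulates the *structure* of a lifespan TLDA screening study:
365 assays; 30 preterm, 66 child, 32 young-adult and 28 middle-aged-adult
samples; control Ct ~ N(25, 0.5²); target Ct = control + planted stratum
mean ΔCt + N(0, σ²) with σ = 1 cycle; censoring at Ct ≥ 40 (plus an
optional logistic extra-dropout near the limit, off by default). Planted
class fractions are the exact ratios 137:104:1:22:20:81 over 365 —
nonexpressed assays sit ~5 cycles past the detection limit, age-limited
assays are expressed (baseline ΔCt uniform on [2, 8]) in one cohort only,
and up/down classes differ by 1.5 cycles between cohorts, chosen so typical
realized |fold changes| fall in the 1.4–2.4 range. Six of the ~227
adult-expressed assays (fraction 6/227) decline with adult age at +0.03
ΔCt cycles/year, centred at the young-stratum mean age of 28 so the young
cohort mean is unshifted; children have their own stratum means so all four
transition templates are expressible (via `transition_template_means` or a
truth-table override). Annotation generation plants configurable
same-class cytoband clusters (defaults: 16 age-constant on 14q32.31, 6
up-regulated on 9q22.32), scatters everything else at ≤ 3 per filler band,
and gives 36 assays a second locus so placements exceed the panel size, as
with real multi-copy miRNA genes. Clinical flags are Bernoulli draws whose
probability depends on a named assay's detection state (defaults 0.10
detected / 0.50 undetected).

Everything is driven by one seeded generator, so output is bit-exact under
a fixed seed. What the simulator does **not** emulate: amplification
chemistry, plate/batch effects, inter-assay efficiency differences,
correlated co-expression between miRNAs, and non-Gaussian Ct noise.
Passing recovery tests therefore demonstrates that the pipeline's decision
rules are implemented correctly at realistic effect/noise/sample-size
ratios — not that real cohorts of this size would yield the same power.

## Numerical and design choices

- Detectability boundaries are inclusive (`fraction ≥ min_frac`); the
  hot-spot rule is strict (`count > threshold`); the adult split is
  inclusive on the young side; significance calls use strict `p < α`.
- Class labels are a partition of the panel; the aging-diminished flag is
  an orthogonal annotation (an aging-diminished assay also belongs to an
  adult-detectable class), so class counts stay interpretable.
- Report files echo every threshold actually applied (per-test Bonferroni
  threshold, realized BH cutoff, universe sizes) in `summary.json`;
  pipeline stages can be re-run in isolation from the on-disk TSVs.
- Degenerate inputs: all-tied rank tests return p = 1; degenerate 2×2
  margins return p = 1 with a flag (Fisher) or an error pointing to the
  exact test (chi-squared); zero-variance correlation inputs are an error,
  not a NaN.
- Test problem sizes: exact-test oracle suites enumerate up to 20,000
  arrangements per instance and 2×2 margins up to ~30; recovery suites use
  the full default study shape (365 assays, 156 samples), which runs the
  whole pipeline in a few seconds.

## Limitations

- The rank-sum test is unmoderated; no shrinkage or empirical-Bayes
  variance pooling is offered (deliberately, to mirror the plain
  procedure).
- Detection-limit imputation biases fold-change magnitudes toward the
  limit for heavily censored assays; fold changes for age-limited classes
  are therefore not reported.
- All age contrasts are cross-sectional; no longitudinal modeling.
- The hypergeometric hot-spot p ignores genomic clustering of miRNA
  families and should not be read as a calibrated genome-wide test.
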