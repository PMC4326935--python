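# mirlifespan

Circulating microRNA (miRNA) levels change over the human lifespan: some
miRNAs are expressed at a constant level from infancy to adulthood, some are
switched on or off with age, some are up- or down-regulated in adults
relative to preterm infants, and a small set keeps declining through adult
aging. `mirlifespan` is a reusable implementation of the analysis that maps
this landscape from qPCR-array (TaqMan low-density array, TLDA) screening
data, for transcriptomics researchers working with censored Ct panels.

## The method

Each well of the array reports a threshold cycle `Ct`; wells that never
amplify are **censored** at the detection limit (40 cycles), not missing.
Expression is normalized against an endogenous small-RNA control (RNU48):

```
ΔCt = Ct(miRNA) − Ct(RNU48),   relative expression = 2^(−ΔCt)
```

The pipeline then applies, in order:

1. **Detectability rule.** A miRNA enters the analysis only if it amplified
   in ≥ 30 % of the samples of at least one comparison cohort (preterm
   infants or adults).
2. **Five-class assignment.** Detectable in neither cohort → *nonexpressed*;
   in exactly one → *age-limited* (`preterm_only` / `adult_only`); in both →
   two-sided Wilcoxon rank-sum test on ΔCt at the per-test Bonferroni
   threshold `α/m` (m = number of detectable miRNAs, e.g. 0.05/228 ≈
   0.00022), splitting significant miRNAs into `down_in_adult` /
   `up_in_adult` by the signed fold change
   `2^(−ΔCt_adult)/2^(−ΔCt_preterm)` (reported as `−1/r` when `r < 1`).
3. **Adult aging diminution.** Adults are split at 35 years (young ≤ 35 <
   middle-aged); per-miRNA rank tests are corrected by Benjamini–Hochberg at
   a 20 % FDR over the adult-detectable universe, and discoveries are
   followed up with Pearson and gender-partialled correlations against age
   (Bonferroni `0.05/k`, e.g. 0.0083 for six candidates).
4. **Transition patterns.** Over the four ordered strata (preterm → child →
   young adult → middle-aged adult) each trajectory is matched to one of
   four templates: adult-onset, stable→down→diminish, stable→up→diminish,
   down→up→diminish.
5. **Cytoband hot spots.** miRNAs are placed on cytogenetic bands from
   miRBase-style GFF3 (or TSV) annotation plus a UCSC cytoband map; any band
   carrying **more than five** same-class miRNAs is a hot spot, reported
   with within-band vs genome-wide class proportions and a right-tail
   hypergeometric enrichment p.
6. **2×2 association utilities.** Fisher exact and Pearson chi-squared tests
   for detection-state/outcome tables, plus the network score
   `−log10(p)` (so p = 1×10⁻²⁴ scores 24).

Because TLDA screening cohorts of this design are rarely public, the package
ships a first-class simulator that generates study-shaped data (365-assay
panel, 30 preterm / 66 children / 32 young / 28 middle-aged adult samples,
~1/3 undetectable assays, planted 1.5-cycle class effects at σ = 1, planted
aging slopes and cytoband clusters) together with the planted truth, so
every stage is testable end to end.

## Worked example

```python
import mirlifespan as ml

study = ml.LifespanStudy.from_simulation()   # default study-shaped config
results = study.fit()                        # full pipeline
print(results.summary())
```

prints

```
Lifespan miRNA expression study
===============================================
panel size:            365
detectable (>= 30% in a cohort): 228
per-test Bonferroni threshold: 0.05/228 = 0.000219298

class counts
-----------------------------------------------
  nonexpressed            137  ( 37.5% of panel)
  age_constant            105  ( 28.8% of panel)
  preterm_only              1  (  0.3% of panel)
  adult_only               22  (  6.0% of panel)
  down_in_adult            20  (  5.5% of panel)
  up_in_adult              80  ( 21.9% of panel)

differential super-category: 123 assays
  preterm_only             0.8% of differential
  adult_only              17.9% of differential
  down_in_adult           16.3% of differential
  up_in_adult             65.0% of differential

aging-diminished (BH q=0.2, universe 227): 9 assays (realized crude-p cutoff 0.00793)

cytoband hot spots (> 5 same-class members):
  9q22.32    up_in_adult        6/6 on band (100.0% vs 35.1% genome-wide)
  14q32.31   age_constant       16/16 on band (100.0% vs 46.1% genome-wide)
```

Reading this: of 365 assays, 228 passed the 30 % detectability rule, so the
per-test rank-sum threshold is 0.05/228. The classifier recovered the
planted class structure almost exactly (one `age_constant` extra, one
`up_in_adult` short of the planted 104/81 — a single borderline assay;
macro-averaged class recall 0.998, available via
`ml.score_class_recovery(study.truth, results.assignments)`). 65 % of the
differentially expressed assays are up-regulated in adults. Nine assays
decline from young to middle-aged adults at BH q = 0.2 (the six planted
decliners plus three borderline calls at this liberal FDR level), with
follow-up age correlations around r = −0.26 to −0.50. Both planted cytoband
clusters — and nothing else — are flagged as hot spots.

`results.to_files("out/")` writes `classes.tsv`, `aging.tsv`,
`patterns.tsv`, `hotspots.tsv` and `summary.json` (with every threshold
echoed). The same run is available from the shell:

```sh
mirlifespan simulate --out data/            # synthetic study + truth
mirlifespan all --config run.yaml --out out/
mirlifespan score -a 2 -b 18 -c 5 -d 5      # 2x2 association + network score
```

where `run.yaml` lists the input paths (`ct`, `meta`, optional `annotation`
and `cytobands`) or `simulate: true` with a `simulation:` block.

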