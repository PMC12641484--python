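# chronoscan

A pool-seq genome-scan pipeline for migratory chronotype — the heritable
timing class (early vs late departure) of seasonal migration in birds. The
motivating design is a great reed warbler (*Acrocephalus arundinaceus*)
study in which DNA from pools of nine early- and nine late-departing
birds, for spring and autumn separately, was whole-genome sequenced and
scanned for regions differentiating early from late migrants.

`chronoscan` takes PoPoolation2-style synchronized ("sync") files of
per-pool nucleotide counts and runs the full scan:

1. **Site filtering** — biallelic reduction, minor-allele count ≥ 2 summed
   over the compared pools, per-pool coverage within [5, 57].
2. **Per-site statistics** — pool allele frequencies, allele frequency
   difference AFD = |f₁ − f₂|, the classical pool-seq F_ST
   (H_T − H_S)/H_T with a min(coverage, Z) finite-sample correction
   (Z = 18 chromosomes for pools of 9 diploids), and a two-sided Fisher's
   exact test per site, BH-FDR adjusted genome-wide.
3. **Spline windowing** — a cubic smoothing spline (smoothness chosen by
   generalized cross-validation) is fitted to each scaffold's F_ST series;
   windows are cut at the spline's inflection points, so window sizes
   adapt to the local differentiation landscape.
4. **Outlier windows** — windows containing ≥ 2 SNPs significant at
   FDR < 0.01.
5. **Candidate genes** — genes within 25 kb of an outlier window.
6. **GO overrepresentation** — one-sided hypergeometric test of each
   functional term among candidates vs the gene universe, fold enrichment
   (k/n)/(K/N), retained at FDR < 0.05.
7. **Seasonal contrast** — a two-sample Z-test comparing genome-wide
   per-site F_ST and AFD between the spring and the autumn comparison.

Because the raw reads of the motivating study are not public, the package
includes a synthetic pool-seq generator (`chronoscan.simdata`) that
emulates the study design — binomial chromosome sampling from Z = 18,
Poisson depth around 22.4×, per-read sequencing error, planted
high-differentiation regions and a planted enriched GO term — so every
stage of the pipeline is testable against known ground truth.

## Worked example

Simulate a four-pool study with two planted 5-kb regions (AFD 0.6 between
the two spring pools), then scan it:

```python
from chronoscan import SimConfig, PlantedRegion, RunConfig
from chronoscan import simulate_study, run_scan, run_contrast

cfg = SimConfig(
    n_scaffolds=2, scaffold_length_bp=200_000, n_pools=4, depth_mean=30,
    planted_regions=(
        PlantedRegion("scaffold_1", 60_000, 65_000, delta_afd=0.6),
        PlantedRegion("scaffold_2", 120_000, 125_000, delta_afd=0.6),
    ),
    n_genes=100, seed=23,
)
paths, truth = simulate_study(cfg, "example_study")
run = RunConfig(sync=paths["sync"], gff=paths["gff"], terms=paths["terms"],
                out_dir="example_run")
report = run_scan(run)
print(report.summary["n_outlier_windows"], "outlier windows;",
      report.summary["n_candidate_genes"], "candidate genes")
print(report.enrichment[report.enrichment.retained][["term_id", "fold", "fdr"]])
```

prints

```
25 outlier windows; 42 candidate genes
      term_id      fold       fdr
0  GO:0004806  2.005013  0.000885
```

— the scan found 25 spline windows with ≥ 2 significant SNPs, clustered
in the two planted regions; 42 genes lie within 25 kb of them, and the
planted term (assigned at rate 0.5 near planted regions vs 0.02
elsewhere) is retained as 2.0-fold enriched at FDR = 8.9 × 10⁻⁴. The
seasonal contrast on the same study (`run_contrast(run)`) gives a positive
Z for the spring-vs-autumn F_ST comparison, as only the spring pair
carries planted differentiation.

The same pipeline is available from the shell:

```bash
chronoscan simulate --config sim.yaml --out-dir study/
chronoscan scan     --config run.yaml
chronoscan contrast --config run.yaml
chronoscan report   --run-dir runs/spring/
```

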