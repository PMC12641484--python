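# Methods

## The scan

`chronoscan` implements a pairwise pool-seq differentiation scan. Input
is a synchronized ("sync") file: per genomic site, one column per pool of
six colon-separated counts (A:T:C:G:N:deletion). All positions are
1-based and intervals closed internally; BED output converts to 0-based
half-open at the writing boundary.

### Site filtering

For the compared pool pair a site is reduced to its two most frequent
alleles (counts summed over the two pools; N and deletions are never
eligible; ties for the second allele break by the fixed order
A < T < C < G). A site is analyzed iff

* it is biallelic over the pair (at least two alleles with nonzero pooled
  count),
* the minor-allele count summed over the two pools is ≥ `min_count`
  (default 2),
* every compared pool's allele coverage (A+T+C+G; N/deletions are not
  allele observations) lies in [`min_coverage`, `max_coverage`]
  (defaults 5 and 57 — 57 being 2.5× a mean depth of 22.4×, an absolute
  guard against collapsed repeats).

`min_count` is interpreted as the *sum over the two compared pools*
(the PoPoolation2 convention); a per-pool reading would drop pool-private
variants, exactly the sites the exact test is most sensitive to. Whether
the original tooling evaluates the threshold per pairwise comparison or
across all pools is not documented; the per-comparison reading is used.

### Per-site statistics

With `f_j` the major-allele frequency of pool `j`:

* AFD = |f₁ − f₂|.
* F_ST = (H_T − H_S)/H_T with h_j = 2 f_j (1 − f_j),
  H_S = (h₁ + h₂)/2, and H_T = 2 f̄ (1 − f̄) from the unweighted mean
  frequency. In the default corrected mode each h_j is scaled by
  c_j/(c_j − 1) with c_j = min(coverage_j, Z_j) — the effective number of
  sampled chromosomes can exceed neither read depth nor the haploid pool
  size Z = 2 × individuals (18 for pools of 9) — and the total term by
  c_T/(c_T − 1), c_T = min(c₁, c₂). When c₁ = c₂ = c_T the corrections
  cancel and the estimator reduces to the plain Nei form (a property the
  tests exploit as an oracle). F_ST is undefined (NaN) when H_T = 0 or,
  in corrected mode, when any c_j < 2. The exact finite-sample correction
  inside the originally cited tool's "classical" mode is not published;
  parity with it is approximate by design, and an uncorrected switch
  exists for cross-checks.
* Fisher's exact test, two-sided by the point-probability method (the sum
  of hypergeometric probabilities of all tables at the observed margins
  no more probable than the observed table), computed via
  `scipy.stats.fisher_exact` with a zero-margin convention of p = 1 and a
  memoization cache (tables repeat heavily at pool-seq depths).
* Benjamini–Hochberg step-up q-values (via statsmodels), applied
  genome-wide across all analyzed sites of one comparison.

Monomorphic-rejected sites are excluded from all statistics and from the
n of the seasonal contrast.

### Windows

Per scaffold, a cubic smoothing spline is fitted to (position, F_ST) with
`scipy.interpolate.make_smoothing_spline`; the penalty is chosen by
generalized cross-validation unless a `smoothness` override is given (the
original study's windowing tool does not report its setting). Inflection
points — sign changes of the spline's second derivative — are located on
a dense grid (1 bp steps up to 200 kb spans, proportionally coarser
above) and refined by bisection to < 1 bp. Window boundaries are the
midpoints between the two SNPs flanking each inflection point; windows
tile [first SNP, last SNP] of the scaffold, so every analyzed SNP belongs
to exactly one window. Scaffolds are windowed independently (draft
assemblies carry no inter-scaffold order).

Numerical choices: a fit whose value range is at float-noise level is
treated as curvature-free (one window) rather than hunting sign changes
in coefficient noise; second-derivative values within 10⁻⁹ of the
per-scaffold maximum magnitude are treated as zero. Scaffolds with fewer
than 5 SNPs — the minimum the GCV spline fit accepts — become a single
window flagged `unsplined`; how the original tooling handled such
scaffolds is undocumented, and this fallback keeps the SNP partition
property intact.

A window's `mean_fst` averages members with defined F_ST (undefined
members still count in `n_snps`). A window is an **outlier** iff it
contains ≥ `min_significant` (default 2) SNPs with q < `alpha` (default
0.01).

### Candidate genes and overrepresentation

A gene is a candidate iff its interval intersects an outlier window
extended by `flank` (default 25 000 bp) on the same scaffold — edge-based
distance, overlap counting as zero, deduplicated to each gene's nearest
window. Whether the original rule measured from window edge or midpoint
is unstated; edge-based intersection (the convention of interval tools)
is used.

Each functional term with at least one universe gene is tested one-sided
(enrichment direction) with the hypergeometric tail P(X ≥ k) for k of n
candidates annotated versus K of N universe genes; fold enrichment is
(k/n)/(K/N). The universe is every gene in the supplied annotation —
unannotated genes count in N, mirroring a whole-proteome reference set.
Terms are BH-adjusted jointly and retained at FDR < `fdr_cut` (default
0.05) with fold > 1. A two-sided switch exists for parity experiments.

### Seasonal contrast

Per-site F_ST and AFD vectors are computed for the spring pair and the
autumn pair on their own filtered site sets (one shared `FilterSettings`
for both, since the original analysis documents only one), then compared
with a two-sample Z-test treating the sample standard deviations
(n − 1 denominator, computed internally from the raw vectors) as known:
z = (m_a − m_b)/√(s_a²/n_a + s_b²/n_b), two-sided normal p, 95% CI =
difference ± 1.959964 SE. The test requires n ≥ 30 per group and is
applied to the full per-site vectors so z and the CI are reproducible
from emitted output. Caveat: the spring and autumn comparisons share
genomic sites, so treating them as independent samples is
anti-conservative; the test is implemented as the original analysis
states, and this caveat stands.

## The synthetic-data generator

`simdata` emulates the sampling structure of the motivating study, and
its defaults are that study's design:

| parameter | default | meaning |
|---|---|---|
| `pool_individuals` | 9 | diploids per pool → Z = 18 chromosomes |
| `depth_mean` | 22.4 | Poisson mean reads/site/pool (the study's filtered mean depth) |
| `snp_density` | 0.01 | ≈ 14.4 M polymorphic sites on a ~1.2 Gb genome |
| `error_rate` | 0.001 | per-read allele-flip probability (post-Q20 scale) |
| `background_freq_low/high` | 0.1 / 0.9 | uniform ancestral-frequency band |
| `near_term_prob` / `background_term_prob` | 0.5 / 0.02 | planted-term rate near/far from planted regions |

Per site: an ancestral alternate-allele frequency q is drawn uniformly;
every pool shares q except inside planted regions, where the designated
pool pair is moved to q ± delta_afd/2, clipped to [0.01, 0.99] to keep
sites polymorphic. Per site and pool: chromosomes k ~ Binomial(Z, q) give
the pool frequency g = k/Z, depth d ~ Poisson(depth_mean), alternate
reads ~ Binomial(d, g), and each read flips to a uniformly random other
nucleotide with probability `error_rate` (re-introducing third alleles at
rate ⅔ · error_rate, which biallelic reduction removes — as in real
data). Simulation is biallelic by design since the analysis reduces sites
to two alleles anyway. Genes are placed one per uniform slot (guaranteed
non-overlap); genes within 25 kb of a planted region carry the planted
term at the elevated rate, and 20 neutral background terms are assigned
independently at rate 0.05 per gene. All randomness flows from one seed
through named per-stage substreams (frequencies, counts, annotation), so
outputs are byte-identical under a fixed config.

What the generator does **not** model: linkage and haplotype structure,
mapping artifacts, indels, coverage autocorrelation along the genome, a
realistic (non-uniform) allele-frequency spectrum, and correlated term
assignment (GO-graph structure). Passing recovery tests therefore shows
the pipeline's statistics behave correctly under the idealized sampling
model, not that the biological conclusions of any particular study are
robust to those real-data features.

## Calibration caveat

Fisher's exact test conditions on read-count margins and is slightly
conservative on discrete tables under reads-only binomial sampling
(measured ≈0.5% of null sites at p < 0.01, depth 22.4). Real pool-seq
counts, and this generator, add a chromosome-sampling stage with finite
Z, overdispersing allele counts by roughly 1 + depth/Z (≈2.2 at the
default design). The per-site exact test is therefore anti-conservative
on pool-seq data — ≈6% of null sites reach p < 0.01 — which is a known
property of read-count exact tests in pool-seq, not an implementation
artifact. The downstream decision rule (genome-wide BH at FDR < 0.01
plus ≥ 2 significant SNPs per spline window) absorbs this inflation: in
20 replicate null studies of 100 kb, no replicate produced an outlier
window. Interpret per-site p-values accordingly; outlier windows, not
single sites, are the scan's unit of inference.

## Problem sizes used in verification

The test-suite and acceptance-script studies use scaffolds of 100–200 kb
at default SNP density (≈1 000–2 000 SNPs per scaffold), 25 replicates
for recovery rates, ~100 000 sites for null calibration, and 5-kb planted
blocks at delta_afd 0.5–0.6 with depth 30× — sizes chosen so planted
blocks hold tens of SNPs, enrichment universes hold ~120 genes, and every
study can be regenerated from its seed in seconds.

## Pipeline mechanics

A scan run writes per-site, window (TSV + BED6), candidate-gene and
enrichment tables plus a JSON summary and a manifest of settings, input
checksums and package version. A rerun whose manifest matches (same
inputs, settings, version) is reloaded from disk rather than recomputed.
Genome-wide mean F_ST is reported both per window (the windowed scan's
headline scale) and per site (the contrast's scale); the two differ
because windows weight the genome unevenly in SNP count.
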