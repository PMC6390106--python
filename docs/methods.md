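# Methods

## Model and procedure

`gwaspec` analyses two diseases' GWAS summary statistics jointly. The
per-variant inputs are the effect-allele log odds ratio β, its standard
error se, the association P value, the effect-allele frequency (eaf) and an
imputation quality score. The pipeline is:

1. **Read and filter.** Odds ratios are converted to log-odds by natural
   log. Variants are kept when min(eaf, 1−eaf) ≥ 0.005 and info ≥ 0.5, both
   thresholds inclusive and applied uniformly (sources vary between "\>" and
   "≥" phrasing; one inclusive rule avoids an ambiguous boundary).
2. **Harmonise.** The two tables are joined on variant id (positional key
   chrom:pos:sorted-alleles as a fallback when the id spaces are disjoint)
   and disease B's statistics are mapped onto disease A's effect allele:
   swapped alleles negate β and complement eaf; strand flips are resolved by
   reverse complement; palindromic variants (A/T, C/G) with eaf in
   [0.4, 0.6] in either study are dropped because their strand cannot be
   resolved; incompatible allele pairs are dropped with a logged reason.
   Harmonisation is idempotent and invariant to a study-wide allele flip.
3. **MHC exclusion.** chr6:25–34 Mb (GRCh37, closed interval), the
   conventional bounds for the extended MHC's extreme LD.
4. **Meta-analysis and heterogeneity.** Inverse-variance-weighted
   fixed-effects combination; Cochran's Q with, for two studies,
   Q = (β_A−β_B)²/(se_A²+se_B²), chi-square df=1;
   z_het = Φ⁻¹(1−p_Q). The one-sided transform is deliberate: it puts
   z_het = 0 at p_Q = 0.5 so that "no heterogeneity" contributes nothing to
   the specificity score, and lets z_het (hence S) go negative when the two
   effects agree more than chance expects. p_Q is clamped to
   [1e−300, 1−1e−16] so the transform stays finite while preserving ranks.
5. **Pruning.** Greedy clumping on the reference panel: visit variants by
   descending priority (−log10 meta P for the analysis backbone; |S| when
   pruning specificity lists), keep the current variant, remove everything
   within ±2 Mb on the same chromosome with r² ≥ 0.2. Ties in priority break
   by (chrom, pos). The result is independent of input row order. r² is the
   squared Pearson correlation of dosage vectors.
6. **Sharing diagnostics.** Signed-logP concordance: per disease,
   score = ±(−log10 P), positive when the minor allele increases risk; one
   minor-allele definition (disease A's eaf) is used for both scores so they
   refer to the same allele. Conditional QQ: for thresholds
   {0.05, 0.01, 0.005, 0.001, 5e−4, 1e−4}, the target disease's P values
   among variants passing the conditioning disease's threshold, with
   expected quantiles −log10(i/(n+1)) and λ = median(χ²)/χ²₀.₅(1), the
   median-based inflation factor (chosen for robustness; the plotting layer
   is a thin wrapper over emitted plot-data tables so the numbers are
   testable without graphics).
7. **Specificity.** S = |β/se| × z_het per disease; each variant is assigned
   to the disease with the larger S (ties to the smaller association P).
   The top-1% quota is ceil(0.01 × pruned-universe size) per disease — the
   universe, not each disease's assigned subset, so the two lists have equal
   size. Records with S ≤ 0 are never promoted even if a disease falls short
   of quota (truncated with a warning). Percentile ranks are computed within
   the assigned-disease subset; they act as pseudo-P values in the gene-set
   export (top-1% variants with meta P < 0.05, pruned at r² < 0.2 with
   priority = S). S is a prioritisation score only; no parametric P is ever
   attached to it because its null distribution depends on the studies'
   allele frequencies and sample sizes.
8. **Proxy expansion.** For each top-1% index variant, all panel variants
   within ±1 Mb with r² strictly above 0.8 join the disease-specific set
   (the index always belongs, r² = 1). 1 Mb bounds the search while easily
   covering the span where r² > 0.8 is attainable.
9. **Enrichment.** Enhancer identity is the exact (chrom, start, end)
   triple; the union over cell types forms the rows of a binary activity
   matrix. The observed statistic counts distinct active enhancers
   containing ≥ 1 query SNP (not SNP–enhancer pairs). Intervals are
   half-open 0-based, SNPs 1-based: containment is start < pos ≤ end.
   The default null jointly permutes the interval→activity-profile mapping,
   conserving both margins of the matrix exactly; an independent per-column
   shuffle (conserving column sums only) is available, and its per-cell-type
   marginal null coincides with the joint one. SNPs are never shuffled, so
   the query set's LD is preserved by construction. P values use the add-one
   rule p = (b+1)/(n_perm+1), never zero; with the default 10,000 shuffles
   the floor is ≈ 1e−4. No multiple-testing correction is applied across
   cell types; the output records how many were tested.

## Synthetic data

The generator emulates the structure this analysis consumes, with known
ground truth.

* **Panel.** Haplotypes follow a Markov copying model within blocks: the
  allele at the next SNP copies the previous one with probability ρ,
  otherwise it is drawn fresh from Bernoulli(f). The allele frequency f is
  shared within a block (drawn U(0.05, 0.5) per block), as tightly linked
  real variants share frequencies. This realises corr = ρ^|i−j| exactly on
  the observable dosage scale. A thresholded latent-Gaussian model was
  rejected: dichotomising attenuates correlation tetrachorically (badly at
  low f), so no latent ρ can deliver the intended observable LD decay.
  Blocks are placed ≥ 3 Mb apart round-robin over 22 chromosomes, outside
  the 2 Mb pruning window, so they are LD-independent by construction.
* **Summary statistics** are simulated at the summary level: within each
  block β̂_d ~ Normal(Rβ_d, S_d R S_d), with R the block's empirical dosage
  correlation, β_d the class-assigned true log-odds and
  S_d = diag(1/√(2f(1−f)·n_eff,d)), n_eff = 4/(1/n_cases + 1/n_controls).
  This matches the distributional assumptions the downstream statistics
  make and is orders of magnitude faster than individual-level logistic
  regression. Effect classes: shared (same β both diseases), A-specific
  (β_B = 0), B-specific (β_A = 0), null; at most one causal variant per
  block. Cohort sizes default to 14,361/43,923 (A) and 4,036/6,959 (B) so
  the two diseases' standard errors show the power asymmetry of a large RA
  study against a smaller SLE study.
* **Annotations.** Each cell type receives fixed-length intervals placed
  uniformly over the panel's coordinate space; the designated target cell
  type instead centres a fraction f of its intervals on randomly chosen
  truth SNPs. All outputs are deterministic functions of (config, seed).

### Default parameters that matter

| parameter | default | rationale |
|---|---|---|
| blocks × SNPs/block | 2,000 × 10 (20,000 SNPs) | enough blocks for stable tail quantiles; runs in seconds |
| ρ (copy probability) | 0.5 | adjacent dosage r² = 0.25: realistic moderate LD under which the ranking recovers ≥ 90% of the weaker disease's causal variants across seeds; at ρ ≥ 0.7 clumps grow beyond the r² > 0.8 proxy radius and weak-signal tags drift off their causal variant |
| reference samples | 500 | r² estimation noise ≪ the thresholds being applied |
| causal classes | 100 shared (β=0.10), 50+50 specific (β=0.15) | modest-effect polygenic signals at which the specificity ranking is challenged but not saturated |
| annotation | 20 cell types × 300 enhancers × 1 kb, f = 0.3 | one clearly enriched cell type among uniform background tracks |

## What the generator does and does not emulate

It reproduces block LD, realistic standard-error scales, the power asymmetry
between cohorts, effect-direction symmetry, and annotation tracks with a
planted enrichment. It does **not** emulate real human LD maps or
recombination hotspots, genome-wide SNP density, frequency-dependent
architecture, case-control liability-scale subtleties, population
stratification, or overlapping controls between studies. Passing tests
therefore demonstrate the statistics are implemented correctly and behave as
designed under their own assumptions — not that the pipeline's operating
characteristics transfer quantitatively to any particular pair of real
GWAS. In particular, at the default ρ = 0.5 proxy sets are near-singletons
(r² > 0.8 pairs are rare); high-LD behaviour of the proxy machinery is
exercised separately at ρ close to 1.

## Numerical choices and degenerate inputs

* p_Q clamp [1e−300, 1−1e−16]; simulated P values floored at 5e−324;
  −log10 priorities floored accordingly.
* Pruning/ranking tie-breaks are total orders ((chrom, pos) ascending;
  larger |t| before position for equal S), so every output is deterministic.
* The proxy threshold is strict (r² > 0.8), the pruning threshold inclusive
  (remove r² ≥ 0.2), matching their "greater than" / "less than" readings.
* Empty SNP sets give p = 1 everywhere with a warning; a disease with no
  positive-S variants gets an empty top list; an index variant missing from
  the panel is kept as a singleton with a warning.
* Noise Cholesky factors add 1e−4 jitter to the empirical correlation to
  guarantee positive-definiteness; monomorphic panel columns are rejected at
  load (and the generator guards against the vanishingly rare monomorphic
  draw).
* A single master seed derives one sub-seed per pipeline stage (stage-name
  keyed), so stages rerun in isolation reproduce the pipeline bit for bit.

## Validation experiment sizes

The test suite and `scripts/acceptance.py` size their experiments to run the
whole battery in a few minutes on one CPU: oracle equivalence on 1,000
random draws; Q-test calibration and null inflation at 20,000 variants
(independent variants for the λ check, where the median's sampling noise
would otherwise dominate the tolerance); ranking recovery at the default
20,000-SNP configuration over 10 seeds; enrichment calibration over 200
null (cell type × replicate) runs plus exhaustive enumeration on ≤ 7
enhancers; enrichment power over 50 seeds of a 4,000-SNP configuration; and
a double pipeline run compared byte for byte.

## Known limitations

* Exactly two studies; no random-effects model and no compatibility with
  external meta-analysis tools' file formats.
* LD comes from dosage correlation in a single panel; no haplotype phasing,
  no shrinkage estimators, no external LD services.
* No liftover, multi-allelic splitting, or X-chromosome handling.
* The enrichment statistic treats all enhancers as exchangeable rows; no
  length or GC matching of a SNP-based null (the null shuffles annotations,
  not SNPs, by design).
* S values are comparable within one pair of studies only — sample size and
  allele frequency enter se directly, so S is not calibrated across
  datasets.
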